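"""Parametric five-spline flower catheter.

Each spline is a planar petal loop lying flat on the myocardial surface.
The loop is an ellipse whose major axis points radially outward: it
leaves the central hub, reaches the flower tip radius and returns, so
consecutive petals tile the annulus around the vein orifice.  Four
cylindrical electrodes per spline sit on the loop at equal arc spacing
straddling the outer tip.  Walking along the loop the electrode serial
order is i, ii, iii, iv; ii and iii flank the tip (radially outermost)
while i and iv sit closer to the hub — so between adjacent petals
electrode iv of one spline faces electrode i of the next.  That
arrangement is what makes the discharge modes behave so differently:
with i/iv grounded and ii/iii positive the inter-petal region sees two
like-polarity electrodes (field cancellation, lesion gaps), whereas
alternating polarity along the loop puts opposite polarities across the
inter-petal gap (field superposition, continuous lesion).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

from .config import GeometryConfig, ConfigError

_ROMAN = {1: "i", 2: "ii", 3: "iii", 4: "iv"}
_ROMAN_INV = {v: k for k, v in _ROMAN.items()}


@dataclass(frozen=True)
class ElectrodeSegment:
    """One cylindrical electrode on a spline.

    ``electrode_id`` is the global 1..20 identifier
    (``(spline_id - 1) * 4 + position_id``); ``center`` and ``tangent``
    are 3-vectors in mm (tangent is unit length, parallel to the petal
    plane).  The rasterised electrode is a capsule: a core segment of
    length ``length - diameter`` with hemispherical caps, so the overall
    tip-to-tip extent equals ``length``.
    """

    electrode_id: int
    spline_id: int
    position_id: int  # 1..4 == i..iv
    center: np.ndarray
    tangent: np.ndarray
    length: float
    diameter: float

    @property
    def position_name(self) -> str:
        return _ROMAN[self.position_id]

    @property
    def address(self) -> str:
        return f"s{self.spline_id}:{self.position_name}"


def electrode_id(spline_id: int, position_id: int, electrodes_per_spline: int = 4) -> int:
    """Global electrode id from (spline, position), both 1-based."""
    return (spline_id - 1) * electrodes_per_spline + position_id


def parse_address(addr: str, electrodes_per_spline: int = 4) -> int:
    """Parse ``"s3:ii"``-style electrode addressing to a global id."""
    spline_part, pos_part = addr.strip().lower().split(":")
    spline_id = int(spline_part.lstrip("s"))
    position_id = _ROMAN_INV[pos_part] if pos_part in _ROMAN_INV else int(pos_part)
    return electrode_id(spline_id, position_id, electrodes_per_spline)


@dataclass(frozen=True)
class CatheterLayout:
    """Flower catheter pose: petal curves plus 20 electrode segments.

    ``pose_angle`` is the rotation of the whole catheter about the vein
    axis, in degrees, counterclockwise viewed from the blood side.
    ``spline_curves`` holds one (n, 3) polyline per petal for
    rasterising the insulating spline body.
    """

    electrodes: tuple[ElectrodeSegment, ...]
    spline_curves: tuple[np.ndarray, ...]
    pose_angle: float
    plane_z: float

    def __iter__(self) -> Iterator[ElectrodeSegment]:
        return iter(self.electrodes)

    def electrode(self, eid: int) -> ElectrodeSegment:
        return self.electrodes[eid - 1]

    def rotated(self, delta_deg: float) -> "CatheterLayout":
        """Rigidly rotate the layout by ``delta_deg`` about the vein axis."""
        rot = _rotz(np.deg2rad(delta_deg))
        electrodes = tuple(
            replace(e, center=rot @ e.center, tangent=rot @ e.tangent)
            for e in self.electrodes
        )
        curves = tuple(curve @ rot.T for curve in self.spline_curves)
        return CatheterLayout(
            electrodes=electrodes,
            spline_curves=curves,
            pose_angle=(self.pose_angle + delta_deg) % 360.0,
            plane_z=self.plane_z,
        )


def _rotz(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _petal_curve(config: GeometryConfig, n_samples: int = 720) -> np.ndarray:
    """Reference petal polyline (spline 1, pose 0) in the z = 0 plane.

    Ellipse loop: parameter t runs from -pi (hub, side 1) through 0
    (outer tip) to +pi (hub, side 2).
    """
    a = 0.5 * (config.flower_radius - config.hub_radius)
    m = 0.5 * (config.flower_radius + config.hub_radius)
    b = config.petal_halfwidth
    t = np.linspace(-np.pi, np.pi, n_samples)
    x = m + a * np.cos(t)       # radial coordinate along the petal axis
    y = b * np.sin(t)           # transverse coordinate
    # tip taper: narrows the petal towards its outer tip (1 - taper of
    # the full halfwidth at the tip, untouched at the hub), giving the
    # pointed-petal profile of deployed flower catheters
    y = y * (1.0 - config.petal_tip_taper * ((1.0 + np.cos(t)) / 2.0) ** 2)
    # optional recurve: pulls the petal sides toward the axis without
    # moving the tip, so the hub-side electrodes sit nearer the vein rim
    x = x - config.petal_inner_pull * 0.5 * (1.0 - np.cos(t))
    return np.column_stack([x, y, np.zeros_like(t)])


def place_catheter(config: GeometryConfig, pose_angle: float = 0.0) -> CatheterLayout:
    """Build the flower layout at a given pose angle (degrees, ccw).

    Electrode centres sit on the petal arc at centre-to-centre spacing
    ``electrode_length + electrode_spacing`` (5.0 mm for the reference
    catheter), symmetric about the outer tip.  The insulating petal
    body lies tangent on the myocardial surface (its underside grazes
    z = 0 without displacing tissue); the electrodes are lowered by
    ``contact_embed`` so their capsules dip below the surface,
    guaranteeing electrical contact after rasterisation.
    """
    pose_angle = pose_angle % 360.0
    n_per = config.electrodes_per_spline
    pitch = config.electrode_pitch
    plane_z = config.electrode_radius  # polymer tangent to the surface
    electrode_z = config.electrode_radius - config.contact_embed

    curve = _petal_curve(config)
    seg = np.diff(curve[:, :2], axis=0)
    ds = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(ds)])  # arc length from t = -pi
    total = s[-1]
    s_tip = 0.5 * total  # t = 0 by symmetry

    # Arc positions of the electrode centres, symmetric about the tip.
    offsets = (np.arange(n_per) - (n_per - 1) / 2.0) * pitch
    chain_span = offsets[-1] - offsets[0] + config.electrode_length
    if chain_span > total:
        raise ConfigError(
            f"electrode chain ({chain_span:.1f} mm) exceeds the petal "
            f"arc length ({total:.1f} mm); enlarge the flower or petal"
        )
    s_centers = s_tip + offsets

    centers_xy = np.column_stack(
        [np.interp(s_centers, s, curve[:, 0]), np.interp(s_centers, s, curve[:, 1])]
    )
    # Unit tangents along the arc at the electrode centres.
    eps = 1e-3
    ahead = np.column_stack(
        [np.interp(s_centers + eps, s, curve[:, 0]), np.interp(s_centers + eps, s, curve[:, 1])]
    )
    behind = np.column_stack(
        [np.interp(s_centers - eps, s, curve[:, 0]), np.interp(s_centers - eps, s, curve[:, 1])]
    )
    tangents_xy = ahead - behind
    tangents_xy /= np.linalg.norm(tangents_xy, axis=1, keepdims=True)

    electrodes: list[ElectrodeSegment] = []
    curves: list[np.ndarray] = []
    base_curve = curve.copy()
    base_curve[:, 2] = plane_z
    for spline_id in range(1, config.n_splines + 1):
        theta = np.deg2rad(pose_angle + (spline_id - 1) * 360.0 / config.n_splines)
        rot = _rotz(theta)
        curves.append(base_curve @ rot.T)
        for position_id in range(1, n_per + 1):
            cxy = centers_xy[position_id - 1]
            txy = tangents_xy[position_id - 1]
            center = rot @ np.array([cxy[0], cxy[1], electrode_z])
            tangent = rot @ np.array([txy[0], txy[1], 0.0])
            electrodes.append(
                ElectrodeSegment(
                    electrode_id=electrode_id(spline_id, position_id, n_per),
                    spline_id=spline_id,
                    position_id=position_id,
                    center=center,
                    tangent=tangent,
                    length=config.electrode_length,
                    diameter=config.electrode_diameter,
                )
            )

    return CatheterLayout(
        electrodes=tuple(electrodes),
        spline_curves=tuple(curves),
        pose_angle=pose_angle,
        plane_z=plane_z,
    )
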