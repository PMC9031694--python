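"""Configuration objects for the ablation phantom and simulation.

All lengths are millimetres, conductivities S/m, potentials volts and
field magnitudes V/cm unless noted otherwise.  The defaults describe a
left-atrial pulmonary-vein ostium phantom: a 10 mm myocardial slab under
50 mm of blood, pierced by a 25 mm vein lumen, with a five-spline
"flower" catheter (20 platinum electrodes) pressed flat onto the
myocardium around the orifice.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

# Voxel labels.  Electrode k (1..20) is stored as ELECTRODE_BASE + k so a
# single integer grid carries tissue identity and electrode identity.
LABEL_EXTERIOR = 0
LABEL_BLOOD = 1
LABEL_MYOCARDIUM = 2
LABEL_CATHETER = 3
ELECTRODE_BASE = 10

#: Irreversible-electroporation threshold for myocardium, V/cm.
DEFAULT_ELA_THRESHOLD = 400.0


def electrode_label(electrode_id: int) -> int:
    """Grid label for electrode ``electrode_id`` (1-based)."""
    return ELECTRODE_BASE + electrode_id


def is_electrode_label(label: int) -> bool:
    return label > ELECTRODE_BASE


class ConfigError(ValueError):
    """Raised when a configuration violates a geometric invariant."""


@dataclass(frozen=True)
class GeometryConfig:
    """Geometry of the tissue phantom, catheter and voxel grid.

    The petal curve of each spline is a planar ellipse-like loop running
    from ``hub_radius`` out to ``flower_outer_diameter / 2`` with
    half-width ``petal_halfwidth``; four electrodes sit on the loop at
    equal arc spacing straddling the outer tip.  ``voxel_size`` is the
    in-plane (x, y) spacing inside the region of interest and
    ``voxel_size_z`` the vertical spacing in the refined slab; outside
    the region of interest the grid is geometrically stretched out to
    the full domain so the insulating far boundary stays far away
    without an infeasible uniform fine grid.
    """

    blood_height: float = 50.0          # H1: blood layer above the myocardium
    myocardium_thickness: float = 10.0  # H2: myocardial slab thickness
    vein_diameter: float = 25.0         # D1: pulmonary-vein lumen diameter
    domain_diameter: float = 200.0      # full model diameter
    flower_outer_diameter: float = 36.0  # tip-to-tip diameter of the petals
    petal_halfwidth: float = 5.5        # half-width of one petal loop
    petal_tip_taper: float = 0.5        # 0 = blunt elliptic tip, ->1 = pointed tip
    petal_inner_pull: float = 0.0       # recurve of the petal sides toward the axis
    hub_radius: float = 2.5             # radius where petals meet the shaft
    electrode_length: float = 2.5
    electrode_diameter: float = 2.33
    electrode_spacing: float = 2.5      # end-to-end gap between electrodes
    n_splines: int = 5
    electrodes_per_spline: int = 4
    voxel_size: float = 0.25            # in-plane ROI spacing
    voxel_size_z: float = 0.25          # vertical spacing in the refined slab
    roi_halfwidth: float = 30.0         # |x|,|y| extent of the fine grid
    roi_top: float = 4.0                # fine vertical spacing up to this z
    contact_embed: float = 0.5          # electrode embedding below z = 0
    stretch_ratio: float = 1.35         # geometric grading outside the ROI

    def __post_init__(self) -> None:
        for name in (
            "blood_height",
            "myocardium_thickness",
            "domain_diameter",
            "flower_outer_diameter",
            "petal_halfwidth",
            "electrode_length",
            "electrode_diameter",
            "electrode_spacing",
            "voxel_size",
            "voxel_size_z",
            "roi_halfwidth",
            "roi_top",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.vein_diameter < 0:
            raise ConfigError("vein_diameter must be non-negative")
        if self.voxel_size > self.electrode_diameter / 2:
            raise ConfigError(
                "voxel_size must not exceed half the electrode diameter "
                f"({self.electrode_diameter / 2:.3f} mm) or electrodes "
                "cannot be resolved"
            )
        if self.flower_outer_diameter <= self.vein_diameter:
            raise ConfigError(
                "flower_outer_diameter must exceed vein_diameter so the "
                "petals rest on the myocardium around the orifice"
            )
        if self.domain_diameter < 2 * self.roi_halfwidth:
            raise ConfigError("domain_diameter smaller than the ROI")
        if self.stretch_ratio <= 1.0:
            raise ConfigError("stretch_ratio must be > 1")

    # Derived quantities -------------------------------------------------
    @property
    def vein_radius(self) -> float:
        return self.vein_diameter / 2.0

    @property
    def flower_radius(self) -> float:
        return self.flower_outer_diameter / 2.0

    @property
    def domain_radius(self) -> float:
        return self.domain_diameter / 2.0

    @property
    def electrode_radius(self) -> float:
        return self.electrode_diameter / 2.0

    @property
    def electrode_pitch(self) -> float:
        """Centre-to-centre arc distance of consecutive electrodes."""
        return self.electrode_length + self.electrode_spacing

    @property
    def n_electrodes(self) -> int:
        return self.n_splines * self.electrodes_per_spline

    @property
    def reporting_radius(self) -> float:
        """Outer radius for ring-closure and gap reporting.

        Midway between the flower radius and the ROI edge, so the far
        field never masquerades as lesion boundary.
        """
        return 0.5 * (self.flower_radius + self.roi_halfwidth)

    def replace(self, **kwargs: Any) -> "GeometryConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class MaterialTable:
    """Electrical properties per tissue label at a stated frequency.

    Defaults are low-frequency (5 kHz, 37 °C) values for myocardium,
    blood, platinum electrodes and the insulating catheter polymer.
    """

    conductivity: Mapping[str, float] = field(
        default_factory=lambda: {
            "myocardium": 0.137,
            "blood": 0.70,
            "electrode": 4.6e6,
            "catheter": 1.0e-5,
        }
    )
    relative_permittivity: Mapping[str, float] = field(
        default_factory=lambda: {
            "myocardium": 1.28e5,
            "blood": 5250.0,
            "electrode": 1.0,
            "catheter": 1.0,
        }
    )
    frequency: float = 5000.0

    def __post_init__(self) -> None:
        for name, sigma in self.conductivity.items():
            if sigma <= 0:
                raise ConfigError(f"conductivity of {name!r} must be > 0")

    def sigma_for_label(self, label: int) -> float:
        return self.conductivity[_LABEL_NAMES[min(label, ELECTRODE_BASE + 1)]]

    def replace(self, **kwargs: Any) -> "MaterialTable":
        return dataclasses.replace(self, **kwargs)


_LABEL_NAMES = {
    LABEL_BLOOD: "blood",
    LABEL_MYOCARDIUM: "myocardium",
    LABEL_CATHETER: "catheter",
    ELECTRODE_BASE + 1: "electrode",
}


@dataclass(frozen=True)
class PulseSpec:
    """Biphasic pulse description (metadata under the static model).

    The solver treats the plateau as a static excitation; with static,
    isotropic conductivities the pulse count and timing cannot change
    the field distribution, so these values are carried for reporting
    only.  ``amplitude_vpp`` is the peak-to-peak generator amplitude;
    ``plateau_potential`` is the electrode-to-ground potential actually
    applied in the static solve (calibrated once, see the pipeline
    module).
    """

    amplitude_vpp: float = 1800.0
    phase_us: float = 50.0
    interphase_delay_us: float = 50.0
    plateau_potential: float = 900.0


@dataclass(frozen=True)
class SolverOptions:
    """Iterative-solver controls (deterministic: no randomisation).

    ``float_conductors`` switches undriven electrodes from the default
    open-circuit treatment to isolated equipotential platinum bodies
    (sensitivity analysis; see the solver module).
    """

    tol: float = 1e-8
    maxiter: int = 20000
    float_conductors: bool = False


@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of everything one run needs."""

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    materials: MaterialTable = field(default_factory=MaterialTable)
    pulse: PulseSpec = field(default_factory=PulseSpec)
    solver: SolverOptions = field(default_factory=SolverOptions)
    ela_threshold: float = DEFAULT_ELA_THRESHOLD  # V/cm

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def replace(self, **kwargs: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str | Path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from a YAML/JSON key tree.

    Any omitted key keeps its default, so a config file only states
    deviations from the reference phantom.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: Mapping[str, Any]) -> SimulationConfig:
    geometry = GeometryConfig(**raw.get("geometry", {}))
    mat_raw = dict(raw.get("materials", {}))
    materials = MaterialTable(
        conductivity={**MaterialTable().conductivity, **mat_raw.get("conductivity", {})},
        relative_permittivity={
            **MaterialTable().relative_permittivity,
            **mat_raw.get("relative_permittivity", {}),
        },
        frequency=mat_raw.get("frequency", 5000.0),
    )
    pulse = PulseSpec(**raw.get("pulse", {}))
    solver = SolverOptions(**raw.get("solver", {}))
    threshold = raw.get("ela_threshold", DEFAULT_ELA_THRESHOLD)
    return SimulationConfig(
        geometry=geometry,
        materials=materials,
        pulse=pulse,
        solver=solver,
        ela_threshold=threshold,
    )


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
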