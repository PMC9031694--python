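"""Solve one discharge step and look at the field it produces.

Mode B drives electrodes i/iii of every petal at the plateau potential
against ii/iv: alternating polarity along each petal.  The script
prints the solver diagnostics, the electrode current balance and a
depth profile of |E| under one electrode — the 400 V/cm crossing of
that profile is the local lesion depth.
"""

import numpy as np

import pfasim as pf

config = pf.GeometryConfig(voxel_size=1.0, voxel_size_z=0.5, contact_embed=0.5)
result = pf.run_mode(config, "B", keep_solutions=True)
sol = result.solutions[0]

print(f"CG iterations {sol.iterations}, relative residual {sol.residual:.2e}")
print(f"potential range [{sol.phi.min():.1f}, {sol.phi.max():.1f}] V "
      "(discrete maximum principle: must stay inside [0, V0])")
cur = sol.currents
print(f"current out of + electrodes {cur['positive']:.2f} A, "
      f"into ground {cur['ground']:.2f} A "
      f"(imbalance {abs(cur['positive'] - cur['ground']) / cur['positive']:.2e})")

e = result.phantom.layout.electrode(1)  # electrode i of spline 1
profile = pf.probe_line(sol, e.center[0], e.center[1])
in_myo = (profile[:, 0] > -10) & (profile[:, 0] < 0)
print(f"\n|E| vs depth under electrode {e.address}:")
for z, mag in profile[in_myo][::4]:
    marker = " <- above IRE threshold" if mag >= 400.0 else ""
    print(f"  z = {z:6.2f} mm   |E| = {mag:8.1f} V/cm{marker}")

ela = pf.ELAMask.from_result(result)
print(f"\nlesion depth (deepest E >= 400 V/cm voxel): "
      f"{pf.max_lesion_depth(ela):.2f} mm")
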