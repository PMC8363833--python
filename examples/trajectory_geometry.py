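"""Interdomain geometry of two synthetic MD ensembles.

Simulates 1000-frame Calpha trajectories of a 165-residue two-domain
protein (domains 1-76 and 80-165, linker 77-79) in a free-like and a
bound-like state whose interdomain center-of-mass distance and
linker-vertex angle differ by 0.5 A and 2.5 degrees, then recovers the
ensemble shift and a two-state salt-bridge occupancy.
"""

import numpy as np

from hdxflex import BondPairSpec, TrajSimConfig, bond_occupancy, simulate_trajectory
from hdxflex.geometry import geometry_series, probability_curve

free = simulate_trajectory(TrajSimConfig(n_frames=1000, seed=1))
bound = simulate_trajectory(
    TrajSimConfig(n_frames=1000, distance_mean=29.5, angle_mean=97.5, seed=2)
)

for name, traj in (("free", free), ("bound", bound)):
    d = geometry_series(traj, "distance")
    a = geometry_series(traj, "angle")
    print(f"{name:6s} distance {d.mean():6.2f} +/- {d.sd():.2f} A   "
          f"angle {a.mean():6.2f} +/- {a.sd():.2f} deg")

d_shift = (geometry_series(free, "distance").mean()
           - geometry_series(bound, "distance").mean())
a_shift = (geometry_series(free, "angle").mean()
           - geometry_series(bound, "angle").mean())
print(f"shift  distance {d_shift:+.2f} A   angle {a_shift:+.2f} deg")

# ECDF probability curve (the S-shaped curve of a normal ensemble)
curve = probability_curve(geometry_series(free, "distance"))
median = curve.loc[(curve["probability"] - 0.5).abs().idxmin(), "value"]
print(f"free-state distance ECDF median: {median:.2f} A")

# intermittent salt bridge with 60% stationary occupancy
bp = BondPairSpec(78, "NZ", 120, "OD1", p_on=0.6, k_switch=1.0)
traj = simulate_trajectory(TrajSimConfig(n_frames=2000, bond_pairs=[bp], seed=3))
occ, dist = bond_occupancy(traj, 78, 120, kind="saltbridge",
                           atoms_i=["NZ"], atoms_j=["OD1"])
print(f"salt-bridge occupancy: {occ:.3f} (3.2 A O-N cutoff, truth 0.600)")
print(
    "\nThe bound-like ensemble sits closer and more tightly packed: the\n"
    "domains approach by ~0.5 A and close by ~2.5 deg, the kind of subtle\n"
    "interdomain rearrangement that distinguishes binding-competent states."
)
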