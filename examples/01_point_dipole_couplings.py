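"""Point-dipole couplings of two parallel J-aggregate chains.

Builds the cyanine-like chain pair (0.95 nm lattice spacing, 1.5 nm chain
separation, 11.4 D dipoles along the axis) and prints the couplings that
control intra- and inter-chain energy transfer.
"""

import numpy as np

import mcfret as mc

n = 20
for slip in (0.0, 0.5):
    system = mc.build_parallel_chains(
        n_per_chain=n, spacing=0.95, chain_separation=1.5, slip=slip,
        dipole_magnitude=11.4,
    )
    J = mc.point_dipole_couplings(system)
    inter = J[n:, :n]
    strongest = inter.flat[np.abs(inter).argmax()]
    per_donor, avg = mc.coupling_sum_sq(inter)
    print(f"slip = {slip:.1f}a")
    print(f"  intra-chain nearest-neighbor coupling: {J[0, 1]:9.1f} cm^-1")
    print(f"  strongest inter-chain coupling:        {strongest:9.1f} cm^-1")
    print(f"  donor-averaged sum of squared inter-chain couplings: {avg:9.1f} cm^-2")

# The negative intra-chain coupling makes these J-aggregates (red-shifted,
# nodeless bottom exciton).  Slipping the chains by half a lattice constant
# weakens the strongest contact (193.8 -> 122.0 cm^-1) and lowers the
# pairwise-Förster reference sum by ~19%.
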