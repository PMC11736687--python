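"""Quick-look slip study for two parallel J-aggregates (reduced scale).

Computes the inter-chain transfer rate at slip 0 and 0.5a for the
small-static-disorder chain model, at a reduced scale (40 molecules per
chain, 300 sampling windows, ~30 s) so the script stays interactive.  The
full-scale study uses 200 molecules and 10,000 windows.
"""

import warnings

import numpy as np

import mcfret as mc

with warnings.catch_warnings():
    warnings.simplefilter("ignore", mc.QuadratureWarning)
    res = mc.chain_slip_study(
        sigma_static=750.0, seed=1,
        n_per_chain=40, n_windows=300, interval=200,
        slips=(0.0, 0.25, 0.5),
    )

for slip, k, g in zip(res.slips, res.rates, res.gammas):
    print(f"slip {slip:.2f}a : rate {k:7.3f} ps^-1   decoherence {g:7.1f} ps^-1")
print(f"rate reduction 0 -> 0.5a: {res.reduction_percent():.1f}%")

# The rate decreases with slip because the closest inter-chain contacts
# weaken, and the decoherence rate (hundreds of ps^-1, set by the fast
# 1500 cm^-1 / 6 fs site-energy noise) is far above the transfer rate, so
# the incoherent-rate description is internally consistent.
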