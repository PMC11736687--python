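"""Transfer rate of a weakly coupled dimer vs the analytic Förster rate.

Two resonant single-site segments with Ornstein-Uhlenbeck site-energy noise:
the time-domain rate (integral of the rate response function) must agree
with the golden-rule rate evaluated from the closed-form Kubo dephasing
function.
"""

import numpy as np

import mcfret as mc
from mcfret.constants import U_CM_FS

sigma, tau, dt, t_c, J = 300.0, 20.0, 3.0, 120.0, 10.0
n_windows, interval = 4000, 40

model = mc.DisorderModel([(sigma, tau)])
n_frames = (n_windows - 1) * interval + int(t_c / dt) + 1
energies = mc.generate_ou_trajectory(model, 2, n_frames, dt, seed=3)
traj = mc.HamiltonianTrajectory(energies, np.array([[0.0, J], [J, 0.0]]), dt)

pair = mc.segment_pair_rate(
    traj, donor_sites=[0], acceptor_sites=[1], t_c=t_c,
    thermal=mc.ThermalSpec(temperature=300.0),
    sampling=mc.SamplingSpec(n_windows, interval),
)

t = np.arange(int(t_c / dt) + 1) * dt
g = (sigma * U_CM_FS * tau) ** 2 * (np.exp(-t / tau) - 1 + t / tau)
k_analytic = 2 * (U_CM_FS * J) ** 2 * 1e3 * mc.trapezium_end_weighted(np.exp(-2 * g), dt)

print(f"simulated rate : {pair.rate.rate:.4f} ps^-1  "
      f"(trapezium {pair.rate.trapezium:.4f}, Simpson {pair.rate.simpson:.4f})")
print(f"analytic rate  : {k_analytic:.4f} ps^-1")
print(f"decoherence    : {pair.gamma:.1f} ps^-1")

# The two rates agree within Monte-Carlo error (~1% at 4000 windows).  The
# decoherence rate (inverse persistence time of the rate response) far
# exceeds the transfer rate, so treating this transfer as incoherent is safe.
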