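# Quickstart config for the command-line workflow:
#   mcfret run --config examples/dimer.cfg --out mcfret_out
# Two weakly coupled single-site segments with OU site-energy noise.
system = chains
n_per_chain = 1
separation = 1.5
dipole = 2.5
sigma_dyn = 300
tau_dyn = 20
n_frames = 80030
dt = 3
t_c = 120
temperature = 300
n_samples = 2000
interval = 40
epsilon_p = 0.4
seed = 7
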