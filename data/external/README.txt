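Optional external validation inputs
===================================

The FMO and B850 validation tests in tests/test_acceptance.py run only when
the corresponding input files are placed in this directory; they are skipped
otherwise.  These inputs come from published parameter sets that are not
redistributed with the package:

fmo_hamiltonian.txt   7x7 FMO site Hamiltonian (cm^-1): site energies on the
                      diagonal, resonance couplings off-diagonal.
fmo_bath.txt          two numbers: sigma (cm^-1) and tau (fs) of the
                      overdamped-Brownian-oscillator site-energy disorder.
b850_couplings_75A.txt
                      36x36 coupling matrix (cm^-1, screening included) for
                      two B850 rings at 75 A center-to-center distance;
                      sites 1-18 donor ring, 19-36 acceptor ring (site
                      energies on the diagonal are ignored; the B850 mean
                      transition energy 11955 cm^-1 is used).
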