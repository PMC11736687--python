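"""Physical constants and unit conventions.

The package works in the spectroscopist's mixed unit system: energies and
couplings in wavenumbers (cm^-1), time in femtoseconds, distances in
nanometres, transition dipoles in Debye, and rates in ps^-1.  A frequency
``w`` in cm^-1 corresponds to an angular phase velocity ``U_CM_FS * w`` in
rad/fs, which is the only conversion the dynamics ever needs.
"""

import math

#: Speed of light in cm/fs (CODATA).
C_CM_FS = 2.99792458e-5

#: Angular-frequency conversion, rad fs^-1 per cm^-1:  u = 2*pi*c.
U_CM_FS = 2.0 * math.pi * C_CM_FS  # = 1.883652e-4

#: Boltzmann constant in cm^-1 / K.
KB_CM = 0.6950348

#: Point-dipole coupling constant in cm^-1 Angstrom^3 / Debye^2.
#: J = C * kappa * |mu1||mu2| / r^3 with r in Angstrom and mu in Debye.
DIPOLE_COUPLING_CM_A3_D2 = 5034.12

#: Nanometre -> Angstrom.
NM_TO_ANGSTROM = 10.0

#: fs^-1 -> ps^-1.
FS_INV_TO_PS_INV = 1.0e3
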