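"""Physical constants and unit conversions used across the package.

Unit policy: wavelengths in nm, distances in nm, time in ps (trajectories)
or ns (fluorescence decays), molar absorptivity in L mol^-1 cm^-1 (M^-1 cm^-1),
overlap integrals in nm^4 M^-1 cm^-1.  All conversions live here.
"""

import numpy as np

#: Avogadro constant, mol^-1
N_AVOGADRO = 6.02214076e23

#: ln(10), for Beer-Lambert / Forster prefactors
LN10 = float(np.log(10.0))

#: Forster prefactor 9000 ln10 / (128 pi^5 N_A), mol.  The factor 9000
#: contains the litre -> cm^3 conversion of the molar absorptivity.
FORSTER_PREFACTOR = 9000.0 * LN10 / (128.0 * np.pi**5 * N_AVOGADRO)

#: nm^4 -> cm^4 (J is supplied in nm^4 M^-1 cm^-1; the closed form wants cm)
NM4_TO_CM4 = 1e-28

#: cm -> nm
CM_TO_NM = 1e7

#: nm -> angstrom
NM_TO_ANGSTROM = 10.0
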