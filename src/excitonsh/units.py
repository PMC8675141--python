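"""Physical constants and unit conversions.

Internally everything is in Hartree atomic units (hartree, bohr, electron
mass, au of time).  User-facing interfaces (config files, CLI, tables)
speak eV, angstrom and femtoseconds; conversion happens once at the
boundary.
"""

HARTREE_TO_EV = 27.211386245988
EV_TO_HARTREE = 1.0 / HARTREE_TO_EV

BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

AU_TIME_FS = 0.02418884326586  # one atomic unit of time in fs
FS_TO_AU = 1.0 / AU_TIME_FS

KB_HARTREE = 3.166811563e-6  # Boltzmann constant, hartree / K

AMU_TO_AU = 1822.888486209  # atomic mass unit in electron masses
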