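"""Physical constants and the internal unit system.

Internal units throughout the package:

========  =========
quantity  unit
========  =========
length    angstrom
time      picosecond
mass      atomic mass unit (amu)
energy    kJ/mol
charge    elementary charge
========  =========

One kJ/mol equals 100 amu Å²/ps², so forces in kJ/mol/Å are converted to
accelerations with :data:`KJ_PER_MOL_TO_MD`.  All unit conversions live here;
no other module hard-codes a physical constant.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass(frozen=True)
class PhysicalConstants:
    """SI constants entering the Debye screening length.

    ``relative_permittivity`` is the dielectric constant of water at room
    temperature and is deliberately held fixed at all simulation
    temperatures: the implicit-solvent electrolyte is parameterized at
    ambient conditions and only the explicit ``T`` in the screening formula
    carries the temperature dependence.
    """

    vacuum_permittivity: float = 8.8541878128e-12  # F/m
    relative_permittivity: float = 78.3            # water, 298 K
    gas_constant: float = 8.314462618              # J/(mol K)
    avogadro: float = 6.02214076e23                # 1/mol
    elementary_charge: float = 1.602176634e-19     # C
    boltzmann: float = 1.380649e-23                # J/K

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"constant {f.name} must be positive")


DEFAULT_CONSTANTS = PhysicalConstants()

#: Boltzmann constant in internal energy units, kJ/(mol K).
KB = 8.314462618e-3

#: e^2 N_A / (4 pi eps0) in kJ Å / mol; divide by relative permittivity and
#: the separation in Å to obtain a Coulomb pair energy in kJ/mol.
COULOMB_KJ_A = 1389.35457644382

#: 1 kJ/mol expressed in amu Å²/ps².
KJ_PER_MOL_TO_MD = 100.0

#: 1 amu Å²/ps² expressed in kJ/mol.
MD_TO_KJ_PER_MOL = 0.01

#: Equilibration temperature ("room temperature") in K.
ROOM_TEMPERATURE = 298.0
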