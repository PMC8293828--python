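"""Physical constants in the wavenumber/femtosecond unit system.

All energies (site energies, couplings, reorganization energies, bath
relaxation rates) are expressed in cm^-1 and times in fs, the conventional
units for exciton dynamics in molecular aggregates.  Rates appearing in
equations of motion are obtained by dividing an energy by ``hbar``.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants: ``hbar`` in cm^-1 fs, ``k_B`` in cm^-1/K."""

    hbar: float = 5308.837
    k_B: float = 0.695035


CONST = PhysicalConstants()

HBAR = CONST.hbar
KB = CONST.k_B
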