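"""Physical constants in the CGS-Gaussian unit system.

All magnetics in this package are expressed in CGS-Gaussian units
(fields in Oe, magnetic moments in emu = erg/G, energies in erg),
with aggregate moments quoted in Bohr magnetons and anisotropy
energies in Kelvin, matching the conventions of magnetometry work
on nanoparticle ensembles.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable CGS-Gaussian constants used throughout the package."""

    #: Bohr magneton (emu)
    mu_B: float = 9.274e-21
    #: Boltzmann constant (erg/K)
    k_B: float = 1.3807e-16
    #: gyromagnetic ratio (rad s^-1 Oe^-1)
    gamma: float = 1.76e7


CONST = PhysicalConstants()
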