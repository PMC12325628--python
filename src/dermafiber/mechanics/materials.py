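"""Material parameters in the um-uN-MPa unit system."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MaterialParams:
    """Dermal-matrix and elastin-fiber elastic constants.

    The matrix is a near-incompressible Saint Venant-Kirchhoff solid
    (E = 80 kPa, nu = 0.48); fibers are linear-elastic beams (E = 0.5 MPa).
    The fiber Poisson ratio only enters the torsional shear modulus.
    """

    E_matrix: float = 0.08  # MPa (80 kPa)
    nu: float = 0.48
    E_fiber: float = 0.5  # MPa
    nu_fiber: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 < self.nu < 0.5):
            raise ValueError("matrix Poisson ratio must be in (0, 0.5)")
        if self.E_matrix <= 0 or self.E_fiber <= 0:
            raise ValueError("elastic moduli must be positive")

    @property
    def lam(self) -> float:
        """First Lame parameter of the matrix (MPa)."""
        return self.E_matrix * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))

    @property
    def mu(self) -> float:
        """Shear modulus of the matrix (MPa)."""
        return self.E_matrix / (2 * (1 + self.nu))

    @property
    def G_fiber(self) -> float:
        """Shear modulus of the fiber material (MPa)."""
        return self.E_fiber / (2 * (1 + self.nu_fiber))
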