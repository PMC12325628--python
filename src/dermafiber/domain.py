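"""Physical domain description shared by all pipeline stages.

The model coordinate frame follows the imaging convention: Y is the skin
surface normal (the compression axis), X and Z span the horizontal plane.
All lengths are micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Standardized cross-section of the dermal box model (X times Z, um).
DEFAULT_SIZE_X = 343.57
DEFAULT_SIZE_Z = 99.75


@dataclass(frozen=True)
class DomainSpec:
    """Rectangular dermal-matrix domain.

    Parameters
    ----------
    size_x, size_y, size_z:
        Edge lengths in micrometres. ``size_y`` is the height along the
        surface normal / compression axis.
    """

    size_x: float
    size_y: float
    size_z: float

    def __post_init__(self) -> None:
        if not (self.size_x > 0 and self.size_y > 0 and self.size_z > 0):
            raise ValueError("all domain sizes must be positive")

    @property
    def sizes(self) -> np.ndarray:
        return np.array([self.size_x, self.size_y, self.size_z], dtype=float)

    @property
    def volume(self) -> float:
        """Domain volume in um^3."""
        return float(self.size_x * self.size_y * self.size_z)

    @classmethod
    def standard(cls, height: float = 150.0) -> "DomainSpec":
        """The standardized box: 343.57 x 99.75 um^2 cross-section, given height."""
        return cls(DEFAULT_SIZE_X, height, DEFAULT_SIZE_Z)
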