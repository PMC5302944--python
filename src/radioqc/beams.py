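"""Beam-quality descriptors."""

from __future__ import annotations

import math
from dataclasses import dataclass

SPECIES = ("photon", "proton", "helium", "carbon", "oxygen")


@dataclass(frozen=True)
class BeamQuality:
    """A radiation quality: particle species, dose-averaged LET and fluence.

    Parameters
    ----------
    species:
        One of ``photon``, ``proton``, ``helium``, ``carbon``, ``oxygen``.
    let_d:
        Dose-averaged linear energy transfer in keV/um. ``None`` for photons
        (LET is not a meaningful single number for a photon field here).
    fluence:
        Planned particle fluence in particles/cm^2, or ``None`` when not
        applicable (photons) or not planned.
    """

    species: str
    let_d: float | None = None
    fluence: float | None = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}; expected one of {SPECIES}")
        if self.let_d is not None:
            if not math.isfinite(self.let_d) or self.let_d <= 0:
                raise ValueError("let_d must be finite and > 0 when given")
        if self.fluence is not None:
            if not math.isfinite(self.fluence) or self.fluence < 0:
                raise ValueError("fluence must be finite and >= 0 when given")

    @property
    def is_ion(self) -> bool:
        return self.species != "photon"


# Clinical mid-SOBP qualities studied in the reference experiment: dose-averaged
# LET (keV/um) for the two high-LET beams and total planned fluences at 0.25 Gy.
CARBON_MID_SOBP = BeamQuality("carbon", let_d=95.2, fluence=3.8e6)
OXYGEN_MID_SOBP = BeamQuality("oxygen", let_d=143.5, fluence=2.8e6)
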