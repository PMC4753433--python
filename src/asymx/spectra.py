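"""Isotope-spectrum container and centroiding."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PROTON_MASS", "DEUTERIUM_STEP", "IsotopeSpectrum", "spectrum_centroid"]

PROTON_MASS = 1.007276466622  # Da
DEUTERIUM_STEP = 1.00628  # Da, mass increment per incorporated deuterium


@dataclass
class IsotopeSpectrum:
    """m/z-intensity stick list for one peptide x state x exposure time.

    Intensities are normalized to max = 1 on construction; peaks are stored
    sorted by m/z.
    """

    peptide_id: str
    state: str
    time_s: float
    charge: int
    peaks: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")
        if not self.peaks:
            raise ValueError("spectrum has no peaks")
        mz = np.array([p[0] for p in self.peaks], dtype=float)
        inten = np.array([p[1] for p in self.peaks], dtype=float)
        if np.any(inten < 0):
            raise ValueError("negative intensity")
        top = inten.max()
        if top <= 0:
            raise ValueError("all intensities are zero")
        order = np.argsort(mz)
        self.peaks = [(float(m), float(i / top))
                      for m, i in zip(mz[order], inten[order])]

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])


def spectrum_centroid(s: IsotopeSpectrum) -> float:
    """Intensity-weighted mean m/z converted to the neutral centroid mass (Da).

    neutral = z * (mean m/z - proton mass).
    """
    mz, inten = s.mz, s.intensities
    total = inten.sum()
    if total <= 0:
        raise ValueError("all-zero intensities")
    mean_mz = float(np.dot(mz, inten) / total)
    return s.charge * (mean_mz - PROTON_MASS)
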