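"""Uniform energy grids for spectra and pulse-height distributions.

HPGe acquisition systems in this energy range record pulse heights in
narrow uniform bins (80 eV here), and every downstream object — measured
pulse-height distributions, detector response matrices, stripped photon
spectra — lives on the same grid.  The grid is therefore a small frozen
value type shared across modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EnergyGrid", "DEFAULT_GRID"]


@dataclass(frozen=True)
class EnergyGrid:
    """Uniform energy binning in keV.

    Parameters
    ----------
    e_min, e_max:
        Lower edge of the first bin and upper edge of the last bin, keV.
    bin_width:
        Bin width in keV.  Default 0.08 (80 eV), typical of HPGe
        multichannel analyzers at these energies.
    """

    e_min: float = 0.0
    e_max: float = 60.0
    bin_width: float = 0.08

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.e_max <= self.e_min:
            raise ValueError("e_max must exceed e_min")
        n = (self.e_max - self.e_min) / self.bin_width
        if abs(n - round(n)) > 1e-6:
            raise ValueError("grid span must be an integer number of bins")

    @property
    def n_bins(self) -> int:
        return int(round((self.e_max - self.e_min) / self.bin_width))

    @property
    def centers(self) -> np.ndarray:
        """Bin-center energies, keV."""
        return self.e_min + (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def edges(self) -> np.ndarray:
        return self.e_min + np.arange(self.n_bins + 1) * self.bin_width

    def index_of(self, energy: float) -> int:
        """Index of the bin containing ``energy``."""
        if not (self.e_min <= energy <= self.e_max):
            raise ValueError(f"energy {energy} keV outside grid "
                             f"[{self.e_min}, {self.e_max}] keV")
        i = int((energy - self.e_min) / self.bin_width)
        return min(i, self.n_bins - 1)

    def compatible(self, other: "EnergyGrid") -> bool:
        return (abs(self.e_min - other.e_min) < 1e-9
                and abs(self.e_max - other.e_max) < 1e-9
                and abs(self.bin_width - other.bin_width) < 1e-12)


#: Default acquisition grid: 80 eV bins from 0 to 60 keV (750 bins).
DEFAULT_GRID = EnergyGrid(0.0, 60.0, 0.08)
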