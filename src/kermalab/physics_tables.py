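"""Photon interaction-coefficient tables and interpolation.

Every spectrum integral in the air-kerma chain — the kerma integral, the
in-chamber attenuation correction, the humidity correction — is driven by
mass attenuation coefficients ``μ/ρ`` and mass energy-transfer
coefficients ``μ_tr/ρ`` of dry air (and of water vapor for humid-air
mixtures, and of germanium for the detector response).  This module holds
the table container, log-log interpolation, and the mass-fraction mixing
rule for humid air.

Two photoelectric-cross-section treatments circulate in the reference
data for this energy range: the *unrenormalized* Hartree-Slater results
used by current XCOM-class compilations, and the *renormalized*
(Hartree-Fock-corrected) results favored by recent synchrotron
measurements on air.  Tables carry a ``variant`` flag so either can be
selected consistently; mixing tables of different variants is an error.

Packaged fixture tables (dry air, water vapor, germanium; 0.5 keV grid,
5–60 keV, both variants) are generated once by
``scripts/generate_reference_tables.py`` and shipped as CSV files with a
JSON provenance sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoefficientTable",
    "interpolate_coefficient",
    "mix_coefficients",
    "load_coefficient_table",
]

_VARIANTS = ("unrenormalized", "renormalized")


@dataclass
class CoefficientTable:
    """Mass attenuation / energy-transfer coefficients vs energy.

    Attributes
    ----------
    material:
        Label, e.g. ``"dry air"``.
    energies:
        Strictly increasing grid, keV.
    mu_rho:
        Mass attenuation coefficient μ/ρ, cm²/g.
    mu_tr_rho:
        Mass energy-transfer coefficient μ_tr/ρ, cm²/g.
    variant:
        Photoelectric treatment, ``"unrenormalized"`` or ``"renormalized"``.
    """

    material: str
    energies: np.ndarray
    mu_rho: np.ndarray
    mu_tr_rho: np.ndarray
    variant: str = "unrenormalized"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.mu_rho = np.asarray(self.mu_rho, dtype=float)
        self.mu_tr_rho = np.asarray(self.mu_tr_rho, dtype=float)
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.energies.ndim != 1 or len(self.energies) < 2:
            raise ValueError("need at least two grid energies")
        if not np.all(np.diff(self.energies) > 0):
            raise ValueError("energies must be strictly increasing")
        for name, arr in (("mu_rho", self.mu_rho),
                          ("mu_tr_rho", self.mu_tr_rho)):
            if arr.shape != self.energies.shape:
                raise ValueError(f"{name} shape mismatch")
            if not np.all(arr > 0):
                raise ValueError(f"{name} must be positive everywhere")
        if np.any(self.mu_tr_rho > self.mu_rho * (1 + 1e-12)):
            raise ValueError("mu_tr_rho must not exceed mu_rho")

    # -- interpolation ---------------------------------------------------
    def _interp(self, energy, values: np.ndarray) -> np.ndarray:
        e = np.asarray(energy, dtype=float)
        if np.any(e < self.energies[0]) or np.any(e > self.energies[-1]):
            raise ValueError(
                f"energy outside table range "
                f"[{self.energies[0]}, {self.energies[-1]}] keV for "
                f"{self.material!r}")
        out = np.exp(np.interp(np.log(e), np.log(self.energies),
                               np.log(values)))
        return out if out.shape else float(out)

    def mu_rho_at(self, energy):
        """μ/ρ at ``energy`` (keV) by log-log interpolation, cm²/g."""
        return self._interp(energy, self.mu_rho)

    def mu_tr_rho_at(self, energy):
        """μ_tr/ρ at ``energy`` (keV) by log-log interpolation, cm²/g."""
        return self._interp(energy, self.mu_tr_rho)


def interpolate_coefficient(table: CoefficientTable, energy,
                            which: str = "mu_rho"):
    """Log-log interpolate a coefficient; exact at grid nodes.

    ``which`` is ``"mu_rho"`` or ``"mu_tr_rho"``.  Energies outside the
    table range raise ``ValueError`` (no silent extrapolation).
    """
    if which == "mu_rho":
        return table.mu_rho_at(energy)
    if which == "mu_tr_rho":
        return table.mu_tr_rho_at(energy)
    raise ValueError(f"unknown coefficient {which!r}")


def mix_coefficients(
    components: Sequence[tuple[CoefficientTable, float]],
) -> CoefficientTable:
    """Mass-fraction-weighted mixture of coefficient tables.

    Photon mass coefficients obey simple additivity over constituent mass
    fractions, which is how a humid-air table is assembled from dry air
    plus water vapor.  All components must share the photoelectric
    variant; fractions must be non-negative and sum to 1 within 1e-9.
    The mixture is evaluated on the union of the component energy grids
    restricted to their common range.
    """
    if not components:
        raise ValueError("no components given")
    tables = [t for t, _ in components]
    fracs = np.array([f for _, f in components], dtype=float)
    if np.any(fracs < 0):
        raise ValueError("mass fractions must be non-negative")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"mass fractions sum to {fracs.sum()}, not 1")
    variants = {t.variant for t in tables}
    if len(variants) > 1:
        raise ValueError(f"mismatched variants {sorted(variants)}")

    lo = max(t.energies[0] for t in tables)
    hi = min(t.energies[-1] for t in tables)
    grid = np.unique(np.concatenate([t.energies for t in tables]))
    grid = grid[(grid >= lo) & (grid <= hi)]

    mu = np.zeros_like(grid)
    mutr = np.zeros_like(grid)
    for t, f in components:
        mu += f * t.mu_rho_at(grid)
        mutr += f * t.mu_tr_rho_at(grid)
    label = " + ".join(f"{f:g}*{t.material}" for t, f in components)
    return CoefficientTable(material=label, energies=grid, mu_rho=mu,
                            mu_tr_rho=mutr, variant=tables[0].variant)


# -- packaged fixture tables ----------------------------------------------

def _data_root():
    return resources.files("kermalab") / "data"


def load_coefficient_table(material: str,
                           variant: str = "renormalized") -> CoefficientTable:
    """Load a packaged coefficient table.

    ``material`` is one of ``"dry_air"``, ``"water_vapor"``,
    ``"germanium"``; ``variant`` selects the photoelectric treatment.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    stem = f"{material}_{variant}"
    root = _data_root()
    csv_path = root / f"{stem}.csv"
    try:
        df = pd.read_csv(csv_path.open("r"))
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"no packaged table {stem!r}") from exc
    meta = json.loads((root / f"{stem}.json").read_text())
    return CoefficientTable(
        material=meta.get("material", material),
        energies=df["energy_keV"].to_numpy(),
        mu_rho=df["mu_rho"].to_numpy(),
        mu_tr_rho=df["mu_tr_rho"].to_numpy(),
        variant=variant,
        provenance=meta,
    )
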