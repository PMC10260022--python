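"""Intratumoral concentrations from tissue amounts and tumor density.

Tumor volume is approximated as an ellipsoid from caliper semi-axes,
density is mass over that volume, and amount-per-mass measurements
(pmol/mg) convert to µM because 1 pmol/mm³ = 1 pmol/µL = 1 µM. The
denominator is whole-tissue volume (water plus solid); no intracellular /
extracellular partitioning is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TumorGeometry",
    "TissueAmount",
    "ellipsoid_volume",
    "tumor_density",
    "intratumoral_concentration",
    "compare_if_vs_tumor",
]


@dataclass(frozen=True)
class TumorGeometry:
    """Caliper semi-axes (mm) and mass (mg) of one tumor.

    Measurements are taken as semi-axes; pass ``diameters=True`` to convert
    caliper diameters (halved on construction).
    """

    a_mm: float
    b_mm: float
    c_mm: float
    mass_mg: float

    def __post_init__(self) -> None:
        if min(self.a_mm, self.b_mm, self.c_mm, self.mass_mg) <= 0:
            raise ValueError("semi-axes and mass must all be positive")

    @classmethod
    def from_calipers(
        cls, a: float, b: float, c: float, mass_mg: float, diameters: bool = False
    ) -> "TumorGeometry":
        s = 0.5 if diameters else 1.0
        return cls(a * s, b * s, c * s, mass_mg)


@dataclass(frozen=True)
class TissueAmount:
    """Metabolite amount normalized to extracted tissue mass."""

    metabolite: str
    amount_pmol_per_mg: float
    extracted_mass_mg: float = float("nan")

    def __post_init__(self) -> None:
        if self.amount_pmol_per_mg < 0:
            raise ValueError("amount per mass must be nonnegative")


def ellipsoid_volume(g: TumorGeometry) -> float:
    """V = 4/3 · π · A · B · C, in mm³."""
    return (4.0 / 3.0) * math.pi * g.a_mm * g.b_mm * g.c_mm


def tumor_density(g: TumorGeometry) -> float:
    """Tumor mass divided by ellipsoid volume, mg/mm³."""
    return g.mass_mg / ellipsoid_volume(g)


def intratumoral_concentration(a: TissueAmount, density_mg_per_mm3: float) -> float:
    """amount (pmol/mg) × density (mg/mm³) = pmol/mm³ = µM."""
    if density_mg_per_mm3 <= 0:
        raise ValueError("density must be positive")
    return a.amount_pmol_per_mg * density_mg_per_mm3


def compare_if_vs_tumor(
    if_conc: Mapping[str, Sequence[float]],
    tumor_conc: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Per-metabolite tumor/IF concentration ratio with a two-tailed t test.

    Inputs map metabolite -> replicate concentrations (µM). With fewer than
    two replicates in either group the ratio is still reported but the
    statistic is withheld (NaN) with a note, since no degrees of freedom
    remain for a t test.
    """
    shared = sorted(set(if_conc) & set(tumor_conc))
    if not shared:
        raise ValueError("no shared metabolites between IF and tumor tables")
    rows = []
    for met in shared:
        x = np.asarray(tumor_conc[met], dtype=float)
        y = np.asarray(if_conc[met], dtype=float)
        ratio = float(x.mean() / y.mean())
        if x.size >= 2 and y.size >= 2:
            res = stats.ttest_ind(x, y)
            t_stat, p, note = float(res.statistic), float(res.pvalue), ""
        else:
            t_stat, p = float("nan"), float("nan")
            note = "statistic withheld: fewer than two replicates in a group"
        rows.append(
            {
                "metabolite": met,
                "tumor_mean_uM": float(x.mean()),
                "if_mean_uM": float(y.mean()),
                "tumor_over_if": ratio,
                "t": t_stat,
                "p_two_tailed": p,
                "n_tumor": int(x.size),
                "n_if": int(y.size),
                "note": note,
            }
        )
    df = pd.DataFrame(rows).sort_values("tumor_over_if", ascending=False, ignore_index=True)
    return df
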