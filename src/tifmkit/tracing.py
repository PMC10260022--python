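"""Stable-isotope tracer analysis.

Builds theoretical natural-abundance convolution matrices from elemental
formulas, deconvolves measured isotopologue intensities into tracer-derived
mass-isotopomer distributions (MIDs), and compares tracer enrichment between
compartments (e.g. tumor tissue vs plasma) with paired statistics.

The correction model: the detector observes, for a species carrying exactly
``j`` tracer atoms, a mass-shift spectrum given by convolving the natural
isotope distributions of every atom that is *not* occupied by tracer label.
Stacking those spectra as columns gives a lower-triangular matrix ``M`` such
that ``measured = M @ true_mid``. The true MID is recovered by nonnegative
least squares and renormalized to a probability vector.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ElementalFormula",
    "IsotopologueVector",
    "AbundanceTable",
    "load_abundance_table",
    "build_correction_matrix",
    "correct_natural_abundance",
    "labeled_fraction",
    "excess_enrichment",
    "synthesis_fraction_from_precursor",
]

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Elemental composition of a metabolite plus its tracer configuration.

    Parameters
    ----------
    counts
        Mapping element symbol -> atom count (e.g. ``{"C": 6, "H": 14, ...}``).
    tracer_element
        The element carrying the isotopic label ("C" for 13C, "N" for 15N).
    max_tracer_atoms
        Highest isotopologue index tracked, M+0..M+max. May be lower than the
        atom count of the tracer element when the tracer can only transfer a
        limited number of atoms (e.g. 13C5-citrulline labels at most five of
        argininosuccinate's carbons).
    """

    counts: Mapping[str, int]
    tracer_element: str = "C"
    max_tracer_atoms: int | None = None

    def __post_init__(self) -> None:
        counts = dict(self.counts)
        if any(v < 0 for v in counts.values()):
            raise ValueError("atom counts must be nonnegative")
        if self.tracer_element not in counts:
            raise ValueError(
                f"tracer element {self.tracer_element!r} absent from formula"
            )
        n_max = counts[self.tracer_element]
        m = self.max_tracer_atoms
        if m is None:
            object.__setattr__(self, "max_tracer_atoms", n_max)
        elif not 0 <= m <= n_max:
            raise ValueError(
                f"max_tracer_atoms={m} exceeds {self.tracer_element} count {n_max}"
            )
        object.__setattr__(self, "counts", counts)

    @classmethod
    def parse(
        cls,
        formula: str,
        tracer_element: str = "C",
        max_tracer_atoms: int | None = None,
    ) -> "ElementalFormula":
        """Parse a Hill-notation formula string such as ``"C10H18N4O6"``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_RE.finditer(formula):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = match.end()
            counts[match.group(1)] = counts.get(match.group(1), 0) + int(
                match.group(2) or 1
            )
        if pos != len(formula) or not counts:
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(counts, tracer_element, max_tracer_atoms)


@dataclass
class IsotopologueVector:
    """Fractional abundances of one metabolite's isotopologues M+0..M+n."""

    metabolite: str
    values: np.ndarray
    corrected: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a nonempty 1-D vector")
        if np.any(self.values < -1e-12):
            raise ValueError("isotopologue fractions must be nonnegative")

    @property
    def n_shifts(self) -> int:
        return self.values.size - 1

    def normalized(self) -> "IsotopologueVector":
        total = float(self.values.sum())
        if total <= 0:
            raise ValueError(f"all-zero isotopologue vector for {self.metabolite}")
        return replace(self, values=self.values / total)


class AbundanceTable:
    """Per-element natural isotope abundances indexed by nominal mass shift."""

    def __init__(self, elements: Mapping[str, Sequence[float]], version: str):
        self.version = version
        self._dist: dict[str, np.ndarray] = {}
        for el, probs in elements.items():
            arr = np.asarray(probs, dtype=float)
            if np.any(arr < 0) or not np.isclose(arr.sum(), 1.0, atol=1e-6):
                raise ValueError(
                    f"abundances for element {el!r} must be nonnegative and sum to 1"
                )
            self._dist[el] = arr / arr.sum()

    def distribution(self, element: str) -> np.ndarray:
        try:
            return self._dist[element]
        except KeyError:
            raise KeyError(f"no natural-abundance data for element {element!r}")

    def __contains__(self, element: str) -> bool:
        return element in self._dist


def load_abundance_table() -> AbundanceTable:
    """Load the packaged natural-abundance table (version recorded on it)."""
    text = (
        resources.files("tifmkit.data").joinpath("isotope_abundances.json").read_text()
    )
    payload = json.loads(text)
    return AbundanceTable(payload["elements"], payload["version"])


def _self_convolve(dist: np.ndarray, n_atoms: int, max_shift: int) -> np.ndarray:
    """Mass-shift spectrum of ``n_atoms`` i.i.d. atoms, truncated at max_shift."""
    out = np.zeros(max_shift + 1)
    out[0] = 1.0
    for _ in range(n_atoms):
        out = np.convolve(out, dist)[: max_shift + 1]
    return out


def build_correction_matrix(
    formula: ElementalFormula,
    abundances: AbundanceTable | None = None,
    tracer_only: bool = False,
) -> np.ndarray:
    """Natural-abundance convolution matrix for a labeled metabolite.

    Column ``j`` is the theoretical mass-shift spectrum (truncated to
    M+0..M+n) of the species carrying exactly ``j`` tracer atoms; labeled
    positions are excluded from the natural-abundance draw. With
    ``tracer_only=True`` non-tracer elements are ignored (correction on the
    tracer element alone).
    """
    if abundances is None:
        abundances = load_abundance_table()
    n = int(formula.max_tracer_atoms)
    n_tracer = formula.counts[formula.tracer_element]
    tracer_dist = abundances.distribution(formula.tracer_element)

    base = np.zeros(n + 1)
    base[0] = 1.0
    if not tracer_only:
        for el, count in formula.counts.items():
            if el == formula.tracer_element or count == 0:
                continue
            base = np.convolve(base, _self_convolve(abundances.distribution(el), count, n))[
                : n + 1
            ]

    matrix = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        unlabeled_atoms = n_tracer - j
        spectrum = np.convolve(
            base, _self_convolve(tracer_dist, unlabeled_atoms, n)
        )[: n + 1]
        matrix[j:, j] = spectrum[: n + 1 - j]
    return matrix


def correct_natural_abundance(
    raw: IsotopologueVector,
    matrix: np.ndarray,
    nonnegative: bool = True,
) -> IsotopologueVector:
    """Deconvolve natural isotope abundance out of a measured MID.

    Solves ``matrix @ x = raw`` under ``x >= 0`` (nonnegative least squares;
    set ``nonnegative=False`` for a diagnostic unconstrained solve), then
    normalizes ``x`` to sum to one.
    """
    y = np.asarray(raw.values, dtype=float)
    if not np.any(y > 0):
        raise ValueError(f"all-zero isotopologue vector for {raw.metabolite}")
    if matrix.shape != (y.size, y.size):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match MID length {y.size}"
        )
    if nonnegative:
        x, _ = optimize.nnls(matrix, y)
    else:
        x = np.linalg.solve(matrix, y)
    total = x.sum()
    if total <= 0:
        raise ValueError("correction produced a degenerate (all-zero) MID")
    meta = dict(raw.metadata)
    meta.setdefault("correction", "nnls" if nonnegative else "unconstrained")
    return IsotopologueVector(
        metabolite=raw.metabolite, values=x / total, corrected=True, metadata=meta
    )


def labeled_fraction(mid: IsotopologueVector) -> float:
    """Fraction of the pool carrying any tracer label: 1 - M+0.

    Refuses uncorrected input so that natural-abundance correction is always
    an explicit, recorded step.
    """
    if not mid.corrected:
        raise ValueError(
            "labeled_fraction requires a natural-abundance-corrected MID; "
            "run correct_natural_abundance first"
        )
    values = mid.normalized().values
    return float(1.0 - values[0])


def synthesis_fraction_from_precursor(
    mid: IsotopologueVector,
    diagnostic_shift: int,
    steady_state: bool = True,
) -> float:
    """Fraction of a pool carrying the tracer-diagnostic mass shift.

    With a fully labeled precursor at isotopic steady state this equals the
    fraction of the pool synthesized de novo during the labeling window.
    For non-steady-state (e.g. bolus-injection) data that inference is not
    valid and the call is refused.
    """
    if not steady_state:
        raise ValueError(
            "synthesis fraction is undefined for non-steady-state labeling; "
            "use excess_enrichment to compare enrichment instead"
        )
    if not mid.corrected:
        raise ValueError("synthesis fraction requires a corrected MID")
    values = mid.normalized().values
    if not 0 <= diagnostic_shift < values.size:
        raise ValueError(
            f"diagnostic shift +{diagnostic_shift} exceeds MID capacity "
            f"M+{values.size - 1}"
        )
    return float(values[diagnostic_shift])


def excess_enrichment(
    tissue: Mapping[str, IsotopologueVector],
    plasma: Mapping[str, IsotopologueVector],
) -> pd.DataFrame:
    """Per-isotopologue paired tissue-minus-plasma differences.

    Animals are paired by id. For each isotopologue index the mean paired
    difference, the paired t statistic and a one-tailed p-value (testing
    tissue > plasma, n-1 degrees of freedom) are reported. A zero-variance
    positive difference underflows to the smallest positive float rather
    than reporting p = 0.
    """
    tissue_ids, plasma_ids = set(tissue), set(plasma)
    if tissue_ids != plasma_ids:
        mism = sorted(tissue_ids.symmetric_difference(plasma_ids))
        raise ValueError(f"unpaired animal ids: {mism}")
    ids = sorted(tissue_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("paired comparison requires at least two animals")
    lengths = {tissue[i].values.size for i in ids} | {plasma[i].values.size for i in ids}
    if len(lengths) != 1:
        raise ValueError("all MIDs must have the same number of isotopologues")

    t_mat = np.vstack([tissue[i].normalized().values for i in ids])
    p_mat = np.vstack([plasma[i].normalized().values for i in ids])
    diffs = t_mat - p_mat

    rows = []
    tiny = float(np.finfo(float).tiny)
    for k in range(diffs.shape[1]):
        d = diffs[:, k]
        mean = float(d.mean())
        sd = float(d.std(ddof=1))
        if sd == 0.0:
            if mean > 0:
                t_stat, p = np.inf, tiny
            elif mean < 0:
                t_stat, p = -np.inf, 1.0
            else:
                t_stat, p = 0.0, 0.5
        else:
            t_stat = mean / (sd / np.sqrt(n))
            p = float(stats.t.sf(t_stat, df=n - 1))
            p = max(p, tiny)
        rows.append(
            {
                "isotopologue": k,
                "mean_difference": mean,
                "sd_difference": sd,
                "t": t_stat,
                "p_one_tailed": p,
                "n_pairs": n,
            }
        )
    return pd.DataFrame(rows)
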