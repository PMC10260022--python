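"""Interstitial-fluid-matched medium formulation.

Builds a culture-medium recipe from interstitial-fluid (IF) metabolite
measurements: candidate nutrients are filtered on commercial availability,
aqueous stability and an IF concentration strictly above a threshold
(default 0.5 µM); the recipe is organised into ten separately compounded
pools; electrolytes are balanced against a reference medium (RPMI-1640 by
default) accounting for counter-ions of ionic components and serum salt;
and a compounded batch is verified against the intended recipe by Pearson
correlation of measured vs expected concentrations.

The packaged formulation table is a synthetic stand-in for the published
recipe (see ``data/tifm_formulation_synthetic.tsv``): component count (115),
pool count (10) and the anchor concentrations (citrulline 67 µM, arginine
2 µM) are faithful; the remaining entries are representative IF-scale values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from io import StringIO
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetaboliteSpec",
    "MediumFormulation",
    "IonBalance",
    "BalanceResult",
    "FidelityReport",
    "select_components",
    "balance_electrolytes",
    "verify_formulation",
    "validate_pools",
    "load_packaged_formulation",
    "load_rpmi_ion_reference",
    "load_counterion_map",
]

DEFAULT_THRESHOLD_UM = 0.5  # strict '>' per the selection rule
N_POOLS = 10
BALANCE_TOL_MM = 1e-9


@dataclass(frozen=True)
class MetaboliteSpec:
    """One IF-measured nutrient considered for inclusion in the medium."""

    name: str
    if_concentration: float  # µM, mean across tumors
    commercially_available: bool = True
    aqueous_stable: bool = True
    pool_id: int | None = None

    def __post_init__(self) -> None:
        if self.if_concentration < 0:
            raise ValueError(f"{self.name}: IF concentration must be nonnegative")
        if self.pool_id is not None and not 1 <= self.pool_id <= N_POOLS:
            raise ValueError(f"{self.name}: pool_id must be in 1..{N_POOLS}")


@dataclass
class MediumFormulation:
    """A compounded medium recipe: components, salts, bicarbonate, serum."""

    components: list[tuple[str, float]]
    salt_adjustments: dict[str, float] = field(default_factory=dict)  # mM per ion
    bicarbonate_mM: float = 23.8  # RPMI-1640 level, maintains physiological pH
    serum_fraction: float = 0.10

    def __post_init__(self) -> None:
        names = [n for n, _ in self.components]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate components in formulation: {dupes}")
        for name, conc in self.components:
            if conc <= 0:
                raise ValueError(f"component {name!r} has nonpositive concentration")
        if not 0 <= self.serum_fraction < 1:
            raise ValueError("serum fraction must be in [0, 1)")

    def concentration(self, name: str) -> float:
        for n, c in self.components:
            if n == name:
                return c
        raise KeyError(f"component {name!r} not in formulation")

    @property
    def n_components(self) -> int:
        """Metabolite components only; salts and bicarbonate are counted
        separately, so both inclusive and exclusive totals are computable."""
        return len(self.components)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.components, columns=["name", "target_uM"])


class IonBalance(dict):
    """Per-ion totals in mM. Plain mapping with validation."""

    def __init__(self, totals: Mapping[str, float] | None = None):
        super().__init__()
        for ion, mM in (totals or {}).items():
            if mM < 0:
                raise ValueError(f"ion total for {ion!r} must be nonnegative")
            self[ion] = float(mM)


@dataclass
class BalanceResult:
    """Outcome of electrolyte balancing: the adjusted formulation plus any
    ions whose required salt addition would have been negative."""

    formulation: MediumFormulation
    component_contributions_mM: dict[str, float]
    infeasible: dict[str, float]  # ion -> deficit in mM (positive magnitude)

    @property
    def feasible(self) -> bool:
        return not self.infeasible


def select_components(
    specs: Sequence[MetaboliteSpec], threshold: float = DEFAULT_THRESHOLD_UM
) -> list[MetaboliteSpec]:
    """Filter IF metabolites for inclusion in the medium.

    Keeps exactly the specs that are commercially available, stable in
    aqueous solution and present strictly above ``threshold`` µM
    (a spec at exactly the threshold is excluded). Input order is preserved.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    seen: set[str] = set()
    for s in specs:
        if s.name in seen:
            raise ValueError(f"duplicate metabolite spec: {s.name!r}")
        seen.add(s.name)
    return [
        s
        for s in specs
        if s.commercially_available and s.aqueous_stable and s.if_concentration > threshold
    ]


def validate_pools(specs: Sequence[MetaboliteSpec]) -> None:
    """Check the assigned pools form the expected ten-pool layout."""
    pools = {s.pool_id for s in specs if s.pool_id is not None}
    if pools and pools != set(range(1, N_POOLS + 1)):
        raise ValueError(
            f"expected pools 1..{N_POOLS}, found {sorted(pools)}"
        )


def balance_electrolytes(
    formulation: MediumFormulation,
    reference_ions: IonBalance,
    serum_ions: IonBalance | None = None,
    counterion_map: Mapping[str, Mapping[str, float]] | None = None,
) -> BalanceResult:
    """Adjust added salts so each tracked ion matches the reference medium.

    For every ion in ``reference_ions``, the amount to add as salt is the
    reference total minus what the components' counter-ions and the serum
    already contribute. A negative requirement cannot be compounded; such
    ions are reported in ``infeasible`` with the deficit magnitude and the
    salt adjustment is clamped to zero.
    """
    serum_ions = serum_ions or IonBalance()
    counterion_map = counterion_map or {}

    contributions: dict[str, float] = {ion: 0.0 for ion in reference_ions}
    for name, conc_uM in formulation.components:
        stoich = counterion_map.get(name)
        if not stoich:
            continue
        for ion, mmol_per_mmol in stoich.items():
            contributions[ion] = contributions.get(ion, 0.0) + conc_uM / 1000.0 * mmol_per_mmol

    adjustments: dict[str, float] = {}
    infeasible: dict[str, float] = {}
    for ion, target in reference_ions.items():
        needed = target - contributions.get(ion, 0.0) - serum_ions.get(ion, 0.0)
        if needed < -BALANCE_TOL_MM:
            infeasible[ion] = -needed
            adjustments[ion] = 0.0
        else:
            adjustments[ion] = max(needed, 0.0)

    balanced = MediumFormulation(
        components=list(formulation.components),
        salt_adjustments=adjustments,
        bicarbonate_mM=formulation.bicarbonate_mM,
        serum_fraction=formulation.serum_fraction,
    )
    return BalanceResult(
        formulation=balanced,
        component_contributions_mM=contributions,
        infeasible=infeasible,
    )


@dataclass
class FidelityReport:
    """Measured-vs-expected agreement for a compounded medium batch."""

    r_squared: float
    p_value: float
    per_metabolite: pd.DataFrame  # ordered by |log fold error|, descending
    log_scale: bool = False


def verify_formulation(
    expected: MediumFormulation,
    measured: Mapping[str, tuple[float, float]],
    log_scale: bool = False,
) -> FidelityReport:
    """Compare measured concentrations (mean, SD) against the recipe.

    Pearson correlation of measured vs expected concentrations (on raw
    values by default, matching how such verifications are plotted; set
    ``log_scale=True`` to correlate log-concentrations), plus per-metabolite
    fold errors sorted worst-first.
    """
    shared = [name for name, _ in expected.components if name in measured]
    if len(shared) < 3:
        raise ValueError(
            f"need at least 3 shared metabolites to verify, got {len(shared)}"
        )
    exp = np.array([expected.concentration(n) for n in shared])
    meas = np.array([measured[n][0] for n in shared])
    sds = np.array([measured[n][1] for n in shared])
    if np.any(meas <= 0):
        bad = [n for n, m in zip(shared, meas) if m <= 0]
        raise ValueError(f"nonpositive measured concentrations for {bad}")

    x, y = (np.log10(exp), np.log10(meas)) if log_scale else (exp, meas)
    res = stats.pearsonr(x, y)
    fold = meas / exp
    table = pd.DataFrame(
        {
            "metabolite": shared,
            "expected_uM": exp,
            "measured_uM": meas,
            "measured_sd": sds,
            "fold_error": fold,
            "abs_log_fold_error": np.abs(np.log(fold)),
        }
    ).sort_values("abs_log_fold_error", ascending=False, ignore_index=True)
    return FidelityReport(
        r_squared=float(res.statistic**2),
        p_value=float(res.pvalue),
        per_metabolite=table,
        log_scale=log_scale,
    )


def _read_packaged(name: str) -> pd.DataFrame:
    text = resources.files("tifmkit.data").joinpath(name).read_text()
    return pd.read_csv(StringIO(text), sep="\t")


def load_packaged_formulation() -> tuple[MediumFormulation, pd.DataFrame]:
    """Load the packaged (synthetic stand-in) TIFM recipe.

    Returns the formulation plus the raw table (with pool assignments).
    """
    df = _read_packaged("tifm_formulation_synthetic.tsv")
    formulation = MediumFormulation(
        components=[(r.name, float(r.target_uM)) for r in df.itertuples()],
    )
    specs = [
        MetaboliteSpec(r.name, float(r.target_uM), pool_id=int(r.pool_id))
        for r in df.itertuples()
    ]
    validate_pools(specs)
    return formulation, df


def load_rpmi_ion_reference() -> IonBalance:
    """Tracked-ion totals of the RPMI-1640 reference medium, mM."""
    df = _read_packaged("rpmi1640_ions.tsv")
    return IonBalance(dict(zip(df["ion"], df["mM"])))


def load_counterion_map() -> dict[str, dict[str, float]]:
    """Counter-ion stoichiometry for ionic components (salt forms), as data."""
    df = _read_packaged("counterion_stoichiometry.tsv")
    out: dict[str, dict[str, float]] = {}
    for r in df.itertuples():
        out.setdefault(r.component, {})[r.ion] = float(r.mmol_per_mmol)
    return out
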