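"""Per-cell metabolite consumption/release (Co/Re) rates.

Paired unspent/spent media concentrations and day-1/day-2 cell counts are
combined into per-cell fluxes: cell counts are fit to exponential growth,
the growth curve is integrated analytically to cell-days, and the change in
each metabolite's media concentration is normalized to that integral to give
pmol/cell/day. Standard errors on concentrations and cell-days propagate
into the rate by the usual quotient formula.

Sign convention: negative = net consumption, positive = net release.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CultureTimecourse",
    "GrowthModel",
    "FluxEstimate",
    "GlucoseQCReport",
    "growth_rate_doublings",
    "fit_exponential",
    "integrate_cell_days",
    "co_re_rate",
    "propagate_sem",
    "co_re_from_replicates",
    "glucose_qc",
]

#: 1 µM x 1 mL = 1 nmol = 1000 pmol
PMOL_PER_UM_ML = 1000.0

#: below this |k·Δt| the exponential integral switches to its series expansion
K_SWITCHOVER = 1e-8

#: explicit missing marker for metabolites below the detection limit ("ND")
ND = float("nan")


@dataclass
class CultureTimecourse:
    """Two-timepoint culture: counts, media volume, unspent/spent media.

    Concentrations are ``{metabolite: (mean_uM, sem_uM)}``. A metabolite that
    was not detected is carried as NaN, never as zero.
    """

    t1: float
    t2: float
    n1: float
    n2: float
    volume_ml: float
    conc_unspent: Mapping[str, tuple[float, float]]
    conc_spent: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.t2 > self.t1:
            raise ValueError("t2 must be later than t1")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("cell counts must be positive")
        if self.volume_ml <= 0:
            raise ValueError("culture volume must be positive")


@dataclass(frozen=True)
class GrowthModel:
    """Exponential growth N(t) = n_ref * exp(k * (t - t_ref))."""

    k: float
    n_ref: float
    t_ref: float = 0.0

    def __post_init__(self) -> None:
        if self.n_ref <= 0:
            raise ValueError("n_ref must be positive")
        if not math.isfinite(self.k):
            raise ValueError("growth rate k must be finite")

    def population(self, t: float) -> float:
        return self.n_ref * math.exp(self.k * (t - self.t_ref))


@dataclass
class FluxEstimate:
    """A Co/Re rate in pmol/cell/day with its provenance and propagated SEM."""

    metabolite: str
    rate: float
    sem: float = 0.0
    delta_conc: float = 0.0
    cell_days: float = 0.0
    volume_ml: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be nonnegative")


def growth_rate_doublings(initial_signal: float, final_signal: float, days: float) -> float:
    """Doublings/day from start/end proliferation signals (counts or A510)."""
    if initial_signal <= 0 or final_signal <= 0:
        raise ValueError("proliferation signals must be positive")
    if days <= 0:
        raise ValueError("elapsed days must be positive")
    return math.log2(final_signal / initial_signal) / days


def fit_exponential(
    tc: CultureTimecourse | None = None,
    times: Sequence[float] | None = None,
    counts: Sequence[float] | None = None,
) -> GrowthModel:
    """Fit exponential growth to a timecourse.

    Two timepoints give the exact fit k = ln(n2/n1)/(t2-t1); three or more
    trigger log-linear least squares (which reduces to the same answer for
    two points).
    """
    if tc is not None:
        times = [tc.t1, tc.t2]
        counts = [tc.n1, tc.n2]
    t = np.asarray(times, dtype=float)
    n = np.asarray(counts, dtype=float)
    if t.size != n.size or t.size < 2:
        raise ValueError("need matched times and counts, at least two points")
    if np.any(n <= 0):
        raise ValueError("cell counts must be positive")
    if t.size == 2:
        k = math.log(n[1] / n[0]) / (t[1] - t[0])
        return GrowthModel(k=k, n_ref=float(n[0]), t_ref=float(t[0]))
    slope, intercept = np.polyfit(t - t[0], np.log(n), 1)
    return GrowthModel(k=float(slope), n_ref=float(np.exp(intercept)), t_ref=float(t[0]))


def integrate_cell_days(model: GrowthModel, t1: float, t2: float) -> float:
    """Analytic integral of the growth curve over [t1, t2], in cell-days.

    For k away from zero this is (N(t2) - N(t1))/k; for |k·Δt| below the
    switchover tolerance the second-order series expansion is used so the
    constant-population limit is exact.
    """
    if not t2 > t1:
        raise ValueError("t2 must be later than t1")
    dt = t2 - t1
    n1 = model.population(t1)
    x = model.k * dt
    if abs(x) < K_SWITCHOVER:
        return n1 * dt * (1.0 + x / 2.0 + x * x / 6.0)
    return (model.population(t2) - n1) / model.k


def co_re_rate(tc: CultureTimecourse, metabolite: str) -> FluxEstimate:
    """Net consumption/release rate of one metabolite, pmol/cell/day."""
    for table, label in ((tc.conc_unspent, "unspent"), (tc.conc_spent, "spent")):
        if metabolite not in table:
            raise KeyError(f"metabolite {metabolite!r} missing from {label} media table")
    unspent, _ = tc.conc_unspent[metabolite]
    spent, _ = tc.conc_spent[metabolite]
    if math.isnan(unspent) or math.isnan(spent):
        raise ValueError(f"metabolite {metabolite!r} is ND (not detected); no rate")
    model = fit_exponential(tc)
    cell_days = integrate_cell_days(model, tc.t1, tc.t2)
    delta = spent - unspent
    rate = delta * tc.volume_ml * PMOL_PER_UM_ML / cell_days
    return FluxEstimate(
        metabolite=metabolite,
        rate=rate,
        delta_conc=delta,
        cell_days=cell_days,
        volume_ml=tc.volume_ml,
    )


def propagate_sem(
    delta_conc_sem: float, cell_days_sem: float, estimate: FluxEstimate
) -> FluxEstimate:
    """Propagate concentration and cell-day SEMs into the rate SEM.

    sem = |rate| * sqrt((sigma_dC/dC)^2 + (sigma_cd/cd)^2) for dC != 0;
    when dC = 0 the quotient form degenerates and the concentration term
    alone survives: sem = V * sigma_dC / cell_days.
    """
    if delta_conc_sem < 0 or cell_days_sem < 0:
        raise ValueError("SEMs must be nonnegative")
    if estimate.cell_days <= 0:
        raise ValueError("estimate must carry positive cell_days")
    if estimate.delta_conc == 0:
        sem = estimate.volume_ml * PMOL_PER_UM_ML * delta_conc_sem / estimate.cell_days
    else:
        rel = math.hypot(
            delta_conc_sem / estimate.delta_conc, cell_days_sem / estimate.cell_days
        )
        sem = abs(estimate.rate) * rel
    return replace(estimate, sem=sem)


def co_re_from_replicates(
    timecourses: Sequence[CultureTimecourse], metabolite: str
) -> FluxEstimate:
    """Co/Re rate across replicate cultures with fully propagated SEM.

    Replicate media concentrations are averaged (SEM over replicates for both
    unspent and spent, combined in quadrature for the difference); the growth
    integral is computed per replicate and averaged with its own SEM.
    """
    if not timecourses:
        raise ValueError("need at least one replicate")
    n = len(timecourses)
    unspent = np.array([tc.conc_unspent[metabolite][0] for tc in timecourses])
    spent = np.array([tc.conc_spent[metabolite][0] for tc in timecourses])
    if np.any(np.isnan(unspent)) or np.any(np.isnan(spent)):
        raise ValueError(f"metabolite {metabolite!r} is ND in at least one replicate")
    cds = np.array(
        [integrate_cell_days(fit_exponential(tc), tc.t1, tc.t2) for tc in timecourses]
    )
    volume = timecourses[0].volume_ml
    delta = float(spent.mean() - unspent.mean())
    cell_days = float(cds.mean())
    rate = delta * volume * PMOL_PER_UM_ML / cell_days
    if n > 1:
        delta_sem = math.hypot(
            float(unspent.std(ddof=1)) / math.sqrt(n),
            float(spent.std(ddof=1)) / math.sqrt(n),
        )
        cd_sem = float(cds.std(ddof=1)) / math.sqrt(n)
    else:
        delta_sem = cd_sem = 0.0
    est = FluxEstimate(
        metabolite=metabolite,
        rate=rate,
        delta_conc=delta,
        cell_days=cell_days,
        volume_ml=volume,
        n=n,
    )
    return propagate_sem(delta_sem, cd_sem, est)


@dataclass(frozen=True)
class GlucoseQCReport:
    drop_fraction: float
    max_drop_fraction: float
    passed: bool


def glucose_qc(
    conc_unspent_glucose: float,
    conc_spent_glucose: float,
    max_drop_fraction: float = 0.30,
) -> GlucoseQCReport:
    """Flag cultures whose glucose availability dropped more than allowed.

    Fails iff (unspent - spent)/unspent exceeds ``max_drop_fraction``
    (default 30%). Apparent release (spent > unspent) always passes.
    """
    if conc_unspent_glucose <= 0:
        raise ValueError("unspent glucose concentration must be positive")
    drop = (conc_unspent_glucose - conc_spent_glucose) / conc_unspent_glucose
    return GlucoseQCReport(
        drop_fraction=drop,
        max_drop_fraction=max_drop_fraction,
        passed=drop <= max_drop_fraction,
    )
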