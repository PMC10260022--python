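"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator emulates the statistical structure of one experimental
design — exponentially growing cultures consuming/releasing nutrients,
a linear LC-MS detector with spiked internal standards and external
standard dilutions, tracer labeling convolved with natural isotope
abundance, and ellipsoidal tumors with known amino-acid pools — so that at
zero noise every analysis stage inverts its generator exactly.

Measurement noise is multiplicative lognormal (areas and concentrations are
positive and coefficients of variation are the natural LC-MS error scale);
isotopologue channels optionally take additive Gaussian noise clipped at
zero. All randomness flows through one seeded ``numpy`` generator recorded
in the ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flux import PMOL_PER_UM_ML, CultureTimecourse
from .quantitation import DilutionSeries, ExtractionProtocol, PeakTable
from .tissueconc import TumorGeometry
from .tracing import (
    AbundanceTable,
    ElementalFormula,
    IsotopologueVector,
    build_correction_matrix,
    load_abundance_table,
)

__all__ = [
    "GroundTruth",
    "simulate_culture",
    "simulate_peak_tables",
    "simulate_labeling",
    "simulate_tumors",
    "default_ground_truth",
]

#: serial dilution span of the external standard pools, µM
DILUTION_SERIES_MAX_UM = 5000.0
DILUTION_SERIES_MIN_UM = 1.0
DILUTION_SERIES_LEVELS = 8


@dataclass
class GroundTruth:
    """All true parameters behind one synthetic experiment.

    Defaults mirror the study conditions the generators emulate: ~1
    doubling/day growth from 1e5 cells in 2 ml, media citrulline 67 µM and
    arginine 2 µM, plasma arginine 125 µM, per-cell fluxes within a few
    pmol/cell/day, and a 5 µl + 45 µl extraction (10× dilution).
    """

    medium_uM: dict[str, float]
    fluxes_pmol_cell_day: dict[str, float]  # negative = consumption
    growth_rate_per_day: float = math.log(2.0)
    n0_cells: float = 1.0e5
    volume_ml: float = 2.0
    t1_day: float = 1.0
    t2_day: float = 2.0
    response_factors: dict[str, float] = field(default_factory=dict)
    is_mix_uM: dict[str, float] = field(default_factory=dict)
    synthesis_fraction: float = 0.45
    precursor_enrichment: float = 1.0
    tumor_axes_mm: tuple[float, float, float] = (4.0, 3.0, 2.5)
    tumor_density_mg_mm3: float = 1.05
    tumor_uM: dict[str, float] = field(default_factory=dict)
    if_uM: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.medium_uM.values()):
            raise ValueError("medium concentrations must be nonnegative")
        if any(rf <= 0 for rf in self.response_factors.values()):
            raise ValueError("response factors must be positive")
        if not 0 <= self.synthesis_fraction <= 1:
            raise ValueError("synthesis fraction must be in [0, 1]")
        if not 0 <= self.precursor_enrichment <= 1:
            raise ValueError("precursor enrichment must be in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_ground_truth(seed: int = 0, n_metabolites: int = 20) -> GroundTruth:
    """The study-condition scenario used throughout the test-suite.

    ``n_metabolites`` generic media metabolites with per-cell fluxes evenly
    covering [-5, +5] pmol/cell/day at baseline concentrations high enough
    that a day of consumption cannot deplete them, plus the named anchor
    metabolites (citrulline, arginine, glucose) at their IF-scale levels.
    """
    rng = np.random.default_rng(seed)
    names = [f"met{i:02d}" for i in range(n_metabolites)]
    fluxes = dict(zip(names, np.linspace(-5.0, 5.0, n_metabolites)))
    medium = {name: float(c) for name, c in zip(names, rng.uniform(800.0, 2000.0, n_metabolites))}
    medium.update({"citrulline": 67.0, "arginine": 2.0, "glucose": 1900.0})
    # anchor fluxes sized so none of the low-concentration nutrients deplete
    # within the sampling window (citrulline 67 µM, arginine 2 µM) and the
    # culture stays within the 30% glucose-availability QC margin
    fluxes.update({"citrulline": -0.3, "arginine": -0.01, "glucose": -3.5})
    rfs = {name: float(rf) for name, rf in zip(medium, rng.uniform(0.5, 2.0, len(medium)))}
    is_mix = {name: float(c) for name, c in zip(medium, rng.uniform(10.0, 100.0, len(medium)))}
    tumor = {"arginine": 300.0, "glutamine": 900.0, "serine": 250.0, "glycine": 400.0}
    if_conc = {"arginine": 30.0, "glutamine": 850.0, "serine": 260.0, "glycine": 380.0}
    return GroundTruth(
        medium_uM=medium,
        fluxes_pmol_cell_day=fluxes,
        response_factors=rfs,
        is_mix_uM=is_mix,
        tumor_uM=tumor,
        if_uM=if_conc,
        seed=seed,
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit median and the stated CV."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def simulate_culture(
    gt: GroundTruth,
    n_replicates: int = 3,
    noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[CultureTimecourse]:
    """Replicate two-timepoint cultures under exponential growth.

    Spent-media concentrations follow the exact mass balance
    ``spent = unspent + flux · cell_days / (volume · 1000)`` (flux negative
    for consumption). A metabolite driven below zero is clipped at 0 and a
    depletion warning is attached — the synthetic analogue of a culture
    failing its nutrient-availability QC.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    if rng is None:
        rng = gt.rng()
    k, dt = gt.growth_rate_per_day, gt.t2_day - gt.t1_day
    n1_true = gt.n0_cells * math.exp(k * gt.t1_day)
    n2_true = gt.n0_cells * math.exp(k * gt.t2_day)
    if abs(k * dt) < 1e-12:
        cell_days = n1_true * dt
    else:
        cell_days = (n2_true - n1_true) / k

    out = []
    for _ in range(n_replicates):
        unspent, spent = {}, {}
        depleted = []
        for met, conc in gt.medium_uM.items():
            flux = gt.fluxes_pmol_cell_day.get(met, 0.0)
            true_spent = conc + flux * cell_days / (gt.volume_ml * PMOL_PER_UM_ML)
            if true_spent < 0:
                depleted.append(met)
                true_spent = 0.0
            unspent[met] = (conc * float(_lognormal_factor(rng, noise_cv)), 0.0)
            spent[met] = (true_spent * float(_lognormal_factor(rng, noise_cv)), 0.0)
        tc = CultureTimecourse(
            t1=gt.t1_day,
            t2=gt.t2_day,
            n1=n1_true * float(_lognormal_factor(rng, noise_cv)),
            n2=n2_true * float(_lognormal_factor(rng, noise_cv)),
            volume_ml=gt.volume_ml,
            conc_unspent=unspent,
            conc_spent=spent,
        )
        tc.depleted = depleted  # attached report, mirrors the glucose QC concern
        out.append(tc)
    return out


def simulate_peak_tables(
    gt: GroundTruth,
    protocol: ExtractionProtocol | None = None,
    noise_cv: float = 0.0,
    sample_concentrations: dict[str, dict[str, float]] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PeakTable, dict[str, DilutionSeries], dict[str, np.ndarray]]:
    """Linear-detector peak tables plus external standard dilution series.

    ``area = response_factor × concentration-in-extract``; internal-standard
    areas come from the mix concentrations through the same response model.
    Returns the media-sample peak table (isotopologue 0 = analyte, 1 = its
    labeled internal standard), the per-metabolite dilution series spanning
    5 mM → 1 µM, and the internal-standard areas across the dilution runs.
    """
    protocol = protocol or ExtractionProtocol()
    if rng is None:
        rng = gt.rng()
    if sample_concentrations is None:
        sample_concentrations = {"media_1": dict(gt.medium_uM)}
    df = protocol.dilution_factor

    levels = np.geomspace(DILUTION_SERIES_MAX_UM, DILUTION_SERIES_MIN_UM, DILUTION_SERIES_LEVELS)
    series: dict[str, DilutionSeries] = {}
    is_series_areas: dict[str, np.ndarray] = {}
    rows = []
    for met, rf in gt.response_factors.items():
        std_areas = rf * (levels / df) * _lognormal_factor(rng, noise_cv, levels.size)
        series[met] = DilutionSeries(met, levels, std_areas)
        c_is = gt.is_mix_uM.get(met)
        if c_is is not None:
            is_series_areas[met] = rf * (c_is / df) * _lognormal_factor(
                rng, noise_cv, levels.size
            )
    for sample_id, concs in sample_concentrations.items():
        for met, conc in concs.items():
            rf = gt.response_factors.get(met)
            if rf is None:
                continue
            area = rf * (conc / df) * float(_lognormal_factor(rng, noise_cv))
            rows.append((sample_id, met, 0, area, 0.0))
            c_is = gt.is_mix_uM.get(met)
            if c_is is not None:
                is_area = rf * (c_is / df) * float(_lognormal_factor(rng, noise_cv))
                rows.append((sample_id, met, 1, is_area, 0.0))
    table = PeakTable(
        pd.DataFrame(
            rows,
            columns=["sample_id", "metabolite", "isotopologue_index", "peak_area", "retention_time"],
        )
    )
    return table, series, is_series_areas


def simulate_labeling(
    gt: GroundTruth,
    formula: ElementalFormula,
    abundances: AbundanceTable | None = None,
    diagnostic_shift: int | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    metabolite: str = "argininosuccinate",
) -> tuple[IsotopologueVector, np.ndarray]:
    """Raw (natural-abundance-convolved) MID for a two-pool labeling mix.

    The true MID is ``1 - f·e`` unlabeled plus ``f·e`` at the diagnostic
    shift, where ``f`` is the synthesis fraction and ``e`` the precursor
    enrichment; it is forward-convolved through the correction matrix, with
    optional per-channel Gaussian noise clipped at zero. Returns the raw
    vector and the true MID.
    """
    if abundances is None:
        abundances = load_abundance_table()
    if rng is None:
        rng = gt.rng()
    n = int(formula.max_tracer_atoms)
    shift = n if diagnostic_shift is None else diagnostic_shift
    if not 0 <= shift <= n:
        raise ValueError(f"diagnostic shift +{shift} exceeds tracer capacity M+{n}")
    fe = gt.synthesis_fraction * gt.precursor_enrichment
    true_mid = np.zeros(n + 1)
    true_mid[0] = 1.0 - fe
    true_mid[shift] += fe
    matrix = build_correction_matrix(formula, abundances)
    raw = matrix @ true_mid
    if noise_sd > 0:
        raw = np.clip(raw + rng.normal(0.0, noise_sd, raw.size), 0.0, None)
    vec = IsotopologueVector(
        metabolite=metabolite,
        values=raw,
        corrected=False,
        metadata={"abundance_version": abundances.version},
    )
    return vec, true_mid


def simulate_tumors(
    gt: GroundTruth,
    n: int = 4,
    axis_cv: float = 0.15,
    rng: np.random.Generator | None = None,
) -> tuple[list[TumorGeometry], pd.DataFrame, pd.DataFrame]:
    """Ellipsoidal tumor cohort with known amino-acid pools.

    Semi-axes are lognormal around the ground-truth axes; mass follows the
    true density exactly so the density round-trip is noiseless; tissue
    amounts are ``true concentration / density`` (pmol/mg). IF replicate
    concentrations are drawn independently around the true IF levels.
    """
    if n < 1:
        raise ValueError("need at least one tumor")
    if rng is None:
        rng = gt.rng()
    geoms = []
    amount_rows = []
    for i in range(n):
        axes = [ax * float(_lognormal_factor(rng, axis_cv)) for ax in gt.tumor_axes_mm]
        volume = (4.0 / 3.0) * math.pi * axes[0] * axes[1] * axes[2]
        g = TumorGeometry(axes[0], axes[1], axes[2], mass_mg=gt.tumor_density_mg_mm3 * volume)
        geoms.append(g)
        for met, conc in gt.tumor_uM.items():
            amount_rows.append(
                {
                    "tumor_id": f"tumor_{i + 1}",
                    "metabolite": met,
                    "pmol_per_mg": conc / gt.tumor_density_mg_mm3,
                }
            )
    if_rows = [
        {"sample_id": f"if_{j + 1}", "metabolite": met, "uM": conc}
        for j in range(max(n - 1, 2))
        for met, conc in gt.if_uM.items()
    ]
    return geoms, pd.DataFrame(amount_rows), pd.DataFrame(if_rows)
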