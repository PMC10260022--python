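"""Absolute metabolite quantitation from LC-MS / GC-MS peak areas.

Two routes to micromolar concentrations, mirroring standard practice for
media metabolomics:

* **internal standard**: the peak area of the unlabeled analyte is ratioed
  to the peak area of a co-eluting isotopically labeled internal standard
  whose concentration in the extraction mix was itself calibrated against
  external standard dilutions;
* **external curve**: the (optionally internal-standard-normalized) peak
  area is inverse-predicted through a linear calibration curve fit to a
  serial dilution series, with curves below r² = 0.95 excluded.

Both routes assume labeled and unlabeled species of the same metabolite
share a detector response factor (the isotope-dilution assumption), and
both correct for the extraction dilution explicitly so that asymmetric
sample/standard protocols are handled; with a shared protocol the dilution
cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PeakTable",
    "InternalStandard",
    "DilutionSeries",
    "CalibrationCurve",
    "ExtractionProtocol",
    "QuantResult",
    "calibrate_internal_standard",
    "quantify_by_internal_standard",
    "match_internal_standard_by_elution",
    "fit_external_curve",
    "quantify_by_external_curve",
    "quantify_by_spiked_ratio",
]

R2_USABLE = 0.95  # curves below this are excluded from quantitation

PEAK_COLUMNS = ["sample_id", "metabolite", "isotopologue_index", "peak_area", "retention_time"]


@dataclass(frozen=True)
class ExtractionProtocol:
    """Volumes of sample and extraction solvent; dilution factor follows."""

    sample_volume_ul: float = 5.0
    extraction_volume_ul: float = 45.0

    def __post_init__(self) -> None:
        if self.sample_volume_ul <= 0 or self.extraction_volume_ul <= 0:
            raise ValueError("extraction volumes must be positive")

    @property
    def dilution_factor(self) -> float:
        return (self.sample_volume_ul + self.extraction_volume_ul) / self.sample_volume_ul


@dataclass
class PeakTable:
    """Long-format detector peak areas, one row per isotopologue peak."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PEAK_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"peak table missing columns: {missing}")
        if (self.data["peak_area"] < 0).any():
            raise ValueError("peak areas must be nonnegative")
        key = ["sample_id", "metabolite", "isotopologue_index"]
        if self.data.duplicated(key).any():
            dups = self.data.loc[self.data.duplicated(key), key].iloc[0].tolist()
            raise ValueError(f"duplicate peak entry for {dups}")

    def area(self, sample_id: str, metabolite: str, isotopologue_index: int = 0) -> float:
        sel = self.data[
            (self.data["sample_id"] == sample_id)
            & (self.data["metabolite"] == metabolite)
            & (self.data["isotopologue_index"] == isotopologue_index)
        ]
        if sel.empty:
            raise KeyError(
                f"no peak for ({sample_id!r}, {metabolite!r}, M+{isotopologue_index})"
            )
        return float(sel["peak_area"].iloc[0])


@dataclass
class InternalStandard:
    """An isotopically labeled spike used for ratio quantitation."""

    metabolite: str
    label: str = ""
    retention_time: float = 0.0
    concentration_in_mix: float | None = None
    calibration_r2: float | None = None
    calibration_protocol: ExtractionProtocol = field(default_factory=ExtractionProtocol)

    def __post_init__(self) -> None:
        if self.concentration_in_mix is not None and self.concentration_in_mix <= 0:
            raise ValueError("calibrated mix concentration must be positive")

    @property
    def name(self) -> str:
        return f"{self.label} {self.metabolite}".strip()


@dataclass
class DilutionSeries:
    """External standard serial dilution: known µM paired with peak areas."""

    metabolite: str
    concentrations: Sequence[float]
    areas: Sequence[float]

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        a = np.asarray(self.areas, dtype=float)
        if c.size != a.size:
            raise ValueError("concentrations and areas must be paired")
        if c.size < 4:
            raise ValueError("a dilution series needs at least four levels")
        if not np.all(np.diff(c) < 0):
            raise ValueError("series concentrations must be strictly decreasing")
        if np.any(c <= 0):
            raise ValueError("series concentrations must be positive")
        self.concentrations = c
        self.areas = a


@dataclass
class CalibrationCurve:
    """Fitted linear external-standard model: area = slope·conc + intercept."""

    metabolite: str
    slope: float
    intercept: float
    r_squared: float
    conc_min: float
    conc_max: float
    normalized: bool = False

    @property
    def usable(self) -> bool:
        return self.r_squared >= R2_USABLE


@dataclass(frozen=True)
class QuantResult:
    """A concentration plus an extrapolation flag for out-of-range inverse
    predictions."""

    metabolite: str
    uM: float
    extrapolated: bool = False
    method: str = "external_curve"


def _dilution_ratio(
    protocol: ExtractionProtocol, calibration_protocol: ExtractionProtocol | None
) -> float:
    """Sample/standard dilution correction; exactly 1 for a shared protocol."""
    if calibration_protocol is None:
        return 1.0
    return protocol.dilution_factor / calibration_protocol.dilution_factor


def calibrate_internal_standard(
    series: DilutionSeries,
    is_areas: Sequence[float],
    retention_time: float = 0.0,
    label: str = "",
    mode: str = "regression",
    protocol: ExtractionProtocol | None = None,
) -> InternalStandard:
    """Determine an internal standard's concentration from external standards.

    Across the dilution runs the labeled spike is at one fixed concentration
    C while the unlabeled analyte steps through known concentrations c_i, so
    (unlabeled area)/(labeled area) = c_i / C under the shared-response
    assumption. ``mode="regression"`` fits the ratio against c_i through the
    origin (default); ``mode="single_point"`` averages c_i·b_i/a_i. A fit
    with r² < 0.95 rejects the calibration.
    """
    b = np.asarray(is_areas, dtype=float)
    c = np.asarray(series.concentrations, dtype=float)
    a = np.asarray(series.areas, dtype=float)
    if b.size != c.size:
        raise ValueError("need one internal-standard area per dilution level")
    if np.any(b <= 0):
        raise ValueError("internal-standard areas must be positive")
    ratios = a / b
    r = stats.pearsonr(c, ratios).statistic
    r2 = float(r * r) if np.isfinite(r) else 0.0
    if r2 < R2_USABLE:
        raise ValueError(
            f"internal-standard calibration for {series.metabolite!r} rejected: "
            f"response not linear (r²={r2:.3f} < {R2_USABLE})"
        )
    if mode == "regression":
        slope = float(np.dot(c, ratios) / np.dot(c, c))  # through-origin OLS
        conc = 1.0 / slope
    elif mode == "single_point":
        conc = float(np.mean(c / ratios))
    else:
        raise ValueError(f"unknown calibration mode {mode!r}")
    return InternalStandard(
        metabolite=series.metabolite,
        label=label,
        retention_time=retention_time,
        concentration_in_mix=conc,
        calibration_r2=r2,
        calibration_protocol=protocol or ExtractionProtocol(),
    )


def quantify_by_internal_standard(
    sample_area: float,
    is_area: float,
    istd: InternalStandard,
    protocol: ExtractionProtocol | None = None,
) -> float:
    """Concentration (µM in the original sample) by internal-standard ratio."""
    if istd.concentration_in_mix is None:
        raise ValueError(f"internal standard {istd.name!r} is not calibrated")
    if is_area <= 0:
        raise ValueError(
            f"internal-standard peak area is zero for {istd.metabolite!r}; "
            "ratio undefined"
        )
    if sample_area < 0:
        raise ValueError("sample peak area must be nonnegative")
    correction = _dilution_ratio(protocol or istd.calibration_protocol, istd.calibration_protocol)
    return (sample_area / is_area) * istd.concentration_in_mix * correction


def match_internal_standard_by_elution(
    metabolite_rt: float, standards: Sequence[InternalStandard]
) -> InternalStandard:
    """Pick the standard with the nearest retention time (ties: name order)."""
    if not standards:
        raise ValueError("no internal standards to match against")
    return min(standards, key=lambda s: (abs(s.retention_time - metabolite_rt), s.name))


def fit_external_curve(
    series: DilutionSeries, normalized: bool = False, weighting: str = "none"
) -> CalibrationCurve:
    """Linear fit through the dilution series (r² gates usability).

    Unweighted OLS by default; ``weighting="1/x"`` down-weights high
    concentrations for heteroscedastic detectors. The r² gate is always
    computed on the unweighted correlation so usability does not depend on
    the weighting choice.
    """
    c = np.asarray(series.concentrations, dtype=float)
    a = np.asarray(series.areas, dtype=float)
    fit = stats.linregress(c, a)
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 0.0
    if weighting == "none":
        slope, intercept = float(fit.slope), float(fit.intercept)
    elif weighting == "1/x":
        slope, intercept = (float(v) for v in np.polyfit(c, a, 1, w=1.0 / np.sqrt(c)))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return CalibrationCurve(
        metabolite=series.metabolite,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        conc_min=float(c.min()),
        conc_max=float(c.max()),
        normalized=normalized,
    )


def quantify_by_external_curve(
    normalized_area: float,
    curve: CalibrationCurve,
    protocol: ExtractionProtocol | None = None,
    calibration_protocol: ExtractionProtocol | None = None,
) -> QuantResult:
    """Inverse-predict a concentration through a usable calibration curve.

    Values outside the calibrated range are returned flagged as extrapolated
    rather than refused.
    """
    if not curve.usable:
        raise ValueError(
            f"calibration curve for {curve.metabolite!r} is not usable "
            f"(r²={curve.r_squared:.3f} < {R2_USABLE})"
        )
    if curve.slope == 0:
        raise ValueError(f"degenerate zero-slope curve for {curve.metabolite!r}")
    raw = (normalized_area - curve.intercept) / curve.slope
    extrapolated = not (curve.conc_min <= raw <= curve.conc_max)
    correction = _dilution_ratio(protocol or ExtractionProtocol(), calibration_protocol)
    return QuantResult(
        metabolite=curve.metabolite, uM=raw * correction, extrapolated=extrapolated
    )


def quantify_by_spiked_ratio(
    unlabeled_area: float,
    labeled_spike_area: float,
    spike_concentration: float,
    sample_volume: float = 1.0,
    spike_volume: float = 1.0,
) -> float:
    """Concentration from a known-concentration labeled spike.

    conc = (unlabeled/labeled) × spike concentration × (spike/sample volume);
    with equal volumes and equal areas this returns the spike concentration.
    """
    if labeled_spike_area <= 0:
        raise ValueError("labeled spike peak area must be positive")
    if spike_concentration <= 0:
        raise ValueError("spike concentration must be positive")
    if sample_volume <= 0 or spike_volume <= 0:
        raise ValueError("volumes must be positive")
    if unlabeled_area < 0:
        raise ValueError("unlabeled peak area must be nonnegative")
    return (
        (unlabeled_area / labeled_spike_area)
        * spike_concentration
        * (spike_volume / sample_volume)
    )
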