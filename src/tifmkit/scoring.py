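"""Ancillary assay scores: weighted IHC positive-pixel score and ΔΔCt.

The IHC score weights positive pixels by intensity class (low = 1,
medium = 2, high = 3), normalizes by all pixels in the region, and averages
the per-region scores unweighted across annotated regions. Absolute scores
depend on the upstream pixel classifier's intensity thresholds, which this
module consumes as given class counts.

qPCR relative expression follows the Livak ΔΔCt method: ΔCt = target −
reference per sample, ΔΔCt relative to the arithmetic mean control ΔCt,
expression = 2^−ΔΔCt (so the control condition's geometric-mean expression
is exactly 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegionPixelCounts",
    "CtRecord",
    "ihc_region_score",
    "ihc_sample_score",
    "ddct_expression",
]

INTENSITY_WEIGHTS = {"low": 1.0, "medium": 2.0, "high": 3.0}


@dataclass(frozen=True)
class RegionPixelCounts:
    """Positive-pixel counts by intensity class for one annotated region."""

    region_id: str
    n_low: int
    n_medium: int
    n_high: int
    n_total: int

    def __post_init__(self) -> None:
        counts = (self.n_low, self.n_medium, self.n_high, self.n_total)
        if any(c < 0 for c in counts):
            raise ValueError("pixel counts must be nonnegative")
        if self.n_low + self.n_medium + self.n_high > self.n_total:
            raise ValueError(
                f"region {self.region_id!r}: positive pixels exceed total pixels"
            )


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: target and housekeeping Ct for a sample."""

    sample: str
    condition: str
    target_ct: float
    reference_ct: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.target_ct) and np.isfinite(self.reference_ct)):
            raise ValueError(f"sample {self.sample!r}: Ct values must be finite")


def ihc_region_score(r: RegionPixelCounts) -> float:
    """(1·low + 2·medium + 3·high) / total pixels; in [0, 3]."""
    if r.n_total == 0:
        raise ValueError(f"region {r.region_id!r} has zero total pixels")
    weighted = (
        INTENSITY_WEIGHTS["low"] * r.n_low
        + INTENSITY_WEIGHTS["medium"] * r.n_medium
        + INTENSITY_WEIGHTS["high"] * r.n_high
    )
    return weighted / r.n_total


def ihc_sample_score(
    regions: Sequence[RegionPixelCounts], pixel_weighted: bool = False
) -> float:
    """Average region score for a sample.

    Unweighted mean of per-region scores by default (each annotated region
    counts equally regardless of its size); ``pixel_weighted=True`` pools
    pixels across regions instead.
    """
    if not regions:
        raise ValueError("at least one region is required")
    if pixel_weighted:
        total = sum(r.n_total for r in regions)
        if total == 0:
            raise ValueError("all regions have zero pixels")
        return sum(ihc_region_score(r) * r.n_total for r in regions) / total
    return float(np.mean([ihc_region_score(r) for r in regions]))


def ddct_expression(
    samples: Sequence[CtRecord], control_condition: str
) -> pd.DataFrame:
    """Per-sample relative expression 2^−ΔΔCt against a control condition."""
    if not samples:
        raise ValueError("no Ct records supplied")
    control_dcts = [
        s.target_ct - s.reference_ct for s in samples if s.condition == control_condition
    ]
    if not control_dcts:
        raise ValueError(f"control condition {control_condition!r} has no samples")
    control_mean = float(np.mean(control_dcts))
    rows = []
    for s in samples:
        dct = s.target_ct - s.reference_ct
        ddct = dct - control_mean
        rows.append(
            {
                "sample": s.sample,
                "condition": s.condition,
                "delta_ct": dct,
                "delta_delta_ct": ddct,
                "relative_expression": 2.0 ** (-ddct),
            }
        )
    return pd.DataFrame(rows)
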