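"""Count-based estimators for recombination assays.

Recombination frequencies from colony counts (with Wilson score intervals),
transformation-efficiency-adjusted activities for non-replicative circle
assays, fold changes between induction conditions (log-scale CI), and
restriction-profile population summaries for mismatched-circle clones.
The source assays report point estimates only; the interval machinery here
is added rigor and is documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import DataError
from .site_model import MARKER_CLASSES, StrandMarkerPair


@dataclass(frozen=True)
class AssayCounts:
    """Clone counts from one assay plating.

    ``recombinant`` of ``total`` clones carry the recombination marker.
    ``total`` may be ``None`` for raw clone tallies that only enter ratio
    estimators (e.g. the pir-/pir+ counts of the circle assay), in which
    case no frequency can be computed.  ``normalizer`` holds an optional
    plating/transformation-efficiency factor.
    """

    recombinant: int
    total: int | None = None
    label: str = ""
    normalizer: float | None = None

    def __post_init__(self):
        if self.recombinant < 0:
            raise DataError("recombinant count must be non-negative")
        if self.total is not None:
            if self.total <= 0:
                raise DataError("total must be positive when given")
            if self.recombinant > self.total:
                raise DataError("recombinant count exceeds total")
        if self.normalizer is not None and self.normalizer <= 0:
            raise DataError("normalizer must be positive")


@dataclass(frozen=True)
class FrequencyEstimate:
    """Point estimate with 95% Wilson score interval."""

    point: float
    ci_low: float
    ci_high: float
    recombinant: int
    total: int
    label: str = ""

    def percent(self, sig: int = 2) -> str:
        """Percentage formatted to ``sig`` significant figures, the style
        used for published clone-count frequencies (1/607 -> '0.16%')."""
        return f"{100 * self.point:.{sig}g}%"


def frequency(counts: AssayCounts, alpha: float = 0.05) -> FrequencyEstimate:
    """Recombination frequency: recombinant / total with Wilson 95% CI.

    The Wilson score interval is preferred over the Wald interval because
    colony counts are frequently small or zero; it keeps the interval
    inside [0, 1] and gives a positive upper bound at zero counts.
    """
    if counts.total is None or counts.total <= 0:
        raise DataError(f"frequency undefined: no total clone count ({counts.label})")
    lo, hi = proportion_confint(
        counts.recombinant, counts.total, alpha=alpha, method="wilson"
    )
    point = counts.recombinant / counts.total
    return FrequencyEstimate(
        point=point,
        # guard against float residue at the k=0 / k=n edges so the
        # interval always contains the point estimate
        ci_low=min(max(float(lo), 0.0), point),
        ci_high=max(min(float(hi), 1.0), point),
        recombinant=counts.recombinant,
        total=counts.total,
        label=counts.label,
    )


def adjusted_activity(
    pir_minus: AssayCounts, pir_plus: AssayCounts, te_ratio: float = 1.0
) -> float:
    """Transformation-efficiency-adjusted recombination activity.

    The non-replicative circle assay compares clone yields under
    non-permissive (pir-) and permissive (pir+) replication conditions;
    ``te_ratio`` corrects for the relative transformation efficiency of the
    two strains, measured beforehand.
    """
    if pir_plus.recombinant <= 0:
        raise DataError("pir+ clone count must be positive")
    if te_ratio <= 0:
        raise DataError("te_ratio must be positive")
    return (pir_minus.recombinant / pir_plus.recombinant) * te_ratio


@dataclass(frozen=True)
class FoldChange:
    ratio: float
    ci_low: float | None = None
    ci_high: float | None = None


def fold_change(freq_induced, freq_repressed, alpha: float = 0.05) -> FoldChange:
    """Ratio of two recombination frequencies.

    Accepts floats, :class:`FrequencyEstimate` or :class:`AssayCounts` for
    either argument.  When both carry counts, a CI is propagated on the log
    scale (delta method on log p-hat: var = (1-p)/(n p)); with zero counts
    or bare floats the CI is reported as undefined (``None``).
    """
    p1, n1 = _as_prop(freq_induced)
    p2, n2 = _as_prop(freq_repressed)
    if p2 == 0:
        raise DataError("repressed frequency is zero: fold change undefined")
    ratio = p1 / p2
    if n1 and n2 and p1 > 0:
        se = np.sqrt((1 - p1) / (n1 * p1) + (1 - p2) / (n2 * p2))
        z = stats.norm.ppf(1 - alpha / 2)
        return FoldChange(
            ratio=ratio,
            ci_low=float(ratio * np.exp(-z * se)),
            ci_high=float(ratio * np.exp(z * se)),
        )
    return FoldChange(ratio=ratio)


def _as_prop(x) -> tuple[float, int | None]:
    if isinstance(x, AssayCounts):
        est = frequency(x)
        return est.point, est.total
    if isinstance(x, FrequencyEstimate):
        return x.point, x.total
    x = float(x)
    if not 0 <= x <= 1:
        raise DataError(f"frequency {x} outside [0, 1]")
    return x, None


# -- restriction-profile summaries ------------------------------------------


def largest_remainder_percentages(
    counts: Sequence[int], decimals: int = 1
) -> list[float]:
    """Percentages rounded to ``decimals`` that sum to exactly 100
    (largest-remainder apportionment)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise DataError("cannot compute percentages of an empty tally")
    scale = 10**decimals
    quota = counts / total * 100 * scale
    floors = np.floor(quota).astype(np.int64)
    short = int(round(100 * scale - floors.sum()))
    order = np.argsort(-(quota - floors), kind="stable")
    floors[order[:short]] += 1
    return [float(f) / scale for f in floors]


def profile_summary(
    clone_profiles: Sequence[StrandMarkerPair], decimals: int = 1
) -> dict[str, float]:
    """Percentage of clones in each restriction class.

    Classes are the four marker genotypes (NarI+/SacII-, NarI-/SacII+,
    NarI+/SacII+, NarI-/SacII-); percentages use largest-remainder rounding
    so they sum to exactly 100, matching the reporting style of segregation
    controls.
    """
    if not clone_profiles:
        raise DataError("empty clone list")
    counts = [sum(1 for c in clone_profiles if c == cls) for cls in MARKER_CLASSES]
    if sum(counts) != len(clone_profiles):
        raise DataError("clone profiles contain unknown marker classes")
    pct = largest_remainder_percentages(counts, decimals=decimals)
    return {cls.label: p for cls, p in zip(MARKER_CLASSES, pct)}


# -- replicate-level comparisons (thin pass-through) ------------------------


def compare_replicates(a: Sequence[float], b: Sequence[float]):
    """Two-sample Kolmogorov-Smirnov test on replicate-level frequencies.

    A thin pass-through to :func:`scipy.stats.ks_2samp` for users with
    replicate tables; the estimators above are the substantive layer.
    """
    return stats.ks_2samp(a, b)


def counts_table(df: pd.DataFrame) -> list[AssayCounts]:
    """Parse a TSV-derived frame with columns label, recombinant, total
    [, normalizer] into AssayCounts."""
    out = []
    for _, row in df.iterrows():
        total = row.get("total")
        out.append(
            AssayCounts(
                recombinant=int(row["recombinant"]),
                total=None if pd.isna(total) else int(total),
                label=str(row.get("label", "")),
                normalizer=(None if "normalizer" not in df.columns
                            or pd.isna(row["normalizer"])
                            else float(row["normalizer"])),
            )
        )
    return out
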