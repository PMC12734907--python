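"""Set-level diagnosis: proportion-classified statistic and thresholds.

A trained per-metabolite classifier is turned into a disease-level call
by the *proportion-classified* statistic: the fraction of a disease's
dysregulated metabolites that the reference-disease model flags as
belonging to the reference disease. Uncertainty is quantified by a
bootstrap over the metabolite set (500 resamples with replacement,
percentile interval).

To convert the statistic into a decision threshold between the
reference disease and its most confusable comparator, the confidence
level of both percentile intervals is lowered in small steps until the
intervals become disjoint; the threshold is placed in the gap. Pairwise
disease-vs-disease classification proportions are summarized in a
cross-disease matrix with per-cell Wilson score intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from pascdx.errors import ConfigurationError, InsufficientDataError
from pascdx.features import LabeledDescriptorTable
from pascdx.modeling import ModelSpec, TrainedClassifier, train_final

__all__ = [
    "SetDiagnosis",
    "ThresholdResult",
    "CrossDiseaseMatrix",
    "proportion_flagged",
    "bootstrap_proportion",
    "determine_threshold",
    "wilson_interval",
    "cross_disease_matrix",
]


@dataclass
class SetDiagnosis:
    """Proportion-classified statistic with its bootstrap distribution."""

    n_metabolites: int
    n_flagged: int
    proportion: float
    bootstrap_values: np.ndarray
    ci_low: float
    ci_high: float
    confidence: float

    def to_dict(self) -> dict:
        return {
            "n_metabolites": self.n_metabolites,
            "n_flagged": self.n_flagged,
            "proportion": self.proportion,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "confidence": self.confidence,
            "n_boot": int(self.bootstrap_values.size),
        }


@dataclass
class ThresholdResult:
    """Outcome of the confidence-shrinking disjointness scan."""

    separable: bool
    confidence_level: float
    threshold: float
    reference_ci: tuple[float, float]
    comparator_ci: tuple[float, float]
    gap_low: float  # comparator upper endpoint at disjointness
    gap_high: float  # reference lower endpoint at disjointness

    def to_dict(self) -> dict:
        return {
            "separable": self.separable,
            "confidence_level": self.confidence_level,
            "threshold": self.threshold,
            "reference_ci": list(self.reference_ci),
            "comparator_ci": list(self.comparator_ci),
            "gap": [self.gap_low, self.gap_high],
        }


def proportion_flagged(
    classifier: TrainedClassifier, metabolite_set: LabeledDescriptorTable | np.ndarray
) -> tuple[float, np.ndarray]:
    """Fraction of a metabolite set flagged positive by the classifier."""
    if isinstance(metabolite_set, LabeledDescriptorTable):
        n = len(metabolite_set)
    else:
        n = np.atleast_2d(metabolite_set).shape[0]
    if n == 0:
        raise InsufficientDataError("metabolite set is empty")
    flags = classifier.predict(metabolite_set)
    return float(flags.mean()), flags


def bootstrap_proportion(
    flags: np.ndarray,
    n_boot: int = 500,
    confidence: float = 0.95,
    seed: int = 0,
) -> SetDiagnosis:
    """Percentile-bootstrap CI for the proportion-classified statistic.

    Each replicate resamples the per-metabolite flags with replacement
    at the original set size and records the flagged proportion; the
    interval is the empirical ((1-c)/2, 1-(1-c)/2) percentile pair of
    the replicate proportions.
    """
    flags = np.asarray(flags).astype(bool)
    if flags.size == 0:
        raise InsufficientDataError("flags vector is empty")
    if n_boot < 2:
        raise ConfigurationError(f"n_boot must be >= 2, got {n_boot}")
    if not 0.0 < confidence < 1.0:
        raise ConfigurationError(f"confidence must be in (0, 1), got {confidence}")
    rng = np.random.default_rng(seed)
    n = flags.size
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = flags[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [100 * (1 - confidence) / 2, 100 * (1 + confidence) / 2])
    return SetDiagnosis(
        n_metabolites=n,
        n_flagged=int(flags.sum()),
        proportion=float(flags.mean()),
        bootstrap_values=boots,
        ci_low=float(lo),
        ci_high=float(hi),
        confidence=confidence,
    )


def _middle_interval(values: np.ndarray, confidence: float) -> tuple[float, float]:
    lo, hi = np.percentile(values, [100 * (1 - confidence) / 2, 100 * (1 + confidence) / 2])
    return float(lo), float(hi)


def determine_threshold(
    reference_boot: np.ndarray,
    comparator_boot: np.ndarray,
    c_step: float = 0.001,
    c_start: float = 0.95,
) -> ThresholdResult:
    """Confidence-shrinking disjointness rule for the decision threshold.

    Scans confidence levels downward from ``c_start`` in steps of
    ``c_step``. At each level the middle-c percentile intervals of the
    reference and comparator bootstrap distributions are computed; the
    scan stops at the first level where the comparator's upper endpoint
    falls strictly below the reference's lower endpoint. The threshold
    is the midpoint of that gap (both endpoints are also reported).

    If the reference's bootstrap median does not exceed the
    comparator's, or no level in (0, c_start] achieves disjointness, the
    result is marked non-separable.
    """
    ref = np.asarray(reference_boot, dtype=float)
    comp = np.asarray(comparator_boot, dtype=float)
    if ref.size == 0 or comp.size == 0:
        raise InsufficientDataError("bootstrap vectors must be non-empty")
    if c_step <= 0:
        raise ConfigurationError(f"c_step must be positive, got {c_step}")

    non_sep = ThresholdResult(
        separable=False,
        confidence_level=math.nan,
        threshold=math.nan,
        reference_ci=_middle_interval(ref, c_start),
        comparator_ci=_middle_interval(comp, c_start),
        gap_low=math.nan,
        gap_high=math.nan,
    )
    if np.median(ref) < np.median(comp):
        return non_sep

    n_steps = int(math.floor(c_start / c_step)) + 1
    for i in range(n_steps):
        c = c_start - i * c_step
        if c <= 0:
            break
        ref_lo, ref_hi = _middle_interval(ref, c)
        comp_lo, comp_hi = _middle_interval(comp, c)
        if comp_hi < ref_lo:
            return ThresholdResult(
                separable=True,
                confidence_level=round(c, 10),
                threshold=(comp_hi + ref_lo) / 2.0,
                reference_ci=(ref_lo, ref_hi),
                comparator_ci=(comp_lo, comp_hi),
                gap_low=comp_hi,
                gap_high=ref_lo,
            )
    return non_sep


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    With z the two-sided normal quantile for the given confidence and
    p-hat = k/n:

        center = (p + z^2/2n) / (1 + z^2/n)
        half   = z * sqrt(p(1-p)/n + z^2/4n^2) / (1 + z^2/n)

    No continuity correction. Bounds lie in [0, 1] by construction.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise ConfigurationError(f"k must be in [0, n]={n}, got {k}")
    if not 0.0 < confidence < 1.0:
        raise ConfigurationError(f"confidence must be in (0, 1), got {confidence}")
    z = norm.ppf(0.5 + confidence / 2.0)
    p = k / n
    denom = 1.0 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    # boundary cases are analytically exact: k=0 -> low=0, k=n -> high=1
    low = 0.0 if k == 0 else max(0.0, center - half)
    high = 1.0 if k == n else min(1.0, center + half)
    return low, high


@dataclass
class CrossDiseaseMatrix:
    """Pairwise disease-vs-disease classification proportions.

    ``proportions.loc[row, col]`` is the fraction of the *column*
    disease's dysregulated metabolites that the *row* disease's model
    flags as row-disease-dysregulated; the diagonal uses each model's
    own positives. ``ci_low``/``ci_high`` hold the per-cell Wilson
    intervals.
    """

    proportions: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame

    @property
    def diseases(self) -> list[str]:
        return list(self.proportions.index)

    def to_dict(self) -> dict:
        return {
            "diseases": self.diseases,
            "proportions": self.proportions.to_dict(),
            "ci_low": self.ci_low.to_dict(),
            "ci_high": self.ci_high.to_dict(),
        }


def cross_disease_matrix(
    disease_tables: dict[str, LabeledDescriptorTable],
    spec: ModelSpec,
    seed: int = 0,
    confidence: float = 0.95,
) -> CrossDiseaseMatrix:
    """Train one model per disease and cross-classify every disease's positives.

    Every disease's table must contain both classes (its dysregulated
    metabolites plus negative controls) and share identical descriptor
    columns. All models use the same spec and training pipeline so
    cells are comparable. Each cell carries a Wilson interval at the
    given confidence.
    """
    names = list(disease_tables)
    if len(names) < 2:
        raise ConfigurationError("cross-disease matrix requires >= 2 diseases")
    ref_cols = disease_tables[names[0]].descriptor_names
    for name in names[1:]:
        if disease_tables[name].descriptor_names != ref_cols:
            raise ConfigurationError(
                f"descriptor columns of {name!r} do not match {names[0]!r}"
            )

    positives = {
        name: table.select_rows(table.labels == 1) for name, table in disease_tables.items()
    }
    prop = pd.DataFrame(index=names, columns=names, dtype=float)
    lo = prop.copy()
    hi = prop.copy()
    for i, row in enumerate(names):
        model = train_final(disease_tables[row], spec, seed=seed + i)
        for col in names:
            p, flags = proportion_flagged(model, positives[col])
            w_lo, w_hi = wilson_interval(int(flags.sum()), flags.size, confidence)
            prop.loc[row, col] = p
            lo.loc[row, col] = w_lo
            hi.loc[row, col] = w_hi
    return CrossDiseaseMatrix(proportions=prop, ci_low=lo, ci_high=hi)
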