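"""Dysregulation screening: Welch t-tests and negative-control assembly.

A metabolite is called *dysregulated* when its abundance differs between
cases and controls by a two-tailed two-sample t-test assuming unequal
variances (Welch), at raw p <= 0.05. No multiple-testing correction is
applied by default — the screen is a recall-oriented candidate filter,
not an inferential endpoint — though Benjamini–Hochberg FDR control is
available behind a flag.

The classifier's negative class is assembled by sampling, uniformly
without replacement, an equal number of metabolites from a reference
library, excluding any that appear in the dysregulated (positive) set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pascdx.errors import ConfigurationError, InsufficientDataError

if TYPE_CHECKING:  # pragma: no cover
    from pascdx.features import LabeledDescriptorTable
    from pascdx.synth import MetaboliteLibrary

__all__ = [
    "CohortMatrix",
    "welch_test",
    "screen_cohort",
    "sample_negative_controls",
    "negative_control_stability",
]


@dataclass
class CohortMatrix:
    """Samples x metabolites abundance table with binary group labels.

    ``data`` is indexed by sample_id with one numeric column per
    metabolite; ``groups`` is an aligned Series with values ``"case"``
    and ``"control"``. Missing abundances are permitted (NaN) and are
    dropped per metabolite at test time; infinite values are not.
    """

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ConfigurationError("duplicate sample_id in cohort")
        if self.data.columns.duplicated().any():
            raise ConfigurationError("duplicate metabolite_id in cohort")
        self.groups = self.groups.reindex(self.data.index)
        if self.groups.isna().any():
            raise ConfigurationError("group label missing for some samples")
        bad = set(self.groups.unique()) - {"case", "control"}
        if bad:
            raise ConfigurationError(f"unrecognized group labels: {sorted(bad)}")
        if (self.groups == "case").sum() == 0 or (self.groups == "control").sum() == 0:
            raise ConfigurationError("both case and control groups must be non-empty")
        values = self.data.to_numpy(dtype=float)
        if np.isinf(values).any():
            raise ConfigurationError("abundance values must be finite (NaN allowed)")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_case(self) -> int:
        return int((self.groups == "case").sum())

    @property
    def n_control(self) -> int:
        return int((self.groups == "control").sum())

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "group", self.groups)
        out.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortMatrix":
        df = pd.read_csv(path, index_col="sample_id")
        if "group" not in df.columns:
            raise ConfigurationError(f"{path}: cohort CSV must contain a 'group' column")
        groups = df.pop("group")
        return cls(data=df.astype(float), groups=groups)


def welch_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Two-tailed two-sample t-test with unequal variances (Welch).

    Returns ``(t, df, p)`` with ``t = (mean(x) - mean(y)) / sqrt(s2x/nx
    + s2y/ny)``, the Welch–Satterthwaite degrees of freedom, and the
    two-tailed p-value from the t distribution. NaN values are dropped.

    Degenerate conventions (both sample variances zero): equal means
    give ``(0, nan, 1)``; unequal means give ``(+/-inf, nan, 0)`` — the
    limit of the statistic as the variances vanish.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise InsufficientDataError(
            f"welch_test needs >=2 finite values per group, got {nx} and {ny}"
        )
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if mx == my:
            return 0.0, math.nan, 1.0
        return math.copysign(math.inf, mx - my), math.nan, 0.0
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _vectorized_welch(
    case: np.ndarray, ctrl: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Welch statistics per column, NaN-aware. Returns (t, df, p, valid)."""
    import warnings

    nx = np.sum(np.isfinite(case), axis=0)
    ny = np.sum(np.isfinite(ctrl), axis=0)
    valid = (nx >= 2) & (ny >= 2)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty slices on invalid cols
        mx = np.nanmean(np.where(np.isfinite(case), case, np.nan), axis=0)
        my = np.nanmean(np.where(np.isfinite(ctrl), ctrl, np.nan), axis=0)
        vx = np.nanvar(case, axis=0, ddof=1)
        vy = np.nanvar(ctrl, axis=0, ddof=1)
        se2 = vx / nx + vy / ny
        t = (mx - my) / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero-variance-both-groups convention
    degen = valid & (se2 == 0)
    eq = degen & (mx == my)
    ne = degen & (mx != my)
    t = np.where(eq, 0.0, t)
    p = np.where(eq, 1.0, p)
    t = np.where(ne, np.sign(mx - my) * np.inf, t)
    p = np.where(ne, 0.0, p)
    df = np.where(degen, np.nan, df)
    t[~valid] = np.nan
    df = np.where(valid, df, np.nan)
    p[~valid] = np.nan
    return t, df, p, valid


def screen_cohort(
    cohort: CohortMatrix, alpha: float = 0.05, fdr: bool = False, log: bool = True
) -> pd.DataFrame:
    """Per-metabolite Welch screen of a cohort.

    Returns a DataFrame indexed by metabolite_id with columns
    ``t_statistic``, ``df``, ``p_value``, ``selected`` and
    ``insufficient_data``. Selection is ``p_value <= alpha`` on the raw
    p-value, or on the Benjamini–Hochberg adjusted p-value when
    ``fdr=True``. Metabolites with fewer than two finite values in
    either group are reported unselected with NaN statistics.

    By default abundances are log-transformed before testing, the usual
    treatment for right-skewed metabolomics intensities (it also keeps
    the t-test close to its nominal level at moderate sample sizes).
    Pass ``log=False`` for data already on a symmetric scale.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ConfigurationError(f"alpha must be in [0, 1], got {alpha}")
    values = cohort.data.to_numpy(dtype=float)
    if log:
        if np.nanmin(values) <= 0:
            raise ConfigurationError(
                "log transform requires strictly positive abundances; "
                "pass log=False for data already on a symmetric scale"
            )
        values = np.log(values)
    case = values[(cohort.groups == "case").to_numpy()]
    ctrl = values[(cohort.groups == "control").to_numpy()]
    t, df, p, valid = _vectorized_welch(case, ctrl)

    p_for_selection = p.copy()
    if fdr:
        from statsmodels.stats.multitest import multipletests

        adj = np.full_like(p, np.nan)
        if valid.any():
            adj[valid] = multipletests(p[valid], method="fdr_bh")[1]
        p_for_selection = adj

    with np.errstate(invalid="ignore"):
        selected = valid & (p_for_selection <= alpha)
    return pd.DataFrame(
        {
            "t_statistic": t,
            "df": df,
            "p_value": p,
            "selected": selected,
            "insufficient_data": ~valid,
        },
        index=pd.Index(cohort.metabolite_ids, name="metabolite_id"),
    )


def sample_negative_controls(
    library: "MetaboliteLibrary | Iterable[str]",
    positives: Iterable[str],
    k: int,
    seed: int,
) -> list[str]:
    """Sample ``k`` negative-control metabolite ids from a library.

    Draws uniformly without replacement from the library excluding the
    positive (disease-dysregulated) ids, so the negative class can never
    contain a known positive. Deterministic given ``seed``; returned
    sorted.
    """
    ids = library.ids if hasattr(library, "ids") else list(library)
    pos = set(positives)
    pool = sorted(set(ids) - pos)
    if k < 0:
        raise ConfigurationError(f"k must be >= 0, got {k}")
    if len(pool) < k:
        raise InsufficientDataError(
            f"negative-control pool has {len(pool)} metabolites after excluding "
            f"{len(pos)} positives; {k} requested (short by {k - len(pool)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=k, replace=False)
    return sorted(pool[i] for i in chosen)


def negative_control_stability(
    table: "LabeledDescriptorTable",
    n_boot: int = 100,
    split: float = 0.9,
    seed: int = 0,
    eval_table: "LabeledDescriptorTable | None" = None,
) -> tuple[float, np.ndarray]:
    """Sensitivity of model accuracy to the negative-control draw.

    Performs one stratified ``split``/(1-``split``) split of ``table``;
    then for each of ``n_boot`` iterations resamples the training-side
    negative controls with replacement, concatenates them with the
    training-side positives, fits a random-forest reference classifier,
    and records accuracy on the held-out side (or on ``eval_table`` if
    given). Returns ``(sd_of_accuracy, per_run_accuracies)``.

    A small SD indicates the pipeline is insensitive to which particular
    background metabolites were drawn as the negative class.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import train_test_split
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    y = table.y
    if len(np.unique(y)) < 2:
        raise ConfigurationError("stability check requires both classes in the table")
    if n_boot < 1:
        raise ConfigurationError(f"n_boot must be >= 1, got {n_boot}")
    X = table.X
    rng = np.random.default_rng(seed)
    idx_train, idx_test = train_test_split(
        np.arange(len(y)),
        train_size=split,
        stratify=y,
        random_state=int(rng.integers(2**31)),
    )
    if eval_table is not None:
        X_eval, y_eval = eval_table.X, eval_table.y
    else:
        X_eval, y_eval = X[idx_test], y[idx_test]

    pos = idx_train[y[idx_train] == 1]
    neg = idx_train[y[idx_train] == 0]
    accuracies = np.empty(n_boot)
    for b in range(n_boot):
        neg_b = rng.choice(neg, size=len(neg), replace=True)
        rows = np.concatenate([pos, neg_b])
        clf = make_pipeline(
            StandardScaler(),
            RandomForestClassifier(n_estimators=100, random_state=int(rng.integers(2**31))),
        )
        clf.fit(X[rows], y[rows])
        accuracies[b] = float(np.mean(clf.predict(X_eval) == y_eval))
    return float(np.std(accuracies, ddof=1)) if n_boot > 1 else 0.0, accuracies
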