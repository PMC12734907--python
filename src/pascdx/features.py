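"""Descriptor-table handling and correlation-based feature selection.

Molecular-descriptor tables (metabolites x numeric descriptors, with a
binary disease-dysregulated/control label) are cleaned and then reduced
by correlation-based feature-subset selection (CFS). CFS scores a
subset S of k features by its *merit*

    Merit(S) = k * r_cf / sqrt(k + k (k - 1) * r_ff)

where r_cf is the mean absolute feature–class correlation over S and
r_ff the mean absolute pairwise feature–feature correlation within S.
The numerator rewards relevance to the class; the denominator penalizes
redundancy among the chosen features. Subsets are searched by forward
best-first search that stops after a fixed number of consecutive
non-improving expansions.

Correlations are Pearson on the continuous descriptors with the class
encoded 0/1 (point-biserial), taken in absolute value; a symmetric-
uncertainty variant with equal-frequency discretization is available
for sensitivity analysis via ``correlation="symmetric_uncertainty"``.
"""

from __future__ import annotations

import heapq
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from pascdx.errors import ConfigurationError, InsufficientDataError

__all__ = [
    "LabeledDescriptorTable",
    "CleaningReport",
    "FeatureSubset",
    "clean_descriptor_table",
    "CfsScorer",
    "cfs_merit",
    "best_first_select",
    "exhaustive_select",
    "compute_descriptors_from_smiles",
]


@dataclass
class LabeledDescriptorTable:
    """Metabolites x descriptors numeric matrix with a binary class label.

    ``descriptors`` is indexed by metabolite_id; ``labels`` is aligned
    with values 1 (disease-dysregulated) and 0 (negative control).
    """

    descriptors: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.descriptors.index.duplicated().any():
            raise ConfigurationError("duplicate metabolite_id in descriptor table")
        if self.descriptors.columns.duplicated().any():
            raise ConfigurationError("duplicate descriptor name in table")
        self.labels = self.labels.reindex(self.descriptors.index)
        if self.labels.isna().any():
            raise ConfigurationError("label missing for some metabolites")
        if not set(np.unique(self.labels)).issubset({0, 1}):
            raise ConfigurationError("labels must be binary 0/1")

    @property
    def X(self) -> np.ndarray:
        return self.descriptors.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=int)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.descriptors.columns)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.descriptors.index)

    def __len__(self) -> int:
        return len(self.descriptors)

    def select_columns(self, names_or_indices: Sequence) -> "LabeledDescriptorTable":
        cols = [
            self.descriptors.columns[i] if isinstance(i, (int, np.integer)) else i
            for i in names_or_indices
        ]
        return LabeledDescriptorTable(self.descriptors[cols].copy(), self.labels.copy())

    def select_rows(self, mask_or_ids) -> "LabeledDescriptorTable":
        sub = self.descriptors.loc[mask_or_ids]
        return LabeledDescriptorTable(sub.copy(), self.labels.loc[sub.index].copy())

    def to_csv(self, path: str | Path) -> None:
        out = self.descriptors.copy()
        out.insert(0, "label", self.labels)
        out.to_csv(path, index_label="metabolite_id")

    @classmethod
    def from_csv(cls, path: str | Path, label_column: str = "label") -> "LabeledDescriptorTable":
        df = pd.read_csv(path, index_col="metabolite_id")
        if label_column not in df.columns:
            raise ConfigurationError(f"{path}: missing label column '{label_column}'")
        labels = df.pop(label_column).astype(int)
        return cls(descriptors=df.astype(float), labels=labels)


@dataclass
class CleaningReport:
    """Columns dropped during cleaning, with the reason for each."""

    dropped: list[tuple[str, str]] = field(default_factory=list)
    imputed: dict[str, int] = field(default_factory=dict)

    def summary(self) -> str:
        by_reason: dict[str, int] = {}
        for _, reason in self.dropped:
            by_reason[reason] = by_reason.get(reason, 0) + 1
        parts = [f"{n} columns dropped ({reason})" for reason, n in sorted(by_reason.items())]
        parts.append(f"{len(self.imputed)} columns median-imputed")
        return "; ".join(parts)


def clean_descriptor_table(
    descriptors: pd.DataFrame,
    labels: pd.Series,
    max_missing_frac: float = 0.1,
) -> tuple[LabeledDescriptorTable, CleaningReport]:
    """Clean a raw descriptor table into analysis-ready form.

    Descriptor-generation tools emit inapplicable-descriptor codes that
    parse as missing values, and many descriptors are constant over any
    given metabolite set. Cleaning: (1) drop columns whose missing
    fraction exceeds ``max_missing_frac``; (2) median-impute remaining
    missing cells; (3) drop zero-variance columns. Every dropped column
    is recorded with its reason.
    """
    df = descriptors.apply(pd.to_numeric, errors="coerce").astype(float)
    report = CleaningReport()

    missing_frac = df.isna().mean()
    too_missing = missing_frac[missing_frac > max_missing_frac].index
    for col in too_missing:
        report.dropped.append((str(col), f"missing fraction {missing_frac[col]:.3f}"))
    df = df.drop(columns=too_missing)

    for col in df.columns[df.isna().any()]:
        n_missing = int(df[col].isna().sum())
        df[col] = df[col].fillna(df[col].median())
        report.imputed[str(col)] = n_missing

    variances = df.var(ddof=0)
    constant = variances[variances == 0.0].index
    for col in constant:
        report.dropped.append((str(col), "zero variance"))
    df = df.drop(columns=constant)

    if df.shape[1] == 0:
        raise InsufficientDataError(
            f"cleaning dropped all {descriptors.shape[1]} descriptor columns"
        )
    return LabeledDescriptorTable(descriptors=df, labels=labels.astype(int)), report


def _symmetric_uncertainty(x: np.ndarray, y: np.ndarray, n_bins: int = 10) -> float:
    """SU(X,Y) = 2 I(X;Y) / (H(X) + H(Y)) with equal-frequency binning of x."""
    ranks = pd.qcut(pd.Series(x).rank(method="first"), q=min(n_bins, len(x)), labels=False)
    xd = np.asarray(ranks)
    joint = pd.crosstab(xd, y).to_numpy().astype(float)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    hx = -np.sum(px[px > 0] * np.log2(px[px > 0]))
    hy = -np.sum(py[py > 0] * np.log2(py[py > 0]))
    nz = pxy > 0
    mi = np.sum(pxy[nz] * np.log2(pxy[nz] / np.outer(px, py)[nz]))
    denom = hx + hy
    return float(2.0 * mi / denom) if denom > 0 else 0.0


class CfsScorer:
    """Precomputed CFS correlations for fast subset-merit evaluation.

    Precomputes the absolute feature–class correlation vector and the
    absolute feature–feature correlation matrix once, so each call to
    :meth:`merit` is O(k^2) in the subset size. This is what makes both
    the best-first search and exhaustive brute-force verification cheap.
    """

    def __init__(self, table: LabeledDescriptorTable, correlation: str = "pearson"):
        X = table.X
        y = table.y.astype(float)
        if X.shape[1] == 0:
            raise InsufficientDataError("descriptor table has no columns")
        if np.any(X.std(axis=0) == 0):
            raise ConfigurationError(
                "zero-variance descriptor column; clean the table first"
            )
        if correlation == "pearson":
            Z = (X - X.mean(axis=0)) / X.std(axis=0)
            yc = y - y.mean()
            y_sd = yc.std()
            if y_sd == 0:
                raise ConfigurationError("class label is constant")
            self.r_cf = np.abs(Z.T @ (yc / y_sd)) / X.shape[0]
            self.r_ff = np.abs(np.corrcoef(Z, rowvar=False))
            if self.r_ff.ndim == 0:  # single feature
                self.r_ff = np.ones((1, 1))
        elif correlation == "symmetric_uncertainty":
            p = X.shape[1]
            self.r_cf = np.array(
                [_symmetric_uncertainty(X[:, j], table.y) for j in range(p)]
            )
            self.r_ff = np.ones((p, p))
            for i in range(p):
                xi = np.asarray(
                    pd.qcut(pd.Series(X[:, i]).rank(method="first"),
                            q=min(10, len(y)), labels=False)
                )
                for j in range(i + 1, p):
                    su = _symmetric_uncertainty(X[:, j], xi)
                    self.r_ff[i, j] = self.r_ff[j, i] = su
        else:
            raise ConfigurationError(f"unknown correlation measure: {correlation}")
        self.n_features = X.shape[1]

    def merit(self, subset: Sequence[int]) -> float:
        idx = np.asarray(list(subset), dtype=int)
        k = idx.size
        if k == 0:
            raise ConfigurationError("CFS merit is undefined for the empty subset")
        if idx.min() < 0 or idx.max() >= self.n_features or len(set(idx.tolist())) != k:
            raise ConfigurationError("subset indices must be unique and in range")
        rcf = self.r_cf[idx].mean()
        if k == 1:
            return float(rcf)
        sub = self.r_ff[np.ix_(idx, idx)]
        rff = (sub.sum() - k) / (k * (k - 1))
        return float(k * rcf / np.sqrt(k + k * (k - 1) * rff))


def cfs_merit(
    table: LabeledDescriptorTable,
    subset: Sequence[int],
    correlation: str = "pearson",
) -> float:
    """CFS merit of a descriptor subset (indices into the table's columns)."""
    return CfsScorer(table, correlation=correlation).merit(subset)


@dataclass
class FeatureSubset:
    """Result of a feature-subset search."""

    indices: tuple[int, ...]
    merit: float
    search_trace: list[tuple[int, float]] = field(default_factory=list)
    descriptor_names: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        """Write the selected descriptor names (one per line) plus a JSON sidecar."""
        path = Path(path)
        path.write_text("\n".join(self.descriptor_names) + "\n")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "indices": list(self.indices),
                    "merit": self.merit,
                    "search_trace": [[int(s), float(m)] for s, m in self.search_trace],
                    "descriptor_names": self.descriptor_names,
                },
                indent=2,
            )
        )


def best_first_select(
    table: LabeledDescriptorTable,
    stale_limit: int = 5,
    correlation: str = "pearson",
    max_subset_size: int | None = None,
) -> FeatureSubset:
    """Forward best-first search for the maximum-merit descriptor subset.

    Maintains an open list of subsets ordered by merit; repeatedly
    expands the best open subset by adding each unused feature, and
    terminates after ``stale_limit`` consecutive expansions that fail to
    improve the best merit seen. Deterministic: merit ties are broken by
    the lexicographically smallest sorted index tuple.

    Returns the best subset encountered anywhere in the search.
    """
    scorer = CfsScorer(table, correlation=correlation)
    p = scorer.n_features
    if stale_limit < 1:
        raise ConfigurationError(f"stale_limit must be >= 1, got {stale_limit}")
    cap = p if max_subset_size is None else min(p, max_subset_size)

    # heap entries: (-merit, sorted index tuple); tuple order breaks ties
    # toward lower indices.
    start = ()
    open_heap: list[tuple[float, tuple[int, ...]]] = [(0.0, start)]
    seen: set[tuple[int, ...]] = {start}
    best_subset: tuple[int, ...] = ()
    best_merit = 0.0
    trace: list[tuple[int, float]] = []
    stale = 0

    while open_heap and stale < stale_limit:
        neg_merit, subset = heapq.heappop(open_heap)
        improved = False
        if len(subset) < cap:
            members = set(subset)
            for j in range(p):
                if j in members:
                    continue
                # a feature perfectly correlated with a current member is
                # strictly redundant: it contributes no information beyond
                # its correlate, so it is never added alongside it
                if members and np.any(scorer.r_ff[j, list(members)] >= 1.0 - 1e-12):
                    continue
                child = tuple(sorted(subset + (j,)))
                if child in seen:
                    continue
                seen.add(child)
                m = scorer.merit(child)
                trace.append((len(child), m))
                heapq.heappush(open_heap, (-m, child))
                if m > best_merit or (m == best_merit and best_subset and child < best_subset):
                    if m > best_merit:
                        improved = True
                    best_merit = m
                    best_subset = child
        stale = 0 if improved else stale + 1

    if not best_subset:  # pathological: all merits zero; keep the single best feature
        j = int(np.argmax(scorer.r_cf))
        best_subset = (j,)
        best_merit = scorer.merit(best_subset)
    names = [table.descriptor_names[i] for i in best_subset]
    return FeatureSubset(
        indices=best_subset, merit=best_merit, search_trace=trace, descriptor_names=names
    )


def exhaustive_select(
    table: LabeledDescriptorTable, correlation: str = "pearson", max_features: int = 20
) -> FeatureSubset:
    """Exhaustive maximum-merit search over all admissible subsets.

    Enumerates every non-empty subset containing no perfectly correlated
    feature pair — the same feasible family the best-first search
    explores, since a perfect correlate of a subset member carries no
    additional information. Exponential in the feature count; guarded to
    ``max_features``. Used as the ground-truth oracle against which the
    best-first heuristic is validated on small tables.
    """
    scorer = CfsScorer(table, correlation=correlation)
    p = scorer.n_features
    if p > max_features:
        raise ConfigurationError(
            f"exhaustive search limited to {max_features} features, table has {p}"
        )
    degenerate = scorer.r_ff >= 1.0 - 1e-12
    np.fill_diagonal(degenerate, False)
    best_subset: tuple[int, ...] | None = None
    best_merit = -np.inf
    for k in range(1, p + 1):
        for combo in itertools.combinations(range(p), k):
            if k > 1 and degenerate[np.ix_(combo, combo)].any():
                continue
            m = scorer.merit(combo)
            if m > best_merit or (m == best_merit and combo < best_subset):
                best_merit = m
                best_subset = combo
    names = [table.descriptor_names[i] for i in best_subset]
    return FeatureSubset(indices=best_subset, merit=float(best_merit),
                         descriptor_names=names)


def compute_descriptors_from_smiles(
    smiles: pd.DataFrame, smiles_column: str = "smiles", id_column: str = "metabolite_id"
) -> pd.DataFrame:
    """Compute a stand-in molecular-descriptor table from SMILES strings.

    Uses the RDKit descriptor catalogue (~200 descriptors) as a local
    substitute descriptor set. Output schema matches the descriptor-CSV
    convention: one row per metabolite_id, named numeric columns.
    Unparseable SMILES raise with the offending id.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import Descriptors
    except ImportError as exc:  # pragma: no cover
        raise ImportError("RDKit is required for descriptor computation") from exc

    rows = {}
    for _, rec in smiles.iterrows():
        mol = Chem.MolFromSmiles(str(rec[smiles_column]))
        if mol is None:
            raise ConfigurationError(
                f"unparseable SMILES for {rec[id_column]}: {rec[smiles_column]!r}"
            )
        rows[rec[id_column]] = Descriptors.CalcMolDescriptors(mol)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = id_column
    return out
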