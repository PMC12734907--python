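"""Synthetic cohorts, metabolite libraries and descriptor tables.

The generator emulates the statistical structure the diagnostic chain
assumes, at configurable scale:

* **Cohorts** — case/control abundance matrices. Abundances are
  log-normal (metabolomics intensities are right-skewed); a planted set
  of "dysregulated" metabolites has its case-group mean shifted on the
  log scale by a configurable number of within-group SD units, with a
  random sign per metabolite. Ground truth is always returned beside the
  data so parameter-recovery tests are possible.
* **Descriptor tables** — metabolite x descriptor matrices in which a
  subset of "informative" columns carries a class-conditional mean shift
  for disease-dysregulated metabolites, and the rest are class-independent
  standard-normal noise. Two diseases can share a controllable fraction
  (``overlap``) of their informative columns, which reproduces both the
  mutually-confusable regime (overlap = 1: the two diseases' descriptor
  signatures are identical) and the well-separated regime (overlap = 0).
* **Libraries** — metabolite id/name/SMILES records standing in for a
  reference metabolite compendium, used as the negative-control pool.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from pascdx.errors import ConfigurationError
from pascdx.screen import CohortMatrix
from pascdx.features import LabeledDescriptorTable

__all__ = [
    "SynthConfig",
    "MetaboliteLibrary",
    "generate_library",
    "generate_cohort",
    "disease_signature",
    "generate_descriptor_table",
    "generate_disease_tables",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    The defaults describe a mid-sized two-arm metabolomics study: 50
    cases and 50 controls profiled over 500 metabolites, of which 120
    are dysregulated with a 1.5-SD log-scale shift; each metabolite has
    200 molecular descriptors of which 20 carry the disease signature
    with a 0.8-SD class-conditional shift.

    Parameters
    ----------
    n_case, n_control
        Sample counts per group.
    n_metabolites
        Number of profiled metabolites.
    n_dysregulated
        Number of planted case-shifted metabolites.
    effect_size
        Case-group mean shift of planted metabolites, in within-group SD
        units on the log scale.
    n_descriptors
        Number of numeric molecular descriptors per metabolite.
    n_informative
        Number of descriptor columns carrying the class signal.
    descriptor_shift
        Class-conditional mean difference of informative columns, in SD
        units.
    overlap
        Fraction in [0, 1] of a second disease's informative columns
        shared with the first disease's signature.
    block_rho
        Optional equicorrelation within consecutive blocks of
        ``block_size`` descriptor columns (default 0: independent
        columns, which keeps analytic oracles tractable).
    block_size
        Block width used when ``block_rho > 0``.
    seed
        RNG seed; regeneration with the same config is bit-identical.
    """

    n_case: int = 50
    n_control: int = 50
    n_metabolites: int = 500
    n_dysregulated: int = 120
    effect_size: float = 1.5
    n_descriptors: int = 200
    n_informative: int = 20
    descriptor_shift: float = 0.8
    overlap: float = 0.0
    block_rho: float = 0.0
    block_size: int = 5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_case", "n_control", "n_metabolites", "n_descriptors"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0 <= self.n_dysregulated <= self.n_metabolites:
            raise ConfigurationError(
                f"n_dysregulated={self.n_dysregulated} exceeds n_metabolites={self.n_metabolites}"
            )
        if not 0 <= self.n_informative <= self.n_descriptors:
            raise ConfigurationError(
                f"n_informative={self.n_informative} exceeds n_descriptors={self.n_descriptors}"
            )
        if not 0.0 <= self.overlap <= 1.0:
            raise ConfigurationError(f"overlap must be in [0, 1], got {self.overlap}")
        if not 0.0 <= self.block_rho < 1.0:
            raise ConfigurationError(f"block_rho must be in [0, 1), got {self.block_rho}")

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class MetaboliteLibrary:
    """Reference metabolite records: id, name and optional SMILES."""

    records: pd.DataFrame  # columns: metabolite_id, name, smiles

    def __post_init__(self) -> None:
        required = {"metabolite_id", "name"}
        missing = required - set(self.records.columns)
        if missing:
            raise ConfigurationError(f"library missing columns: {sorted(missing)}")
        if self.records.empty:
            raise ConfigurationError("library must be non-empty")
        if self.records["metabolite_id"].duplicated().any():
            dup = self.records.loc[self.records["metabolite_id"].duplicated(), "metabolite_id"]
            raise ConfigurationError(f"duplicate metabolite_id in library: {sorted(set(dup))[:5]}")

    @property
    def ids(self) -> list[str]:
        return list(self.records["metabolite_id"])

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MetaboliteLibrary":
        return cls(pd.read_csv(path, dtype={"metabolite_id": str}))


# SMILES fragments concatenated into valid linear molecules: simple
# carbon chains with ether/amine/hydroxyl/carbonyl substitutions.
_SMILES_FRAGMENTS = ["C", "CC", "CO", "CN", "C(=O)", "C(C)", "CCO", "CC(=O)O", "CCN"]


def generate_library(
    n: int, seed: int = 0, prefix: str = "LIB", with_smiles: bool = True
) -> MetaboliteLibrary:
    """Generate a synthetic metabolite library of ``n`` records.

    SMILES strings, when requested, are random concatenations of small
    valid fragments — chemically plausible linear molecules sufficient
    for exercising descriptor-computation code paths.
    """
    if n < 1:
        raise ConfigurationError(f"library size must be positive, got {n}")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n)))
    ids = [f"{prefix}{i:0{width}d}" for i in range(n)]
    names = [f"metabolite-{i}" for i in range(n)]
    if with_smiles:
        smiles = [
            "".join(rng.choice(_SMILES_FRAGMENTS, size=rng.integers(2, 7)))
            for _ in range(n)
        ]
    else:
        smiles = [""] * n
    return MetaboliteLibrary(
        pd.DataFrame({"metabolite_id": ids, "name": names, "smiles": smiles})
    )


def generate_cohort(config: SynthConfig) -> tuple[CohortMatrix, list[str]]:
    """Generate a case/control abundance matrix with planted shifts.

    Log-abundances are normal with per-metabolite baseline means drawn
    from N(10, 2^2) — intensities spanning a few orders of magnitude —
    and unit within-group SD. Exactly ``n_dysregulated`` metabolites
    have the case-group log-mean shifted by ``effect_size`` SD, with a
    random sign per metabolite.

    Returns
    -------
    (cohort, dysregulated_ids)
        The cohort and the exact set of planted metabolite ids.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_metabolites
    met_ids = [f"M{i:05d}" for i in range(m)]

    baseline = rng.normal(10.0, 2.0, size=m)
    dys_idx = rng.choice(m, size=config.n_dysregulated, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.n_dysregulated)

    n_total = config.n_case + config.n_control
    log_abund = rng.normal(0.0, 1.0, size=(n_total, m)) + baseline
    # first n_case rows are cases; shift their planted metabolites
    log_abund[: config.n_case, dys_idx] += signs * config.effect_size

    sample_ids = [f"case_{i:03d}" for i in range(config.n_case)] + [
        f"ctrl_{i:03d}" for i in range(config.n_control)
    ]
    groups = pd.Series(
        ["case"] * config.n_case + ["control"] * config.n_control,
        index=sample_ids,
        name="group",
    )
    data = pd.DataFrame(np.exp(log_abund), index=pd.Index(sample_ids, name="sample_id"),
                        columns=met_ids)
    truth = sorted(met_ids[i] for i in dys_idx)
    return CohortMatrix(data=data, groups=groups), truth


def disease_signature(config: SynthConfig, disease_index: int = 0) -> np.ndarray:
    """Informative descriptor columns for the ``disease_index``-th disease.

    Disease 0 uses columns ``0 .. n_informative-1``. Each subsequent
    disease shares the first ``round(overlap * n_informative)`` of
    disease 0's columns and takes the remainder from fresh, previously
    unused columns. Raises if the descriptor space cannot host the
    requested number of distinct signatures.
    """
    config.validate()
    k = config.n_informative
    if disease_index == 0:
        return np.arange(k)
    n_shared = int(round(config.overlap * k))
    n_fresh = k - n_shared
    start = k + (disease_index - 1) * n_fresh
    if start + n_fresh > config.n_descriptors:
        raise ConfigurationError(
            f"n_descriptors={config.n_descriptors} too small for disease "
            f"{disease_index} signature with overlap={config.overlap}"
        )
    return np.concatenate([np.arange(n_shared), np.arange(start, start + n_fresh)]).astype(int)


def _noise_matrix(rng: np.random.Generator, n: int, p: int, config: SynthConfig) -> np.ndarray:
    """Standard-normal noise, optionally block-equicorrelated."""
    z = rng.normal(size=(n, p))
    if config.block_rho <= 0:
        return z
    rho, b = config.block_rho, config.block_size
    out = np.empty_like(z)
    for start in range(0, p, b):
        stop = min(start + b, p)
        shared = rng.normal(size=(n, 1))
        out[:, start:stop] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * z[:, start:stop]
    return out


def generate_descriptor_table(
    library: MetaboliteLibrary,
    class_labels: pd.Series | np.ndarray,
    config: SynthConfig,
    disease_index: int = 0,
    rng: np.random.Generator | None = None,
) -> LabeledDescriptorTable:
    """Generate a labeled molecular-descriptor table for a library.

    Columns in the disease's signature (see :func:`disease_signature`)
    have their mean raised by ``descriptor_shift`` for metabolites
    labeled 1; all other columns are class-independent noise.

    ``rng`` may be passed to draw from an existing stream (e.g. when
    generating several diseases' tables from one seed); by default a
    fresh stream is derived from ``config.seed`` and ``disease_index``.
    """
    config.validate()
    labels = np.asarray(class_labels).astype(int)
    if labels.shape[0] != len(library):
        raise ConfigurationError(
            f"labels cover {labels.shape[0]} metabolites, library has {len(library)}"
        )
    if not np.isin(labels, [0, 1]).all():
        raise ConfigurationError("class labels must be binary 0/1")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1 + disease_index])
        )
    n, p = len(library), config.n_descriptors
    X = _noise_matrix(rng, n, p, config)
    sig = disease_signature(config, disease_index)
    X[np.ix_(labels == 1, sig)] += config.descriptor_shift

    names = [f"D{j:04d}" for j in range(p)]
    df = pd.DataFrame(X, index=pd.Index(library.ids, name="metabolite_id"), columns=names)
    return LabeledDescriptorTable(
        descriptors=df, labels=pd.Series(labels, index=df.index, name="label")
    )


def generate_disease_tables(
    config: SynthConfig,
    n_diseases: int = 2,
    n_positive: int | None = None,
    library: MetaboliteLibrary | None = None,
) -> dict[str, LabeledDescriptorTable]:
    """Generate one balanced labeled descriptor table per disease.

    Each disease gets ``n_positive`` dysregulated metabolites (default:
    ``config.n_dysregulated``) drawn from a shared library plus an equal
    number of negative controls, disjoint from every disease's positives.
    All tables share the same descriptor columns, as the cross-disease
    analysis requires.
    """
    config.validate()
    if n_diseases < 1:
        raise ConfigurationError("n_diseases must be >= 1")
    k = n_positive if n_positive is not None else config.n_dysregulated
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 9000]))
    if library is None:
        library = generate_library(max(2 * k * (n_diseases + 1), 4 * k),
                                   seed=config.seed, prefix="HMDB")
    all_ids = np.array(library.ids)
    perm = rng.permutation(len(all_ids))
    tables: dict[str, LabeledDescriptorTable] = {}
    cursor = 0
    for d in range(n_diseases):
        pos_ids = all_ids[perm[cursor: cursor + k]]
        cursor += k
        neg_ids = all_ids[perm[cursor: cursor + k]]
        cursor += k
        ids = np.concatenate([pos_ids, neg_ids])
        sub = MetaboliteLibrary(
            library.records.set_index("metabolite_id").loc[ids].reset_index()
        )
        labels = np.concatenate([np.ones(k, int), np.zeros(k, int)])
        tables[f"disease_{chr(ord('A') + d)}"] = generate_descriptor_table(
            sub, labels, config, disease_index=d, rng=rng
        )
    return tables


def write_truth(path: str | Path, ids: list[str]) -> None:
    """Write a ground-truth metabolite id list, one id per line."""
    Path(path).write_text("\n".join(ids) + "\n")


def read_truth(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
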