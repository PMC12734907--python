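"""End-to-end pipeline orchestration.

``run_pipeline`` binds the stages together — screen -> negative
controls -> descriptors -> feature selection -> model CV -> set-level
diagnosis -> threshold — under a single :class:`RunConfig` with one
global seed. Per-stage randomness is derived from the global seed by
stage name (:mod:`pascdx.seeds`), so adding, removing or reordering
unrelated stages leaves each stage's draws unchanged.

Two input modes are supported per run: fully synthetic (a
:class:`~pascdx.synth.SynthConfig` block) or file-based (cohort,
descriptor and library CSVs following the package's CSV schemas).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from pascdx.errors import ConfigurationError
from pascdx.seeds import stage_seed
from pascdx import synth as _synth
from pascdx.synth import MetaboliteLibrary, SynthConfig
from pascdx.screen import (
    CohortMatrix,
    negative_control_stability,
    sample_negative_controls,
    screen_cohort,
)
from pascdx.features import (
    LabeledDescriptorTable,
    best_first_select,
    clean_descriptor_table,
)
from pascdx.modeling import ModelSpec, cross_validate, train_final
from pascdx.diagnosis import (
    bootstrap_proportion,
    cross_disease_matrix,
    determine_threshold,
    proportion_flagged,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run.

    Exactly one input mode must be set: ``synth`` (synthetic study) or
    the triple ``cohort_csv``/``descriptor_csv``/``library_csv``.
    """

    seed: int
    output_dir: str | Path | None = None
    synth: SynthConfig | None = None
    cohort_csv: str | Path | None = None
    descriptor_csv: str | Path | None = None
    library_csv: str | Path | None = None
    comparator_csv: str | Path | None = None  # labeled descriptor CSV
    alpha: float = 0.05
    model_family: str = "MLP"
    model_grid: dict[str, list] | None = None
    cv_folds: int = 5
    cv_repeats: int = 10
    n_boot_set: int = 500
    n_boot_stability: int = 100
    c_step: float = 0.001
    run_crossmat: bool = True
    run_stability: bool = True

    def validate(self) -> None:
        synthetic = self.synth is not None
        file_based = self.cohort_csv is not None
        if synthetic == file_based:
            raise ConfigurationError(
                "exactly one of a synth block or cohort/descriptor/library CSV "
                "paths must be configured"
            )
        if file_based and (self.descriptor_csv is None or self.library_csv is None):
            raise ConfigurationError(
                "file-based runs need cohort_csv, descriptor_csv and library_csv"
            )
        for attr in ("cohort_csv", "descriptor_csv", "library_csv", "comparator_csv"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"{attr}: file not found: {path}")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        if raw.get("synth") is not None and not isinstance(raw["synth"], SynthConfig):
            raw["synth"] = SynthConfig(**raw["synth"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolved(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        for key, value in out.items():
            if isinstance(value, Path):
                out[key] = str(value)
        return out


def _log(stage: str, seed: int, t0: float) -> None:
    print(
        json.dumps(
            {"stage": stage, "seed": seed, "elapsed_s": round(time.perf_counter() - t0, 3)}
        )
    )


def _build_synthetic_inputs(
    cfg: RunConfig,
) -> tuple[CohortMatrix, list[str], MetaboliteLibrary, dict[str, LabeledDescriptorTable]]:
    sc = cfg.synth.replace(seed=stage_seed(cfg.seed, "synth"))
    cohort, truth = _synth.generate_cohort(sc)
    # Library: cohort metabolites plus background pool for negative controls
    # and an independent test disease pool.
    pool = _synth.generate_library(
        4 * sc.n_metabolites, seed=stage_seed(cfg.seed, "library"), prefix="HMDB"
    )
    met_records = pd.DataFrame(
        {
            "metabolite_id": cohort.metabolite_ids,
            "name": [f"cohort-{m}" for m in cohort.metabolite_ids],
            "smiles": "",
        }
    )
    library = MetaboliteLibrary(
        pd.concat([met_records, pool.records], ignore_index=True)
    )
    return cohort, truth, library, {}


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full diagnostic chain and return the run report.

    The report is a JSON-serializable dict containing the screen
    summary, selected descriptors, CV report, stability check,
    independent-set diagnosis, threshold result and (optionally) the
    cross-disease matrix, plus the exact resolved configuration. When
    ``config.output_dir`` is set the report and key artifacts are also
    written there.
    """
    config.validate()
    t0 = time.perf_counter()
    report: dict[str, Any] = {"config": config.resolved(), "stages": {}}
    synthetic = config.synth is not None

    # -- stage: inputs -------------------------------------------------
    if synthetic:
        cohort, truth, library, _ = _build_synthetic_inputs(config)
        report["stages"]["inputs"] = {
            "mode": "synthetic",
            "n_case": cohort.n_case,
            "n_control": cohort.n_control,
            "n_metabolites": len(cohort.metabolite_ids),
            "n_planted": len(truth),
        }
    else:
        cohort = CohortMatrix.from_csv(config.cohort_csv)
        library = MetaboliteLibrary.from_csv(config.library_csv)
        truth = None
        report["stages"]["inputs"] = {
            "mode": "files",
            "n_case": cohort.n_case,
            "n_control": cohort.n_control,
            "n_metabolites": len(cohort.metabolite_ids),
        }
    _log("inputs", config.seed, t0)

    # -- stage: screen -------------------------------------------------
    screen = screen_cohort(cohort, alpha=config.alpha)
    positives = sorted(screen.index[screen["selected"]])
    if not positives:
        raise ConfigurationError("screen selected no metabolites; nothing to model")
    stage_report: dict[str, Any] = {
        "n_tested": int(len(screen)),
        "n_selected": len(positives),
        "alpha": config.alpha,
    }
    if truth is not None:
        stage_report["n_planted_recovered"] = len(set(positives) & set(truth))
    report["stages"]["screen"] = stage_report
    _log("screen", stage_seed(config.seed, "screen"), t0)

    # -- stage: negative controls + descriptor table -------------------
    neg_seed = stage_seed(config.seed, "negative_controls")
    negatives = sample_negative_controls(library, positives, len(positives), seed=neg_seed)
    ids = list(positives) + list(negatives)
    labels = pd.Series(
        [1] * len(positives) + [0] * len(negatives), index=ids, name="label"
    )
    if synthetic:
        sub = MetaboliteLibrary(
            library.records.set_index("metabolite_id").loc[ids].reset_index()
        )
        desc_cfg = config.synth.replace(seed=stage_seed(config.seed, "descriptors"))
        raw_table = _synth.generate_descriptor_table(sub, labels.to_numpy(), desc_cfg)
        raw = raw_table.descriptors
    else:
        desc = pd.read_csv(config.descriptor_csv, index_col="metabolite_id")
        missing = [m for m in ids if m not in desc.index]
        if missing:
            raise ConfigurationError(
                f"descriptor table missing {len(missing)} metabolites, e.g. {missing[:3]}"
            )
        raw = desc.loc[ids]
    table, cleaning = clean_descriptor_table(raw, labels)
    report["stages"]["descriptors"] = {
        "n_metabolites": len(table),
        "n_descriptors_raw": int(raw.shape[1]),
        "n_descriptors_clean": len(table.descriptor_names),
        "cleaning": cleaning.summary(),
    }
    _log("descriptors", neg_seed, t0)

    # -- stage: feature selection --------------------------------------
    subset = best_first_select(table)
    reduced = table.select_columns(subset.indices)
    report["stages"]["feature_selection"] = {
        "n_selected": len(subset.indices),
        "merit": subset.merit,
        "descriptors": subset.descriptor_names,
    }
    _log("feature_selection", 0, t0)

    # -- stage: stability of negative-control draw ---------------------
    if config.run_stability:
        sd, accs = negative_control_stability(
            reduced,
            n_boot=config.n_boot_stability,
            seed=stage_seed(config.seed, "stability"),
        )
        report["stages"]["stability"] = {
            "sd_accuracy": sd,
            "mean_accuracy": float(np.mean(accs)),
            "n_boot": config.n_boot_stability,
        }
        _log("stability", stage_seed(config.seed, "stability"), t0)

    # -- stage: cross-validated modeling -------------------------------
    spec = ModelSpec(
        family=config.model_family,
        grid=config.model_grid,
        seed=stage_seed(config.seed, "model"),
    )
    cv = cross_validate(
        reduced,
        spec,
        n_folds=config.cv_folds,
        n_repeats=config.cv_repeats,
        seed=stage_seed(config.seed, "cv"),
    )
    report["stages"]["cross_validation"] = cv.to_dict()
    _log("cross_validation", stage_seed(config.seed, "cv"), t0)

    model = train_final(reduced, spec, seed=stage_seed(config.seed, "final_fit"))

    # -- stage: independent evaluation + threshold ---------------------
    if synthetic:
        eval_cfg = config.synth.replace(seed=stage_seed(config.seed, "independent"))
        eval_tables = _synth.generate_disease_tables(
            eval_cfg, n_diseases=2, n_positive=len(positives)
        )
        independent = eval_tables["disease_A"].select_columns(subset.descriptor_names)
        comparator = eval_tables["disease_B"].select_columns(subset.descriptor_names)
    else:
        independent = None
        comparator = (
            LabeledDescriptorTable.from_csv(config.comparator_csv).select_columns(
                subset.descriptor_names
            )
            if config.comparator_csv
            else None
        )

    if independent is not None:
        from pascdx.modeling import roc_auc

        ind_scores = model.score(independent)
        ind_auc = roc_auc(ind_scores, independent.y)
        ind_pos = independent.select_rows(independent.labels == 1)
        p_ref, flags_ref = proportion_flagged(model, ind_pos)
        diag_ref = bootstrap_proportion(
            flags_ref, n_boot=config.n_boot_set,
            seed=stage_seed(config.seed, "bootstrap_reference"),
        )
        report["stages"]["independent_evaluation"] = {
            "auc": float(ind_auc),
            "reference_set": diag_ref.to_dict(),
        }
        _log("independent_evaluation", stage_seed(config.seed, "bootstrap_reference"), t0)

        if comparator is not None:
            comp_pos = comparator.select_rows(comparator.labels == 1)
            p_comp, flags_comp = proportion_flagged(model, comp_pos)
            diag_comp = bootstrap_proportion(
                flags_comp, n_boot=config.n_boot_set,
                seed=stage_seed(config.seed, "bootstrap_comparator"),
            )
            thr = determine_threshold(
                diag_ref.bootstrap_values, diag_comp.bootstrap_values, c_step=config.c_step
            )
            report["stages"]["threshold"] = {
                "comparator_set": diag_comp.to_dict(),
                "result": thr.to_dict(),
            }
            _log("threshold", 0, t0)

    # -- stage: cross-disease matrix -----------------------------------
    if synthetic and config.run_crossmat:
        # Each disease's model is trained on the full descriptor space so
        # its own signature is available to it regardless of which columns
        # the reference disease's feature selection kept.
        mat = cross_disease_matrix(
            eval_tables, spec, seed=stage_seed(config.seed, "crossmat")
        )
        report["stages"]["cross_disease_matrix"] = mat.to_dict()
        _log("crossmat", stage_seed(config.seed, "crossmat"), t0)

    # -- artifacts ------------------------------------------------------
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        screen.to_csv(out / "screen.csv")
        subset.write(out / "selected_descriptors.txt")
    return report
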