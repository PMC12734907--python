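#!/usr/bin/env python
"""Benchmark the classifier suite by repeated stratified 5-fold CV.

Cross-validates all five families on the CFS-selected descriptor table
and writes a performance table (mean AUC-ROC with the middle-95%
interval of the repeat x fold AUCs). Three CV repeats per family keep
the grid-searched families quick; the MLP — the family carried forward
— is also run at the full ten repeats.
"""

from pathlib import Path

import pandas as pd

from analysis_common import MLP_GRID, SEED
from pascdx.features import LabeledDescriptorTable
from pascdx.modeling import ModelSpec, cross_validate
from pascdx.seeds import stage_seed

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    table = LabeledDescriptorTable.from_csv(OUT / "descriptors_selected.csv")
    rows = []
    for family in ("MLP", "RF", "LR", "SVM", "GB"):
        spec = ModelSpec(family=family, seed=stage_seed(SEED, f"model_{family}"))
        cv = cross_validate(table, spec, n_repeats=3,
                            seed=stage_seed(SEED, f"cv_{family}"))
        rows.append({"family": family, "mean_auc": cv.mean_auc,
                     "ci_low": cv.ci_low, "ci_high": cv.ci_high,
                     "n_repeats": 3, "best": str(cv.best_hyperparameters)})
        print(f"{family:4s} mean AUC {cv.mean_auc:.4f} "
              f"[{cv.ci_low:.4f}, {cv.ci_high:.4f}]  {cv.best_hyperparameters}")

    mlp = ModelSpec(family="MLP", grid=MLP_GRID, seed=stage_seed(SEED, "model"))
    cv10 = cross_validate(table, mlp, n_repeats=10, seed=stage_seed(SEED, "cv"))
    rows.append({"family": "MLP(10x)", "mean_auc": cv10.mean_auc,
                 "ci_low": cv10.ci_low, "ci_high": cv10.ci_high,
                 "n_repeats": 10, "best": str(cv10.best_hyperparameters)})
    print(f"MLP at 10 repeats: mean AUC {cv10.mean_auc:.4f} "
          f"[{cv10.ci_low:.4f}, {cv10.ci_high:.4f}]")

    pd.DataFrame(rows).to_csv(OUT / "model_benchmark.csv", index=False)
    print(f"written {OUT / 'model_benchmark.csv'}")


if __name__ == "__main__":
    main()
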