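#!/usr/bin/env python
"""Generate the synthetic study: cohort, truth list and metabolite library.

Emulates a two-arm plasma metabolomics study (50 cases / 50 controls,
300 metabolites, 100 dysregulated at a 1.5-SD log-scale shift) plus a
reference library used downstream as the negative-control pool. All
later analysis steps read the files written here.
"""

from pathlib import Path

from analysis_common import SEED, STUDY
from pascdx.seeds import stage_seed
from pascdx.synth import generate_cohort, generate_library, write_truth

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort, truth = generate_cohort(STUDY.replace(seed=stage_seed(SEED, "synth")))
    library = generate_library(4 * STUDY.n_metabolites,
                               seed=stage_seed(SEED, "library"), prefix="HMDB")
    cohort.to_csv(OUT / "cohort.csv")
    write_truth(OUT / "truth.txt", truth)
    library.to_csv(OUT / "library.csv")
    print(f"cohort: {cohort.n_case} cases / {cohort.n_control} controls, "
          f"{len(cohort.metabolite_ids)} metabolites "
          f"({len(truth)} planted dysregulated)")
    print(f"library: {len(library)} reference metabolites")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
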