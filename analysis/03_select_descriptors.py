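#!/usr/bin/env python
"""Build the balanced descriptor table and select descriptors by CFS.

Samples negative-control metabolites from the library (one per selected
dysregulated metabolite, never overlapping them), attaches molecular
descriptors, cleans the table and runs CFS best-first selection.
"""

from pathlib import Path

import pandas as pd

from analysis_common import SEED, STUDY
from pascdx.features import best_first_select, clean_descriptor_table
from pascdx.screen import sample_negative_controls
from pascdx.seeds import stage_seed
from pascdx.synth import MetaboliteLibrary, generate_descriptor_table

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    screen = pd.read_csv(OUT / "screen.csv", index_col="metabolite_id")
    positives = sorted(screen.index[screen["selected"]])
    library = MetaboliteLibrary.from_csv(OUT / "library.csv")

    # library for negative sampling includes the cohort metabolites
    cohort_records = pd.DataFrame(
        {"metabolite_id": screen.index, "name": screen.index, "smiles": ""}
    )
    full = MetaboliteLibrary(
        pd.concat([cohort_records, library.records], ignore_index=True)
    )
    negatives = sample_negative_controls(
        full, positives, len(positives), seed=stage_seed(SEED, "negative_controls")
    )
    ids = list(positives) + list(negatives)
    labels = pd.Series([1] * len(positives) + [0] * len(negatives), index=ids)

    sub = MetaboliteLibrary(full.records.set_index("metabolite_id").loc[ids].reset_index())
    raw = generate_descriptor_table(
        sub, labels.to_numpy(),
        STUDY.replace(seed=stage_seed(SEED, "descriptors")),
    )
    table, cleaning = clean_descriptor_table(raw.descriptors, labels)
    table.to_csv(OUT / "descriptors.csv")
    print(f"descriptor table: {len(table)} metabolites "
          f"({len(positives)} positive / {len(negatives)} control), "
          f"{len(table.descriptor_names)} descriptors; {cleaning.summary()}")

    subset = best_first_select(table)
    subset.write(OUT / "selected_descriptors.txt")
    table.select_columns(subset.indices).to_csv(OUT / "descriptors_selected.csv")
    print(f"CFS selected {len(subset.indices)} descriptors "
          f"(merit {subset.merit:.4f}): {', '.join(subset.descriptor_names)}")


if __name__ == "__main__":
    main()
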