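#!/usr/bin/env python
"""Filter, deduplicate and featurize the simulated cohort libraries.

Reads the AIRR tables from ``02_simulate_cohorts.py``, applies the expressed-
repertoire retention rule (productive + CDR3 present, then one representative
per unique nucleotide CDR3) and writes per-library feature tables (segment
usage, VDJ associations, zone shares, CDR3 length/composition, junction
metrics) under ``results/features/``, plus a retention-count summary.
"""

from pathlib import Path

import pandas as pd

from vdjrep.features import compute_features
from vdjrep.germline import load_germline
from vdjrep.ingest import clean_repertoire, read_rearrangements

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "features"


def main() -> None:
    design = pd.read_csv(ROOT / "cohorts" / "design.tsv", sep="\t")
    reference = load_germline(
        ROOT / "reference" / "germline.fasta", ROOT / "reference" / "germline_metadata.tsv"
    )
    OUT.mkdir(parents=True, exist_ok=True)
    counts = []
    for row in design.itertuples(index=False):
        raw = read_rearrangements(ROOT / "cohorts" / f"{row.library_id}.tsv")
        rep = clean_repertoire(raw, row.library_id, row.group)
        ft = compute_features(rep, reference)
        ft.to_frame().to_csv(OUT / f"{row.library_id}.tsv", sep="\t", index=False)
        counts.append({"library_id": row.library_id, "group": row.group, **rep.counts()})
        print(
            f"{row.library_id:10s}: {rep.n_input} read -> {rep.n_filtered} productive+CDR3 "
            f"-> {rep.n_unique} unique CDR3s; {len(ft.families)} feature families"
        )
    pd.DataFrame(counts).to_csv(OUT / "retention_counts.tsv", sep="\t", index=False)
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
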