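#!/usr/bin/env python
"""Dispersion-index comparisons: control vs HU and young vs aged.

Re-ingests the cohort libraries, computes per-library dispersion indexes for
every feature family, runs the adaptive decision tree (variance and
normality gates choosing Student t / Mann-Whitney) per comparison, and
writes ``di_results.tsv`` and ``comparisons_<pair>.tsv`` under
``results/comparisons/``.  Prints the headline DI differences for IGHV
usage and the zone, IGHD-length, palindrome and N-addition patterns.
"""

from pathlib import Path

import pandas as pd

from vdjrep.features import compute_features
from vdjrep.germline import load_germline
from vdjrep.ingest import clean_repertoire, read_rearrangements
from vdjrep.stats import compare_conditions, comparisons_to_frame, di_results_to_frame

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "comparisons"
PAIRS = [("control", "HU"), ("young", "aged")]
HEADLINE = ["v_usage", "v_usage_distal", "v_usage_median", "v_usage_proximal",
            "d_usage", "j_usage", "d_len", "palindrome_vd", "palindrome_dj", "n_added_bins"]


def main() -> None:
    design = pd.read_csv(ROOT / "cohorts" / "design.tsv", sep="\t")
    reference = load_germline(
        ROOT / "reference" / "germline.fasta", ROOT / "reference" / "germline_metadata.tsv"
    )
    OUT.mkdir(parents=True, exist_ok=True)

    tables = {}
    for row in design.itertuples(index=False):
        raw = read_rearrangements(ROOT / "cohorts" / f"{row.library_id}.tsv")
        rep = clean_repertoire(raw, row.library_id, row.group)
        tables[row.library_id] = compute_features(rep, reference)

    all_tables = list(tables.values())
    di_results_to_frame(all_tables).to_csv(OUT / "di_results.tsv", sep="\t", index=False)

    for control, condition in PAIRS:
        subset = [t for t in all_tables if t.group in (control, condition)]
        results = compare_conditions(subset, pairs=[(control, condition)])
        frame = comparisons_to_frame(results)
        frame.to_csv(OUT / f"comparisons_{condition}_vs_{control}.tsv", sep="\t", index=False)
        print(f"\n{condition} vs {control}:")
        shown = frame[frame.feature.isin(HEADLINE)]
        for r in shown.itertuples(index=False):
            d = getattr(r, f"di_diff_{condition}_vs_{control}")
            sd = getattr(r, f"di_diff_sd_{condition}_vs_{control}")
            p = getattr(r, f"p_{condition}_vs_{control}")
            sig = getattr(r, f"sig_{condition}_vs_{control}")
            print(
                f"  {r.feature:18s} DI diff {d:+.3f} +/- {sd:.3f}  "
                f"[{r.test:>12s}] p={p:.4f} {sig}"
            )
    print(f"\nwritten to {OUT}")


if __name__ == "__main__":
    main()
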