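#!/usr/bin/env python
"""Simulate the four-arm study: control vs hindlimb-unloaded (HU), young vs aged.

Uses the reference from ``01_build_reference.py`` (building it if absent) and
emits, per arm, four expressed (productive-only, 10,000-sequence) libraries
as AIRR Rearrangement TSVs under ``results/cohorts/``, together with the
ground-truth snapshots and a design table.  Control and young arms share the
baseline recombination parameters; HU applies the distal-zone usage gradient
only; aging applies distal+median gradients, halved IGHD-end trimming,
1.5x N-addition means and 1.5x D-J palindrome rates.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from vdjrep.germline import load_germline
from vdjrep.simulate import SimulationConfig, apply_condition_effect, simulate_repertoire, write_airr

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "cohorts"
SEED = 1
N_PER_LIBRARY = 10_000
LIBRARIES_PER_GROUP = 4
GROUPS = {"control": "control", "HU": "HU", "young": "control", "aged": "aged"}


def main() -> None:
    ref_dir = ROOT / "reference"
    if not (ref_dir / "germline.fasta").exists():
        from vdjrep.germline import build_toy_reference, write_germline

        ref_dir.mkdir(parents=True, exist_ok=True)
        write_germline(
            build_toy_reference(seed=7),
            ref_dir / "germline.fasta",
            ref_dir / "germline_metadata.tsv",
        )
    reference = load_germline(ref_dir / "germline.fasta", ref_dir / "germline_metadata.tsv")
    OUT.mkdir(parents=True, exist_ok=True)

    children = np.random.SeedSequence(SEED).spawn(len(GROUPS) * LIBRARIES_PER_GROUP)
    design = []
    i = 0
    for group, condition in GROUPS.items():
        for k in range(LIBRARIES_PER_GROUP):
            cfg = apply_condition_effect(
                SimulationConfig(n_sequences=N_PER_LIBRARY), condition, reference
            )
            cfg.seed = int(children[i].generate_state(1)[0] % (2**31))
            i += 1
            library_id = f"{group}-{k + 1}"
            records, snapshot = simulate_repertoire(cfg, reference, id_prefix=f"{library_id}-")
            write_airr(records, OUT / f"{library_id}.tsv")
            with open(OUT / f"{library_id}.snapshot.json", "w") as fh:
                json.dump(snapshot, fh, indent=2, sort_keys=True)
            design.append({"library_id": library_id, "group": group, "condition": condition,
                           "n_records": len(records)})
            print(f"{library_id:10s} ({condition:7s}): {len(records):6d} productive records")
    pd.DataFrame(design).to_csv(OUT / "design.tsv", sep="\t", index=False)
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
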