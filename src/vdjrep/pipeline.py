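"""End-to-end orchestration: simulate/ingest -> features -> statistics -> report.

A run is driven by a single YAML config (comment-friendly, flat keys) plus a
seed; outputs are plain TSV/JSON and are byte-stable for a fixed seed and
inputs (timestamps are confined to the run log).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import germline, ingest, simulate, stats

__all__ = ["RunConfig", "PipelineConfigError", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration (see examples under ``analysis/``)."""

    reference: dict = field(default_factory=dict)
    zone_map: str | None = None
    simulate: dict | None = None
    inputs: list[dict] | None = None
    pairs: list[list[str]] | None = None
    features: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    dedup_key: str = "junction"
    seed: int | None = None

    def validate(self) -> None:
        if not self.simulate and not self.inputs:
            raise PipelineConfigError("no input: provide a 'simulate' block or 'inputs' files")
        if self.simulate and self.seed is None:
            raise PipelineConfigError("seed: mandatory when simulating")
        if not self.reference:
            raise PipelineConfigError("reference: provide fasta+metadata paths or a 'toy' block")
        if self.inputs:
            for i, item in enumerate(self.inputs):
                for key in ("path", "library_id", "group"):
                    if key not in item:
                        raise PipelineConfigError(f"inputs[{i}]: missing {key!r}")


def load_config(path: str | Path, seed: int | None = None) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    if seed is not None:
        cfg.seed = seed
    cfg.validate()
    return cfg


def _load_reference(cfg: RunConfig) -> germline.GermlineReference:
    ref_cfg = cfg.reference
    if "toy" in ref_cfg:
        toy = dict(ref_cfg["toy"])
        toy.setdefault("seed", cfg.seed or 0)
        if "n_v_per_zone" in toy:
            toy["n_v_per_zone"] = tuple(toy["n_v_per_zone"])
        return germline.build_toy_reference(**toy)
    if "fasta" in ref_cfg and "metadata" in ref_cfg:
        return germline.load_germline(ref_cfg["fasta"], ref_cfg["metadata"])
    raise PipelineConfigError("reference: needs either 'toy' or 'fasta'+'metadata'")


def _simulation_configs(cfg: RunConfig, reference) -> list[tuple[str, str, simulate.SimulationConfig]]:
    sim = cfg.simulate
    n = int(sim.get("n_per_library", 10_000))
    libraries: dict[str, int] = sim.get("libraries", {"control": 4, "HU": 4})
    conditions: dict[str, str] = sim.get("conditions", {g: g if g in simulate.CONDITIONS else "control" for g in libraries})
    knobs = sim.get("knobs", {})
    overrides = sim.get("config", {})
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(sum(libraries.values()))
    out = []
    i = 0
    for group, count in libraries.items():
        for k in range(count):
            base = simulate.SimulationConfig(n_sequences=n, **overrides, **knobs)
            cond = conditions.get(group, "control")
            conf = simulate.apply_condition_effect(base, cond, reference)
            conf.seed = int(children[i].generate_state(1)[0] % (2**31))
            out.append((f"{group}-{k + 1}", group, conf))
            i += 1
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Run the full analysis; returns the report directory.

    Writes per-library AIRR tables (when simulating), feature tables, the
    per-library DI table, group comparisons, a JSON report with gate
    decisions, and a manifest with content hashes.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setLevel(logging.INFO)
    logging.getLogger("vdjrep").addHandler(fh)
    try:
        return _run(cfg, out)
    finally:
        logging.getLogger("vdjrep").removeHandler(fh)
        fh.close()


def _run(cfg: RunConfig, out: Path) -> Path:
    reference = _load_reference(cfg)
    zone_map = germline.ZoneMap.from_tsv(cfg.zone_map) if cfg.zone_map else None
    opts = feat.FeatureOptions(
        length_set=tuple(cfg.features.get("length_set", (11, 12, 13, 14))),
        cdr3_cap=int(cfg.features.get("cdr3_cap", 30)),
        trim_cap=int(cfg.features.get("trim_cap", 10)),
    )
    alpha = float(cfg.stats.get("alpha", 0.05))
    metric = str(cfg.stats.get("metric", "shannon"))

    germline.write_germline(reference, out / "reference.fasta", out / "reference_metadata.tsv")

    repertoires: list[ingest.CleanRepertoire] = []
    snapshots: dict[str, dict] = {}
    if cfg.simulate:
        sim_dir = out / "libraries"
        sim_dir.mkdir(exist_ok=True)
        for library_id, group, conf in _simulation_configs(cfg, reference):
            records, snapshot = simulate.simulate_repertoire(conf, reference, id_prefix=f"{library_id}-")
            simulate.write_airr(records, sim_dir / f"{library_id}.tsv")
            snapshots[library_id] = snapshot
            rep = ingest.clean_repertoire(
                ingest.read_rearrangements(sim_dir / f"{library_id}.tsv"),
                library_id,
                group,
                key=cfg.dedup_key,
            )
            repertoires.append(rep)
            log.info("%s (%s): %s", library_id, group, rep.counts())
    else:
        for item in cfg.inputs:
            cm_name = item.get("column_map", "airr")
            cm = (
                ingest.ColumnMap.imgt_highv_quest()
                if cm_name == "imgt"
                else ingest.ColumnMap.airr()
            )
            rep = ingest.clean_repertoire(
                ingest.read_rearrangements(item["path"], cm),
                item["library_id"],
                item["group"],
                key=cfg.dedup_key,
            )
            repertoires.append(rep)
            log.info("%s (%s): %s", item["library_id"], item["group"], rep.counts())

    tables = [feat.compute_features(rep, reference, zone_map, opts) for rep in repertoires]
    feat_dir = out / "features"
    feat_dir.mkdir(exist_ok=True)
    for ft in tables:
        ft.to_frame().to_csv(feat_dir / f"{ft.library_id}.tsv", sep="\t", index=False)

    di = stats.di_results_to_frame(tables, metric=metric)
    di.to_csv(out / "di_results.tsv", sep="\t", index=False)
    pairs = [tuple(p) for p in cfg.pairs] if cfg.pairs else None
    results = stats.compare_conditions(tables, pairs=pairs, alpha=alpha, metric=metric)
    stats.comparisons_to_frame(results).to_csv(out / "comparisons.tsv", sep="\t", index=False)

    report = {
        "seed": cfg.seed,
        "alpha": alpha,
        "metric": metric,
        "reference": {
            "counts": reference.counts(),
            "functional": reference.functional_counts(),
            "zones": {z.value: c for z, c in reference.zone_counts().items()},
        },
        "libraries": {r.library_id: {"group": r.group, **r.counts()} for r in repertoires},
        "feature_families": tables[0].families if tables else {},
        "comparisons": {
            r.feature: {
                "test": r.test,
                "p_omnibus": r.p_omnibus,
                "gates": {k: (bool(v) if isinstance(v, (bool, np.bool_)) else float(v)) for k, v in r.gates.items()},
            }
            for r in results
        },
        "ground_truth": snapshots,
    }
    with open(out / "report.json", "w") as fhj:
        json.dump(report, fhj, indent=2, sort_keys=True)

    manifest = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name not in ("manifest.json", "run.log")
    }
    with open(out / "manifest.json", "w") as fhm:
        json.dump(manifest, fhm, indent=2, sort_keys=True)
    return out
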