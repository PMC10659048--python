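"""Repeatable validation experiments over the full pipeline.

These drive the study-level checks: closed-form and property audits of the
dispersion index, structural audits of the simulator, parameter-recovery
suites, type-I calibration of the adaptive test path under null simulations,
and detection of the packaged condition-effect patterns.  Both the test
suite and the reproduction script call these entry points, so every number
they report is recomputed from scratch.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .features import FeatureOptions, compute_features
from .germline import SegmentClass, build_toy_reference
from .ingest import clean_repertoire, raw_repertoire
from .simulate import SimulationConfig, apply_condition_effect, expected_junction_stats, simulate_repertoire
from .stats import compare_conditions, dispersion_index

__all__ = [
    "di_property_audit",
    "simulator_structure_audit",
    "parameter_recovery_suite",
    "null_type_one_error",
    "effect_detection_suite",
    "EFFECT_PATTERNS",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


# ---------------------------------------------------------------------------
# dispersion-index audit


def di_property_audit(n_vectors: int = 1000, seed: int = 0) -> dict:
    """Closed forms plus transfer-monotonicity and relabeling invariance.

    Randomized vectors are Dirichlet draws of dimension 3..30; returns the
    fraction of vectors satisfying each property (1.0 expected).
    """
    rng = np.random.default_rng(seed)
    mono_ok = relabel_ok = 0
    for _ in range(n_vectors):
        k = int(rng.integers(3, 31))
        p = rng.dirichlet(np.ones(k))
        hi, lo = int(np.argmax(p)), int(np.argmin(p))
        delta = (p[hi] - p[lo]) * rng.uniform(0.0, 0.5)
        q = p.copy()
        q[hi] -= delta
        q[lo] += delta
        if dispersion_index(q, k) >= dispersion_index(p, k) - 1e-12:
            mono_ok += 1
        perm = rng.permutation(k)
        if abs(dispersion_index(p[perm], k) - dispersion_index(p, k)) < 1e-12:
            relabel_ok += 1
    return {
        "di_uniform": dispersion_index([0.25] * 4, 4),
        "di_degenerate": dispersion_index([1, 0, 0, 0], 4),
        "di_half_half_k4": dispersion_index([0.5, 0.5, 0, 0], 4),
        "transfer_monotonicity_fraction": mono_ok / n_vectors,
        "relabel_invariance_fraction": relabel_ok / n_vectors,
        "n_vectors": n_vectors,
    }


# ---------------------------------------------------------------------------
# simulator structural audit


def simulator_structure_audit(n_records: int = 50_000, seed: int = 0) -> dict:
    """Decomposition identity and P-nucleotide legality across raw records."""
    reference = build_toy_reference(n_v_per_zone=(6, 3, 3), n_d=4, n_j=3, seed=seed)
    cfg = SimulationConfig(n_sequences=n_records, seed=seed, productive_only=False)
    df, _ = simulate_repertoire(cfg, reference)
    vt = {s.name: len(s.sequence) - s.anchor_offset for s in reference.functional(SegmentClass.V)}
    jh = {s.name: s.anchor_offset + 3 for s in reference.functional(SegmentClass.J)}
    rhs = (
        df.v_call.map(vt)
        - df.v3_trim
        + df.p3v_len
        + df.n1_len
        + df.p5d_len
        + df.d_retained_len
        + df.p3d_len
        + df.n2_len
        + df.p5j_len
        + df.j_call.map(jh)
        - df.j5_trim
    )
    identity_frac = float((df.junction.str.len() == rhs).mean())
    legal = np.ones(len(df), dtype=bool)
    for p_col, t_col in (
        ("p3v_len", "v3_trim"),
        ("p5d_len", "d5_trim"),
        ("p3d_len", "d3_trim"),
        ("p5j_len", "j5_trim"),
    ):
        legal &= (df[p_col] == 0) | (df[t_col] == 0)
    return {
        "n_records": len(df),
        "decomposition_identity_fraction": identity_frac,
        "p_legality_fraction": float(legal.mean()),
        "nonnegative_d_fraction": float((df.d_retained_len >= 0).mean()),
    }


# ---------------------------------------------------------------------------
# parameter recovery


def _random_config(rng: np.random.Generator, n: int, seed: int) -> SimulationConfig:
    ends = ("v3", "d5", "d3", "j5")
    return SimulationConfig(
        n_sequences=n,
        seed=seed,
        productive_only=False,
        p_trim={e: float(rng.uniform(0.3, 0.7)) for e in ends},
        p_palindrome={e: float(rng.uniform(0.1, 0.4)) for e in ends},
        n_mean={"vd": float(rng.uniform(1.5, 6.0)), "dj": float(rng.uniform(1.5, 6.0))},
    )


def parameter_recovery_suite(
    n_configs: int = 20, n_per_config: int = 20_000, seed: int = 12345
) -> pd.DataFrame:
    """Recover every generative parameter from feature output, as z-scores.

    Each seeded config gets a fresh small reference (3 V, one per zone; 2 D;
    2 J) and randomized usage weights, trim, palindrome and N parameters.
    Simulation is *unselected* (productive_only=False): conditioning on
    productivity provably tilts junction statistics (stop-codon survival
    penalizes long N additions and stop-prone V tails), so the generative law
    is only identifiable from raw records.  Expected values and standard
    errors come from the exact snapshot law (`expected_junction_stats`),
    including the D-end joint trimming constraint.

    Returns one row per (config, parameter) with the empirical estimate, the
    exact expectation, its standard error and z = (est - exp) / se.
    """
    rng = np.random.default_rng(seed)
    config_seeds = _child_seeds(seed, n_configs)
    rows = []
    for c_idx in range(n_configs):
        reference = build_toy_reference(
            n_v_per_zone=(1, 1, 1), n_d=2, n_j=2, seed=config_seeds[c_idx]
        )
        cfg = _random_config(rng, n_per_config, config_seeds[c_idx])
        for cls, attr in (("v", "v_weights"), ("d", "d_weights"), ("j", "j_weights")):
            genes = [s.name for s in reference.functional(SegmentClass(cls.upper()))]
            w = rng.dirichlet(np.ones(len(genes)) * 5.0)
            setattr(cfg, attr, dict(zip(genes, map(float, w))))
        df, snap = simulate_repertoire(cfg, reference)
        rep = raw_repertoire(df, f"cfg{c_idx}", "recovery")
        ft = compute_features(rep, reference)
        oracle = expected_junction_stats(snap)
        n = len(df)

        def add(param, est, exp, se):
            rows.append(
                {
                    "config": c_idx,
                    "parameter": param,
                    "estimate": est,
                    "expected": exp,
                    "se": se,
                    "z": (est - exp) / se if se > 0 else 0.0,
                }
            )

        for cls, genes_key, probs_key in (
            ("v", "v_genes", "v_probs"),
            ("d", "d_genes", "d_probs"),
            ("j", "j_genes", "j_probs"),
        ):
            fv = ft.vectors[f"{cls}_usage"]
            for gene, p in zip(snap[genes_key], snap[probs_key]):
                add(
                    f"{cls}_usage:{gene}",
                    float(fv.freqs[gene]),
                    float(p),
                    math.sqrt(p * (1 - p) / n),
                )
        for col in ("v3_trim", "j5_trim"):
            fv = ft.vectors[col]
            est = float((fv.freqs * fv.freqs.index.astype(float)).sum())
            add(f"{col}_mean", est, oracle[col]["mean"], math.sqrt(oracle[col]["var"] / n))
        fv = ft.vectors["d_len"]
        est = float((fv.freqs * fv.freqs.index.astype(float)).sum())
        add(
            "d_retained_mean",
            est,
            oracle["d_retained_len"]["mean"],
            math.sqrt(oracle["d_retained_len"]["var"] / n),
        )
        for fam, key in (("palindrome_vd", "palindrome_vd_rate"), ("palindrome_dj", "palindrome_dj_rate")):
            p = oracle[key]
            add(
                f"{fam}_rate",
                float(ft.vectors[fam].freqs["with"]),
                p,
                math.sqrt(p * (1 - p) / n),
            )
        p = oracle["n_ge7_rate"]
        add(
            "n_ge7_rate",
            float(ft.vectors["n_added_bins"].freqs["ge7"]),
            p,
            math.sqrt(p * (1 - p) / n),
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# decision-tree calibration and effect detection


def _simulate_tables(
    reference,
    group_conditions: dict[str, str],
    libraries_per_group: int,
    n_per_library: int,
    seed: int,
    base: SimulationConfig | None = None,
    options: FeatureOptions | None = None,
):
    base = base or SimulationConfig()
    seeds = _child_seeds(seed, libraries_per_group * len(group_conditions))
    tables = []
    i = 0
    for group, condition in group_conditions.items():
        for k in range(libraries_per_group):
            cfg = apply_condition_effect(base, condition, reference)
            cfg.n_sequences = n_per_library
            cfg.seed = seeds[i]
            i += 1
            df, _ = simulate_repertoire(cfg, reference, id_prefix=f"{group}{k}-")
            rep = clean_repertoire(df, f"{group}-{k + 1}", group)
            tables.append(compute_features(rep, reference, options=options))
    return tables


def null_type_one_error(
    n_replicates: int = 200,
    libraries_per_group: int = 4,
    n_per_library: int = 400,
    alpha: float = 0.05,
    seed: int = 0,
    feature: str = "v_usage",
) -> dict:
    """Rejection rate of the full compare path when both conditions are identical."""
    reference = build_toy_reference(n_v_per_zone=(4, 2, 2), n_d=3, n_j=3, seed=seed)
    rep_seeds = _child_seeds(seed + 1, n_replicates)
    rejections = 0
    tests_used: dict[str, int] = {}
    for r in range(n_replicates):
        tables = _simulate_tables(
            reference,
            {"control": "control", "sham": "control"},
            libraries_per_group,
            n_per_library,
            rep_seeds[r],
        )
        res = {c.feature: c for c in compare_conditions(tables, pairs=[("control", "sham")], alpha=alpha)}
        c = res[feature]
        tests_used[c.test] = tests_used.get(c.test, 0) + 1
        if c.pairwise_p("control", "sham") <= alpha:
            rejections += 1
    return {
        "type_i_error": rejections / n_replicates,
        "n_replicates": n_replicates,
        "feature": feature,
        "tests_used": tests_used,
    }


#: expected pairwise significance by feature under the packaged effect knobs:
#: aging shifts V usage, distal+median zone usage, D length, D-J palindromes
#: and long N additions; HU shifts V usage and distal-zone usage only.
EFFECT_PATTERNS = {
    "HU": {
        "v_usage": True,
        "v_usage_distal": True,
        "v_usage_median": False,
        "d_len": False,
        "palindrome_dj": False,
        "n_added_bins": False,
    },
    "aged": {
        "v_usage": True,
        "v_usage_distal": True,
        "v_usage_median": True,
        "d_len": True,
        "palindrome_dj": True,
        "n_added_bins": True,
    },
}


def effect_detection_suite(
    n_replicates: int = 50,
    libraries_per_group: int = 4,
    n_per_library: int = 1500,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Significance patterns under the packaged HU and aging knobs.

    Each replicate simulates a control and a condition arm and runs the full
    compare path; returns per (condition, feature) the fraction of replicates
    whose significance status matches the packaged expectation, plus the
    strict all-features-at-once match rate and the mean DI difference.
    """
    reference = build_toy_reference(n_v_per_zone=(8, 4, 3), n_d=4, n_j=3, seed=seed)
    rep_seeds = _child_seeds(seed + 2, n_replicates * 2)
    rows = []
    for cond_idx, (condition, pattern) in enumerate(EFFECT_PATTERNS.items()):
        control_label = "control" if condition == "HU" else "young"
        matches = {f: 0 for f in pattern}
        strict = 0
        di_diffs: dict[str, list[float]] = {f: [] for f in pattern}
        for r in range(n_replicates):
            tables = _simulate_tables(
                reference,
                {control_label: "control", condition: condition},
                libraries_per_group,
                n_per_library,
                rep_seeds[cond_idx * n_replicates + r],
            )
            res = {
                c.feature: c
                for c in compare_conditions(
                    tables, pairs=[(control_label, condition)], alpha=alpha
                )
            }
            all_ok = True
            for feature, expect_sig in pattern.items():
                sig = res[feature].pairwise_p(control_label, condition) <= alpha
                ok = sig == expect_sig
                matches[feature] += ok
                all_ok &= ok
                di_diffs[feature].append(res[feature].di_diff[(control_label, condition)][0])
            strict += all_ok
        for feature, expect_sig in pattern.items():
            rows.append(
                {
                    "condition": condition,
                    "feature": feature,
                    "expected": "significant" if expect_sig else "not significant",
                    "match_rate": matches[feature] / n_replicates,
                    "strict_pattern_rate": strict / n_replicates,
                    "mean_di_diff": float(np.mean(di_diffs[feature])),
                    "n_replicates": n_replicates,
                }
            )
    return pd.DataFrame(rows)
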