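"""Dispersion indexes and the parametric-vs-nonparametric decision tree.

The dispersion index (DI) of a categorical frequency vector is normalized
Shannon evenness (Pielou): DI = H / ln K with H = -sum p_i ln p_i, so DI = 0
when a single category carries all mass and DI = 1 when mass is uniform over
the K categories.  A normalized Gini-Simpson evenness is provided as an
alternative metric behind the same interface.

Group comparisons follow the decision tree used by common graphing software:

* two groups — Fisher variance-ratio test and Lilliefors-corrected
  Kolmogorov-Smirnov normality at alpha; both pass -> Student t, otherwise
  Mann-Whitney;
* three or more groups — Bartlett and per-group Shapiro-Wilk at alpha; all
  pass -> one-way ANOVA with Tukey-Kramer pairwise post hocs, otherwise
  Kruskal-Wallis with Dunn's post hoc (Bonferroni-adjusted).

alpha defaults to 0.05 throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .features import FeatureTable, FrequencyVector

__all__ = [
    "dispersion_index",
    "gini_simpson_evenness",
    "DI_METRICS",
    "TestChoice",
    "choose_two_group_test",
    "choose_multi_group_test",
    "DIResult",
    "GroupComparisonResult",
    "compare_conditions",
    "comparisons_to_frame",
    "di_results_to_frame",
]


def _validate_freqs(freq: np.ndarray, K: int) -> np.ndarray:
    p = np.asarray(freq, dtype=float)
    if (p < -1e-12).any():
        raise ValueError("negative frequency entry")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies sum to {p.sum():.6g}, not 1")
    if K < int((p > 0).sum()):
        raise ValueError(f"K={K} smaller than the number of positive categories")
    return np.clip(p, 0.0, None)


def dispersion_index(freq, K: int) -> float:
    """Normalized Shannon evenness H / ln K on [0, 1] (K=1 -> 0 by convention)."""
    p = _validate_freqs(freq, K)
    if K <= 1:
        return 0.0
    pz = p[p > 0]
    H = float(-(pz * np.log(pz)).sum())
    return min(max(H / math.log(K), 0.0), 1.0) + 0.0  # normalize -0.0


def gini_simpson_evenness(freq, K: int) -> float:
    """Normalized Gini-Simpson evenness (1 - sum p^2) * K / (K - 1); alternative DI."""
    p = _validate_freqs(freq, K)
    if K <= 1:
        return 0.0
    gs = 1.0 - float((p**2).sum())
    return min(max(gs * K / (K - 1), 0.0), 1.0)


DI_METRICS = {"shannon": dispersion_index, "gini_simpson": gini_simpson_evenness}


# ---------------------------------------------------------------------------
# decision tree


@dataclass
class TestChoice:
    """Outcome of a decision-tree comparison."""

    test: str  # t | Mann-Whitney | ANOVA+Tukey-Kramer | Kruskal-Wallis+Dunn
    p: float
    gates: dict[str, float | bool] = field(default_factory=dict)
    pairwise: pd.DataFrame | None = None  # columns: group_a, group_b, p


def _fisher_variance_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided variance-ratio (F) test."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    F = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    cdf = sps.f.cdf(F, dfa, dfb)
    return float(2 * min(cdf, 1 - cdf))


def _normality_p(x: np.ndarray) -> float:
    """Lilliefors-corrected KS normality p (Shapiro-Wilk below its n=4 minimum)."""
    if len(x) >= 4:
        return float(lilliefors(x, dist="norm")[1])
    return float(sps.shapiro(x).pvalue)


def choose_two_group_test(a, b, alpha: float = 0.05) -> TestChoice:
    """Student t when variance homogeneity and normality gates pass, else Mann-Whitney."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs >= 3 observations")
    gates: dict[str, float | bool] = {}
    if np.var(a, ddof=1) == 0.0 or np.var(b, ddof=1) == 0.0:
        gates["zero_variance"] = True
        parametric = False
    else:
        p_var = _fisher_variance_p(a, b)
        p_norm_a = _normality_p(a)
        p_norm_b = _normality_p(b)
        gates.update(fisher_p=p_var, ks_p_a=p_norm_a, ks_p_b=p_norm_b)
        parametric = p_var > alpha and p_norm_a > alpha and p_norm_b > alpha
    if parametric:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        return TestChoice(test="t", p=float(p), gates=gates)
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return TestChoice(test="Mann-Whitney", p=float(p), gates=gates)


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-sum pairwise z tests with tie correction and Bonferroni adjustment."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    mean_ranks = {}
    pos = 0
    for g in labels:
        k = len(groups[g])
        mean_ranks[g] = ranks[pos : pos + k].mean()
        pos += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1))
    base_var = N * (N + 1) / 12.0 - tie_term
    n_pairs = len(labels) * (len(labels) - 1) // 2
    rows = []
    for ga, gb in itertools.combinations(labels, 2):
        se = math.sqrt(base_var * (1.0 / len(groups[ga]) + 1.0 / len(groups[gb])))
        z = (mean_ranks[ga] - mean_ranks[gb]) / se
        p = min(2.0 * sps.norm.sf(abs(z)) * n_pairs, 1.0)
        rows.append({"group_a": ga, "group_b": gb, "p": float(p)})
    return pd.DataFrame(rows)


def choose_multi_group_test(groups: dict[str, "np.ndarray"], alpha: float = 0.05) -> TestChoice:
    """ANOVA + Tukey-Kramer when Bartlett and Shapiro-Wilk gates pass, else KW + Dunn.

    ``groups`` maps group label -> 1-d array of observations (each n >= 3).
    """
    if len(groups) < 3:
        raise ValueError("choose_multi_group_test needs >= 3 groups")
    arrs = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrs.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} needs >= 3 observations")
    gates: dict[str, float | bool] = {}
    if any(np.var(v, ddof=1) == 0.0 for v in arrs.values()):
        gates["zero_variance"] = True
        parametric = False
    else:
        p_bart = float(sps.bartlett(*arrs.values()).pvalue)
        gates["bartlett_p"] = p_bart
        parametric = p_bart > alpha
        for g, v in arrs.items():
            p_sw = float(sps.shapiro(v).pvalue)
            gates[f"shapiro_p_{g}"] = p_sw
            parametric = parametric and p_sw > alpha
    if parametric:
        p_omni = float(sps.f_oneway(*arrs.values()).pvalue)
        values = np.concatenate(list(arrs.values()))
        labels = np.concatenate([[g] * len(v) for g, v in arrs.items()])
        tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
        ia, ib = tk._multicomp.pairindices
        uniq = tk.groupsunique
        pw = pd.DataFrame(
            {
                "group_a": [str(uniq[i]) for i in ia],
                "group_b": [str(uniq[i]) for i in ib],
                "p": np.asarray(tk.pvalues, dtype=float),
            }
        )
        return TestChoice(test="ANOVA+Tukey-Kramer", p=p_omni, gates=gates, pairwise=pw)
    p_omni = float(sps.kruskal(*arrs.values()).pvalue)
    pw = _dunn_posthoc(arrs)
    return TestChoice(test="Kruskal-Wallis+Dunn", p=p_omni, gates=gates, pairwise=pw)


# ---------------------------------------------------------------------------
# condition comparison


@dataclass
class DIResult:
    feature: str
    library_id: str
    group: str
    K: int
    DI: float


@dataclass
class GroupComparisonResult:
    """Per-feature DI comparison across groups.

    ``di_diff`` entries are condition-mean minus control-mean DI; their SD is
    the standard deviation of per-condition-library deviations from the
    control mean (the convention behind "difference in DI of x +/- y").
    """

    feature: str
    K: int
    group_dis: dict[str, list[float]]
    group_mean: dict[str, float]
    group_sd: dict[str, float]
    group_sem: dict[str, float]
    test: str
    p_omnibus: float
    pairwise: pd.DataFrame
    gates: dict
    di_diff: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def pairwise_p(self, ga: str, gb: str) -> float:
        pw = self.pairwise
        hit = pw[((pw.group_a == ga) & (pw.group_b == gb)) | ((pw.group_a == gb) & (pw.group_b == ga))]
        if hit.empty:
            raise KeyError(f"no pairwise comparison {ga} vs {gb}")
        return float(hit.iloc[0]["p"])

    def significance_tier(self, ga: str, gb: str) -> str:
        p = self.pairwise_p(ga, gb)
        if p <= 0.001:
            return "***"
        if p <= 0.01:
            return "**"
        if p <= 0.05:
            return "*"
        return "n.s."


def _union_di(vectors: dict[str, FrequencyVector], metric) -> tuple[dict[str, float], int]:
    """DI per library with K resolved per the vectors' convention."""
    fixed = {lib: fv.fixed_k for lib, fv in vectors.items()}
    if all(fixed.values()):
        ks = {fv.K for fv in vectors.values()}
        if len(ks) != 1:
            raise ValueError("fixed-K feature with inconsistent K across libraries")
        K = ks.pop()
        return {lib: metric(fv.freqs.values, K) for lib, fv in vectors.items()}, K
    # observed union across the compared libraries
    union: set = set()
    for fv in vectors.values():
        union |= set(fv.freqs.index[fv.freqs > 0])
    K = max(len(union), 1)
    return {lib: metric(fv.freqs.values, K) for lib, fv in vectors.items()}, K


def compare_conditions(
    features: list[FeatureTable],
    pairs: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    metric: str = "shannon",
) -> list[GroupComparisonResult]:
    """Run the decision tree on per-library DIs for every shared feature.

    Groups come from each FeatureTable's ``group``.  With exactly two groups
    the two-group tree is used; with three or more, the multigroup tree.
    ``pairs`` (control, condition) selects which DI differences to report;
    by default every pair in order of appearance.
    """
    metric_fn = DI_METRICS[metric]
    groups_order: list[str] = []
    for ft in features:
        if ft.group not in groups_order:
            groups_order.append(ft.group)
    if any(sum(ft.group == g for ft in features) < 2 for g in groups_order):
        raise ValueError("each group needs >= 2 libraries")
    if pairs is None:
        pairs = list(itertools.combinations(groups_order, 2))

    shared = set(features[0].vectors)
    for ft in features[1:]:
        shared &= set(ft.vectors)
    ordered = [name for name in features[0].vectors if name in shared]

    results: list[GroupComparisonResult] = []
    for name in ordered:
        vectors = {ft.library_id: ft.vectors[name] for ft in features}
        if any(fv.empty for fv in vectors.values()):
            continue
        dis, K = _union_di(vectors, metric_fn)
        group_dis: dict[str, list[float]] = {g: [] for g in groups_order}
        for ft in features:
            group_dis[ft.group].append(dis[ft.library_id])
        if len(groups_order) == 2:
            a, b = (np.asarray(group_dis[g]) for g in groups_order)
            choice = choose_two_group_test(a, b, alpha=alpha)
            pairwise = pd.DataFrame(
                [{"group_a": groups_order[0], "group_b": groups_order[1], "p": choice.p}]
            )
        else:
            choice = choose_multi_group_test(
                {g: np.asarray(v) for g, v in group_dis.items()}, alpha=alpha
            )
            pairwise = choice.pairwise
        means = {g: float(np.mean(v)) for g, v in group_dis.items()}
        sds = {g: float(np.std(v, ddof=1)) for g, v in group_dis.items()}
        sems = {g: sds[g] / math.sqrt(len(group_dis[g])) for g in group_dis}
        diffs = {}
        for ctrl, cond in pairs:
            dev = np.asarray(group_dis[cond]) - means[ctrl]
            diffs[(ctrl, cond)] = (float(dev.mean()), float(dev.std(ddof=1)))
        results.append(
            GroupComparisonResult(
                feature=name,
                K=K,
                group_dis=group_dis,
                group_mean=means,
                group_sd=sds,
                group_sem=sems,
                test=choice.test,
                p_omnibus=choice.p,
                pairwise=pairwise,
                gates=choice.gates,
                di_diff=diffs,
            )
        )
    return results


def di_results_to_frame(features: list[FeatureTable], metric: str = "shannon") -> pd.DataFrame:
    """Per-library DI table (one row per library x feature), K per the comparison set."""
    metric_fn = DI_METRICS[metric]
    shared = set(features[0].vectors)
    for ft in features[1:]:
        shared &= set(ft.vectors)
    rows = []
    for name in [n for n in features[0].vectors if n in shared]:
        vectors = {ft.library_id: ft.vectors[name] for ft in features}
        if any(fv.empty for fv in vectors.values()):
            continue
        dis, K = _union_di(vectors, metric_fn)
        for ft in features:
            rows.append(
                {
                    "feature": name,
                    "library_id": ft.library_id,
                    "group": ft.group,
                    "K": K,
                    "DI": dis[ft.library_id],
                }
            )
    return pd.DataFrame(rows)


def comparisons_to_frame(results: list[GroupComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "feature": r.feature,
            "K": r.K,
            "test": r.test,
            "p_omnibus": r.p_omnibus,
        }
        for g in r.group_mean:
            row[f"mean_{g}"] = r.group_mean[g]
            row[f"sd_{g}"] = r.group_sd[g]
            row[f"sem_{g}"] = r.group_sem[g]
        for (ctrl, cond), (d, sd) in r.di_diff.items():
            row[f"di_diff_{cond}_vs_{ctrl}"] = d
            row[f"di_diff_sd_{cond}_vs_{ctrl}"] = sd
            row[f"p_{cond}_vs_{ctrl}"] = r.pairwise_p(ctrl, cond)
            row[f"sig_{cond}_vs_{ctrl}"] = r.significance_tier(ctrl, cond)
        rows.append(row)
    return pd.DataFrame(rows)
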