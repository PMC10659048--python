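import numpy as np
import pandas as pd
import pytest

from vdjrep.features import (
    FEATURE_FAMILIES,
    FeatureOptions,
    FrequencyVector,
    cdr3_aa_composition,
    cdr3_length_distribution,
    compute_features,
    junction_metrics,
    segment_usage,
    vdj_association_table,
    zone_features,
)
from vdjrep.germline import GermlineError, SegmentClass, Zone
from vdjrep.ingest import CleanRepertoire, clean_repertoire
from vdjrep.simulate import (
    SimulationConfig,
    expected_junction_stats,
    simulate_repertoire,
    _Machinery,
)


def rep_from_rows(rows, **attrs):
    """Build a CleanRepertoire from dict rows; junctions made unique automatically."""
    df = pd.DataFrame(rows)
    defaults = {
        "d_call": "D1",
        "j_call": "J1",
        "junction_aa": "",
        "productive": True,
    }
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
    if "junction" not in df.columns:
        df["junction"] = [f"JUNC{i}" for i in range(len(df))]
    df["sequence_id"] = [f"s{i}" for i in range(len(df))]
    df.attrs.update(attrs)
    rep = CleanRepertoire(
        "lib", "g", df, n_input=len(df), n_filtered=len(df), n_unique=len(df),
        has_decomposition=attrs.get("has_decomposition", True),
    )
    return rep


@pytest.fixture(scope="module")
def sim_rep(small_ref):
    cfg = SimulationConfig(n_sequences=6000, seed=21)
    df, snap = simulate_repertoire(cfg, small_ref)
    rep = clean_repertoire(df, "simlib", "control")
    return rep, snap


class TestSegmentUsage:
    def test_direct_tally_over_full_reference_space(self, tiny_ref):
        rep = rep_from_rows([{"v_call": "V1"}] * 3 + [{"v_call": "V2"}])
        fv = segment_usage(rep, tiny_ref, SegmentClass.V)
        assert fv.K == 3
        assert list(fv.freqs.reindex(["V1", "V2", "V3"])) == [0.75, 0.25, 0.0]

    def test_single_record_is_one_hot(self, tiny_ref):
        rep = rep_from_rows([{"v_call": "V2"}])
        fv = segment_usage(rep, tiny_ref, SegmentClass.V)
        assert fv.freqs["V2"] == 1.0 and fv.freqs.sum() == 1.0

    def test_unresolvable_call_listed(self, tiny_ref):
        rep = rep_from_rows([{"v_call": "V9"}])
        with pytest.raises(GermlineError, match="V9"):
            segment_usage(rep, tiny_ref, SegmentClass.V)

    def test_simulated_usage_within_binomial_error(self, small_ref):
        # raw (unselected) records: productivity selection favors V genes
        # whose tails are less stop-prone, so generative usage is only
        # recoverable without the productive filter
        from vdjrep.ingest import raw_repertoire

        cfg = SimulationConfig(n_sequences=20_000, seed=21, productive_only=False)
        df, snap = simulate_repertoire(cfg, small_ref)
        rep = raw_repertoire(df, "raw", "g")
        fv = segment_usage(rep, small_ref, SegmentClass.V)
        for gene, p in zip(snap["v_genes"], snap["v_probs"]):
            se = np.sqrt(p * (1 - p) / fv.n)
            assert abs(fv.freqs[gene] - p) < 3 * se + 1e-12


class TestVdjAssociation:
    def test_triple_tally_with_nod_stratum(self):
        rep = rep_from_rows(
            [
                {"v_call": "V1", "d_call": "D1", "j_call": "J1"},
                {"v_call": "V1", "d_call": "D1", "j_call": "J1"},
                {"v_call": "V2", "d_call": "", "j_call": "J1"},
            ]
        )
        fv = vdj_association_table(rep)
        assert fv.freqs["V1|D1|J1"] == pytest.approx(2 / 3)
        assert fv.freqs["V2|noD|J1"] == pytest.approx(1 / 3)
        assert not fv.fixed_k

    def test_single_triple_has_frequency_one(self):
        rep = rep_from_rows([{"v_call": "V1"}] * 5)
        fv = vdj_association_table(rep)
        assert len(fv.freqs) == 1 and fv.freqs.iloc[0] == 1.0

    def test_counts_conserve_n_unique(self, sim_rep):
        rep, _ = sim_rep
        fv = vdj_association_table(rep)
        assert fv.n == rep.n_unique


class TestZoneFeatures:
    def test_uniform_usage_recovers_zone_composition(self, murine_ref):
        cfg = SimulationConfig(n_sequences=5000, seed=17)
        df, _ = simulate_repertoire(cfg, murine_ref)
        rep = clean_repertoire(df, "lib", "g")
        share, _ = zone_features(rep, murine_ref)
        # closed form: uniform usage -> zone share = segment-count share
        assert share.freqs["distal"] == pytest.approx(81 / 130, abs=0.025)
        assert share.freqs["median"] == pytest.approx(34 / 130, abs=0.025)
        assert share.freqs["proximal"] == pytest.approx(15 / 130, abs=0.02)

    def test_single_distal_gene_gives_pure_distal_share(self, tiny_ref):
        rep = rep_from_rows([{"v_call": "V1"}] * 4)
        share, by_zone = zone_features(rep, tiny_ref)
        assert list(share.freqs) == [1.0, 0.0, 0.0]
        assert by_zone[Zone.DISTAL].freqs["V1"] == 1.0
        assert by_zone[Zone.MEDIAN].empty

    def test_share_equals_usage_aggregated_through_zone_map(self, sim_rep, small_ref):
        rep, _ = sim_rep
        share, _ = zone_features(rep, small_ref)
        usage = segment_usage(rep, small_ref, SegmentClass.V)
        zm = small_ref.zone_map()
        agg = {z.value: 0.0 for z in Zone}
        for gene, f in usage.freqs.items():
            agg[zm.assign(gene).value] += f
        for z, f in share.freqs.items():
            assert f == pytest.approx(agg[z], abs=1e-12)


class TestCdr3Length:
    def test_length_is_junction_aa_minus_anchors(self):
        rep = rep_from_rows([{"junction_aa": "CARDW"}])
        fv = cdr3_length_distribution(rep)
        assert fv.freqs[3] == 1.0

    def test_tally_of_equal_lengths(self):
        rep = rep_from_rows([{"junction_aa": "C" + "A" * 11 + "W"}] * 2)
        fv = cdr3_length_distribution(rep)
        assert fv.freqs[11] == 1.0 and fv.n == 2

    def test_overflow_bin_collects_long_cdr3(self):
        rep = rep_from_rows([{"junction_aa": "C" + "A" * 40 + "W"}])
        fv = cdr3_length_distribution(rep, cap=30)
        assert fv.freqs[31] == 1.0

    def test_simulated_mean_length_matches_model(self, sim_rep, small_ref):
        rep, snap = sim_rep
        fv = cdr3_length_distribution(rep)
        observed_mean = float((fv.freqs * fv.freqs.index).sum())
        # model mean junction nt length, anchors excluded; productivity
        # selection only keeps multiples of 3 so compare loosely (±1 aa)
        stats = expected_junction_stats(snap)
        v_tail = np.dot(
            snap["v_probs"],
            [len(s.sequence) - s.anchor_offset for s in small_ref.functional(SegmentClass.V)],
        )
        j_head = np.dot(
            snap["j_probs"],
            [s.anchor_offset + 3 for s in small_ref.functional(SegmentClass.J)],
        )
        mean_nt = (
            v_tail
            - stats["v3_trim"]["mean"]
            + stats["d_retained_len"]["mean"]
            + stats["n1_len"]["mean"]
            + stats["n2_len"]["mean"]
            + j_head
            - stats["j5_trim"]["mean"]
            # palindromes add max_p nt when present (upper bound p * max_p each)
        )
        assert observed_mean == pytest.approx(mean_nt / 3 - 2, abs=1.0)


class TestComposition:
    def test_pooled_tally(self):
        rep = rep_from_rows([{"junction_aa": "C" + "AAAG" + "W"}])
        comp = cdr3_aa_composition(rep, length_set=(4,))
        assert comp[4].freqs["A"] == 0.75 and comp[4].freqs["G"] == 0.25

    def test_missing_length_class_marked_empty(self):
        rep = rep_from_rows([{"junction_aa": "C" + "A" * 11 + "W"}])
        comp = cdr3_aa_composition(rep, length_set=(11, 14))
        assert not comp[11].empty and comp[14].empty

    def test_empty_length_set_rejected(self):
        rep = rep_from_rows([{"junction_aa": "CAAAW"}])
        with pytest.raises(ValueError):
            cdr3_aa_composition(rep, length_set=())


class TestJunctionMetrics:
    def _rep(self, **over):
        row = {
            "v3_trim": 0,
            "d5_trim": 0,
            "d3_trim": 0,
            "j5_trim": 0,
            "d_retained_len": 10,
            "p3v_len": 0,
            "p5d_len": 0,
            "p3d_len": 0,
            "p5j_len": 0,
            "n1_len": 0,
            "n2_len": 0,
        }
        row.update(over)
        return rep_from_rows([row])

    def test_n_bin_boundary_at_seven(self):
        assert junction_metrics(self._rep(n1_len=3, n2_len=4))["n_added_bins"].freqs["ge7"] == 1.0
        assert junction_metrics(self._rep(n1_len=3, n2_len=3))["n_added_bins"].freqs["le6"] == 1.0

    def test_palindrome_bins(self):
        out = junction_metrics(self._rep(p3v_len=2))
        assert out["palindrome_vd"].freqs["with"] == 1.0
        assert out["palindrome_dj"].freqs["without"] == 1.0

    def test_no_palindrome_simulation_gives_all_without(self, small_ref):
        cfg = SimulationConfig(
            n_sequences=400, seed=3, p_palindrome={e: 0.0 for e in ("v3", "d5", "d3", "j5")}
        )
        df, _ = simulate_repertoire(cfg, small_ref)
        rep = clean_repertoire(df, "lib", "g")
        out = junction_metrics(rep)
        assert out["palindrome_vd"].freqs["without"] == 1.0
        assert out["palindrome_dj"].freqs["without"] == 1.0

    def test_nod_records_excluded_from_d_len(self):
        rep = rep_from_rows(
            [
                {"d_call": "D1", "d_retained_len": 8, "v3_trim": 0, "d5_trim": 0,
                 "d3_trim": 0, "j5_trim": 0, "p3v_len": 0, "p5d_len": 0, "p3d_len": 0,
                 "p5j_len": 0, "n1_len": 0, "n2_len": 0},
                {"d_call": "", "d_retained_len": 0, "v3_trim": 0, "d5_trim": 0,
                 "d3_trim": 0, "j5_trim": 0, "p3v_len": 0, "p5d_len": 0, "p3d_len": 0,
                 "p5j_len": 0, "n1_len": 0, "n2_len": 0},
            ]
        )
        fv = junction_metrics(rep)["d_len"]
        assert fv.n == 1 and fv.freqs[8] == 1.0

    def test_decomposition_required(self):
        rep = rep_from_rows([{"v_call": "V1"}], has_decomposition=False)
        with pytest.raises(ValueError, match="decomposition"):
            junction_metrics(rep)

    def test_mean_retained_d_matches_exact_oracle(self, small_ref):
        # raw (unselected) records so the generative law applies exactly
        cfg = SimulationConfig(n_sequences=20_000, seed=31, productive_only=False)
        df, snap = simulate_repertoire(cfg, small_ref)
        stats = expected_junction_stats(snap)
        mean, var = stats["d_retained_len"]["mean"], stats["d_retained_len"]["var"]
        se = np.sqrt(var / len(df))
        assert abs(df.d_retained_len.mean() - mean) < 3 * se


class TestComputeFeatures:
    def test_all_fourteen_families_present(self, sim_rep, small_ref):
        rep, _ = sim_rep
        ft = compute_features(rep, small_ref)
        assert sorted(ft.families) == sorted(FEATURE_FAMILIES)

    def test_all_vectors_sum_to_one(self, sim_rep, small_ref):
        rep, _ = sim_rep
        ft = compute_features(rep, small_ref)
        for name, fv in ft.vectors.items():
            if not fv.empty:
                assert fv.freqs.sum() == pytest.approx(1.0, abs=1e-9), name

    def test_decomposition_free_input_skips_junction_families(self, sim_rep, small_ref):
        rep, _ = sim_rep
        df = rep.records.drop(columns=["n1_len"]).copy()
        df.attrs["has_decomposition"] = False
        slim = CleanRepertoire(
            "lib", "g", df, n_input=rep.n_input, n_filtered=rep.n_filtered,
            n_unique=rep.n_unique, has_decomposition=False,
        )
        ft = compute_features(slim, small_ref)
        assert "d_len" not in ft.families and "v_usage" in ft.families

    def test_frequency_vector_validates_sum(self):
        with pytest.raises(ValueError, match="sum"):
            FrequencyVector("bad", pd.Series([0.5, 0.4]), K=2, n=10)
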