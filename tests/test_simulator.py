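import numpy as np
import pandas as pd
import pytest

from vdjrep import germline, simulate
from vdjrep.germline import SegmentClass
from vdjrep.simulate import (
    ProductivityReason,
    SimulationConfig,
    apply_condition_effect,
    determine_productivity,
    expected_junction_stats,
    revcomp,
    sample_rearrangement,
    simulate_repertoire,
    translate,
    truncated_geometric_pmf,
    write_airr,
)


def quiet_config(**kw) -> SimulationConfig:
    """A config with every junction-modifying process switched off."""
    base = dict(
        p_trim={e: 0.0 for e in simulate.TRIM_ENDS},
        max_trim={e: 0 for e in simulate.TRIM_ENDS},
        p_palindrome={e: 0.0 for e in simulate.TRIM_ENDS},
        n_mean={"vd": 0.0, "dj": 0.0},
        productive_only=False,
    )
    base.update(kw)
    return SimulationConfig(**base)


def v_tail(ref, name):
    seg = ref.get(SegmentClass.V, name)
    return seg.sequence[seg.anchor_offset :]


def j_head(ref, name):
    seg = ref.get(SegmentClass.J, name)
    return seg.sequence[: seg.anchor_offset + 3]


class TestDegenerateConfig:
    def test_junction_is_vtail_d_jhead_with_zero_decomposition(self, tiny_ref):
        df, _ = simulate_repertoire(quiet_config(n_sequences=50, seed=5), tiny_ref)
        for rec in df.itertuples():
            d_seq = tiny_ref.get(SegmentClass.D, rec.d_call).sequence
            assert rec.junction == v_tail(tiny_ref, rec.v_call) + d_seq + j_head(
                tiny_ref, rec.j_call
            )
        for f in simulate.DECOMPOSITION_FIELDS:
            if f == "d_retained_len":
                continue
            assert (df[f] == 0).all(), f


class TestPalindromes:
    def test_p3v_is_revcomp_of_v_terminal_dinucleotide(self, tiny_ref):
        # V1 tail ends ...AG; with certain palindromes and no trimming the
        # 3'V P insertion must read CT
        cfg = quiet_config(
            n_sequences=40,
            seed=1,
            p_palindrome={"v3": 1.0, "d5": 0.0, "d3": 0.0, "j5": 0.0},
            max_p=2,
            v_weights={"V1": 1.0},
        )
        df, _ = simulate_repertoire(cfg, tiny_ref)
        assert (df.p3v_len == 2).all()
        tail = v_tail(tiny_ref, "V1")
        assert tail.endswith("AG")
        for rec in df.itertuples():
            assert rec.junction[len(tail) : len(tail) + 2] == "CT"

    def test_p_nucleotides_only_at_untrimmed_ends(self, small_ref):
        cfg = SimulationConfig(n_sequences=4000, seed=9, productive_only=False)
        df, _ = simulate_repertoire(cfg, small_ref)
        for p_col, t_col in (
            ("p3v_len", "v3_trim"),
            ("p5d_len", "d5_trim"),
            ("p3d_len", "d3_trim"),
            ("p5j_len", "j5_trim"),
        ):
            assert (df.loc[df[p_col] > 0, t_col] == 0).all()


class TestDecompositionIdentity:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_lengths_sum_exactly(self, small_ref, seed):
        cfg = SimulationConfig(n_sequences=3000, seed=seed, productive_only=False)
        df, _ = simulate_repertoire(cfg, small_ref)
        vt = {s.name: len(s.sequence) - s.anchor_offset for s in small_ref.functional(SegmentClass.V)}
        jh = {s.name: s.anchor_offset + 3 for s in small_ref.functional(SegmentClass.J)}
        dl = {s.name: len(s.sequence) for s in small_ref.functional(SegmentClass.D)}
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
        assert (df.junction.str.len() == rhs).all()
        assert (df.d_retained_len == df.d_call.map(dl) - df.d5_trim - df.d3_trim).all()
        assert (df.d_retained_len >= 0).all()


class TestUsageSampling:
    def test_empirical_v_frequencies_match_weights(self, tiny_ref):
        # binomial sampling error: 3*sqrt(p(1-p)/n) < 0.015 for n=10000
        cfg = quiet_config(
            n_sequences=10_000, seed=4, v_weights={"V1": 0.6, "V2": 0.3, "V3": 0.1}
        )
        df, _ = simulate_repertoire(cfg, tiny_ref)
        freqs = df.v_call.value_counts(normalize=True)
        for gene, p in (("V1", 0.6), ("V2", 0.3), ("V3", 0.1)):
            assert abs(freqs.get(gene, 0.0) - p) < 0.02


class TestProductivity:
    def test_out_of_frame_by_length(self):
        junction = "A" * 38
        ok, reason = determine_productivity(junction)
        assert not ok and reason is ProductivityReason.OUT_OF_FRAME

    def test_caw_junction_is_productive(self):
        ok, reason = determine_productivity("TGTGCGTGG")
        assert ok and reason is ProductivityReason.IN_FRAME_NO_STOP
        assert translate("TGTGCGTGG") == "CAW"

    def test_stop_codon_detected(self):
        ok, reason = determine_productivity("TGTTAATGG")
        assert not ok and reason is ProductivityReason.STOP_CODON

    def test_wrong_anchors_flagged(self):
        ok, reason = determine_productivity("AAAGCGTGG")
        assert not ok and reason is ProductivityReason.ANCHOR_MISMATCH

    def test_short_junction_out_of_frame_by_convention(self):
        ok, reason = determine_productivity("TGT")
        assert not ok and reason is ProductivityReason.OUT_OF_FRAME

    def test_productive_only_repertoires_are_all_productive(self, small_ref):
        df, _ = simulate_repertoire(SimulationConfig(n_sequences=2000, seed=3), small_ref)
        assert df.productive.all()
        for j in df.junction.head(200):
            ok, _ = determine_productivity(j)
            assert ok

    def test_frame_mixing_yields_one_third_in_frame(self, small_ref):
        # trims and Poisson N additions spread junction length mod 3 nearly
        # uniformly, so ~1/3 of unselected records are in frame and
        # productive = in-frame AND stop-free AND anchored
        cfg = SimulationConfig(n_sequences=30_000, seed=6, productive_only=False)
        df, _ = simulate_repertoire(cfg, small_ref)
        in_frame = (df.junction.str.len() % 3 == 0) & (df.junction.str.len() >= 6)
        assert abs(in_frame.mean() - 1 / 3) < 0.02

        def expected_productive(j):
            return len(j) % 3 == 0 and len(j) >= 6 and "*" not in translate(j)

        assert (df.productive == df.junction.map(expected_productive)).all()

    def test_nonfunctional_fraction_retained(self, small_ref):
        cfg = SimulationConfig(n_sequences=1000, seed=8, nonfunctional_fraction=0.2)
        df, _ = simulate_repertoire(cfg, small_ref)
        assert len(df) == 1000
        assert (~df.productive).sum() == 200


class TestConditionEffects:
    def test_control_is_identity(self, small_ref):
        base = SimulationConfig(seed=1)
        out = apply_condition_effect(base, "control", small_ref)
        assert out == base

    def test_hu_scales_only_distal_weights(self, small_ref):
        base = SimulationConfig(seed=1, distal_v_factor=2.0)
        hu = apply_condition_effect(base, "HU", small_ref)
        by_zone = {}
        for seg in small_ref.functional(SegmentClass.V):
            by_zone.setdefault(seg.zone.value, []).append(hu.v_weights[seg.name])
        # median/proximal weights untouched (still the uniform base weight)
        assert all(w == 1.0 for w in by_zone["median"] + by_zone["proximal"])
        # distal weights form a decreasing 5'->3' gradient in (1, factor]
        distal = by_zone["distal"]
        assert distal == sorted(distal, reverse=True)
        assert distal[0] == pytest.approx(2.0) and distal[-1] == pytest.approx(1.0)
        # non-weight parameters untouched by HU
        assert hu.p_trim == base.p_trim and hu.n_mean == base.n_mean

    def test_aged_reduces_d_trims_and_raises_n_and_dj_palindromes(self, small_ref):
        base = SimulationConfig(seed=1, d_trim_scale=0.5, n_mean_scale=1.5)
        aged = apply_condition_effect(base, "aged", small_ref)
        assert aged.p_trim["d5"] == pytest.approx(base.p_trim["d5"] * 0.5)
        assert aged.p_trim["v3"] == base.p_trim["v3"]
        assert aged.n_mean["dj"] == pytest.approx(base.n_mean["dj"] * 1.5)
        assert aged.p_palindrome["d3"] > base.p_palindrome["d3"]
        assert aged.p_palindrome["v3"] == base.p_palindrome["v3"]
        # expected D-end deletions decrease; expected retained D increases
        from vdjrep.simulate import _Machinery

        stats_base = expected_junction_stats(_Machinery(base, small_ref).snapshot())
        stats_aged = expected_junction_stats(_Machinery(aged, small_ref).snapshot())
        assert stats_aged["d5_trim"]["mean"] < stats_base["d5_trim"]["mean"]
        assert stats_aged["d_retained_len"]["mean"] > stats_base["d_retained_len"]["mean"]

    def test_unknown_condition_rejected(self, small_ref):
        with pytest.raises(ValueError, match="unknown condition"):
            apply_condition_effect(SimulationConfig(), "weightless", small_ref)


class TestRepertoireApi:
    def test_zero_sequences_gives_empty_table_and_snapshot(self, small_ref):
        df, snap = simulate_repertoire(SimulationConfig(n_sequences=0, seed=1), small_ref)
        assert len(df) == 0 and "junction" in df.columns
        assert snap["v_genes"]

    def test_same_seed_same_table(self, small_ref):
        cfg = SimulationConfig(n_sequences=500, seed=42)
        a, _ = simulate_repertoire(cfg, small_ref)
        b, _ = simulate_repertoire(cfg, small_ref)
        pd.testing.assert_frame_equal(a, b)

    def test_sample_rearrangement_single_record(self, tiny_ref):
        rng = np.random.default_rng(0)
        rec = sample_rearrangement(quiet_config(), tiny_ref, rng)
        assert rec.junction.startswith(v_tail(tiny_ref, rec.v_call))


class TestTruncatedGeometric:
    def test_pmf_normalizes_and_zero_q_is_point_mass(self):
        pmf = truncated_geometric_pmf(0.6, 7)
        assert pmf.sum() == pytest.approx(1.0)
        assert truncated_geometric_pmf(0.0, 5)[0] == 1.0

    def test_sampler_matches_pmf(self):
        from vdjrep.simulate import _sample_trunc_geom

        rng = np.random.default_rng(12)
        draws = _sample_trunc_geom(rng, 0.6, np.full(50_000, 7))
        pmf = truncated_geometric_pmf(0.6, 7)
        emp = np.bincount(draws, minlength=8) / len(draws)
        assert np.abs(emp - pmf).max() < 0.01


class TestAirrIO:
    def test_three_records_four_lines(self, small_ref, tmp_path):
        df, _ = simulate_repertoire(SimulationConfig(n_sequences=3, seed=2), small_ref)
        path = tmp_path / "lib.tsv"
        write_airr(df, path)
        assert len(path.read_text().splitlines()) == 4

    def test_round_trip_preserves_fields(self, small_ref, tmp_path):
        from vdjrep.ingest import read_rearrangements

        df, _ = simulate_repertoire(SimulationConfig(n_sequences=200, seed=2), small_ref)
        path = tmp_path / "lib.tsv"
        write_airr(df, path)
        back = read_rearrangements(path)
        assert back.attrs["has_decomposition"]
        for col in ["v_call", "d_call", "j_call", "junction", "junction_aa"] + list(
            simulate.DECOMPOSITION_FIELDS
        ):
            assert (back[col] == df[col]).all(), col
        assert (back.productive == df.productive).all()

    def test_empty_table_round_trips(self, small_ref, tmp_path):
        from vdjrep.ingest import read_rearrangements

        df, _ = simulate_repertoire(SimulationConfig(n_sequences=0, seed=2), small_ref)
        path = tmp_path / "empty.tsv"
        write_airr(df, path)
        back = read_rearrangements(path)
        assert len(back) == 0


def test_revcomp():
    assert revcomp("AG") == "CT"
    assert revcomp("GATC") == "GATC"
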