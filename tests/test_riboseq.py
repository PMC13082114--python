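import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uorfded.annotation import Span, TranscriptModel, UORFRecord
from uorfded.riboseq import (
    FeatureCountTable,
    SampleMeta,
    assign_psites,
    classify_dependence,
    compute_crd,
    compute_te,
    count_features,
    delta_crd,
    differential_te,
    filter_features,
    metagene_profile,
    size_factors,
)


class TestAssignPsites:
    def test_single_read_offset(self):
        track, dropped = assign_psites([(10, 28)], 400, {28: 12})
        assert track[22] == 1 and track.sum() == 1 and dropped == 0

    def test_out_of_range_psite_dropped(self):
        track, dropped = assign_psites([(395, 28)], 400, {28: 12})
        assert track.sum() == 0 and dropped == 1

    def test_missing_offset_errors_without_default(self):
        with pytest.raises(KeyError):
            assign_psites([(0, 31)], 400, {28: 12})
        track, _ = assign_psites([(0, 31)], 400, {28: 12}, default_offset=13)
        assert track[13] == 1

    @given(st.lists(st.tuples(st.integers(0, 399), st.integers(25, 34)), max_size=200))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_read_conservation(self, reads):
        """Column sum of the track equals reads placed minus drops."""
        offsets = {n: 12 for n in range(25, 35)}
        track, dropped = assign_psites(reads, 400, offsets)
        assert track.sum() + dropped == len(reads)


class TestCountFeatures:
    def test_utr5_edge_exclusion(self, toy_transcript):
        track = np.zeros(400, dtype=int)
        for p in (0, 1, 2, 5, 27, 28, 29):
            track[p] += 1
        counts = count_features(track, toy_transcript, assay="RPF")
        assert counts["TOY1:utr5"] == 1  # only position 5 survives

    def test_morf_first_20_codons_excluded(self, toy_transcript):
        track = np.zeros(400, dtype=int)
        track[89] = 1  # inside [30, 90) exclusion zone
        track[95] = 1
        counts = count_features(track, toy_transcript, assay="RPF")
        assert counts["TOY1:morf"] == 1

    def test_mrna_counting_uses_full_spans(self, toy_transcript):
        track = np.ones(400, dtype=int)
        counts = count_features(track, toy_transcript, assay="MRNA")
        assert counts["TOY1:utr5"] == 30
        assert counts["TOY1:morf"] == 300
        assert counts["TOY1:utr3"] == 70

    def test_empty_track(self, toy_transcript, toy_uorf):
        counts = count_features(np.zeros(400, dtype=int), toy_transcript, [toy_uorf])
        assert all(v == 0 for v in counts.values())

    def test_short_utr5_counts_zero_with_warning(self):
        tm = TranscriptModel("S1", 100, Span(0, 4), Span(4, 94), Span(94, 100))
        with pytest.warns(UserWarning, match="5'UTR shorter"):
            counts = count_features(np.ones(100, dtype=int), tm, assay="RPF")
        assert counts["S1:utr5"] == 0

    def test_conservation_with_exclusion_zones(self, toy_transcript, rng):
        """Feature counts plus reads in the exclusion zones recover the track total."""
        track = rng.poisson(2.0, 400)
        counts = count_features(track, toy_transcript, assay="RPF")
        excluded = track[0:3].sum() + track[27:30].sum() + track[30:90].sum()
        assert counts["TOY1:utr5"] + counts["TOY1:morf"] + counts["TOY1:utr3"] + excluded == track.sum()


def _table(counts: dict[str, list[int]], metas: list[SampleMeta]) -> FeatureCountTable:
    df = pd.DataFrame(counts, index=[m.sample_id for m in metas]).T
    return FeatureCountTable(df, {m.sample_id: m for m in metas})


_RPF2 = [SampleMeta("a", "WT", "RPF", 1), SampleMeta("b", "WT", "RPF", 2)]


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        t = _table({"T1:morf": [10, 10], "T2:morf": [50, 50]}, _RPF2)
        assert np.allclose(size_factors(t, "RPF"), [1.0, 1.0])

    def test_doubled_sample_gives_sqrt2_factors(self):
        t = _table({"T1:morf": [10, 20], "T2:morf": [50, 100], "T3:morf": [8, 16]}, _RPF2)
        assert np.allclose(size_factors(t, "RPF"), [1 / np.sqrt(2), np.sqrt(2)])

    def test_single_sample_gives_one(self):
        t = _table({"T1:morf": [10]}, [SampleMeta("a", "WT", "RPF", 1)])
        assert np.allclose(size_factors(t, "RPF"), [1.0])

    def test_fallback_to_totals_when_no_positive_row(self):
        t = _table({"T1:morf": [0, 10], "T2:morf": [5, 0]}, _RPF2)
        with pytest.warns(UserWarning, match="total-count"):
            f = size_factors(t, "RPF")
        assert np.isclose(np.exp(np.log(f).mean()), 1.0)


_DESIGN = [
    SampleMeta("rpf_wt_1", "WT", "RPF", 1),
    SampleMeta("rpf_wt_2", "WT", "RPF", 2),
    SampleMeta("rpf_mut_1", "MUT", "RPF", 1),
    SampleMeta("rpf_mut_2", "MUT", "RPF", 2),
    SampleMeta("mrna_wt_1", "WT", "MRNA", 1),
    SampleMeta("mrna_wt_2", "WT", "MRNA", 2),
    SampleMeta("mrna_mut_1", "MUT", "MRNA", 1),
    SampleMeta("mrna_mut_2", "MUT", "MRNA", 2),
]


def _design_table(rows: dict[str, list[int]]) -> FeatureCountTable:
    return _table(rows, _DESIGN)


class TestComputeTe:
    def test_direct_ratio_without_pseudocount(self):
        t = _design_table({"T1:morf": [100, 100, 100, 100, 100, 100, 100, 100],
                           "u1": [8, 8, 8, 8, 0, 0, 0, 0]})
        te = compute_te(t, {"u1": "T1"}, factors=pd.Series(1.0, index=t.counts.columns), pseudocount=0.0)
        assert np.isclose(te.loc["u1", "te_wt"], 0.08)
        assert np.isclose(te.loc["T1:morf", "te_wt"], 1.0)

    def test_pseudocount_rule_for_zero_counts(self):
        t = _design_table({"T1:morf": [100, 100, 100, 100, 100, 100, 100, 100],
                           "u1": [0, 0, 0, 0, 0, 0, 0, 0]})
        te = compute_te(t, {"u1": "T1"}, factors=pd.Series(1.0, index=t.counts.columns))
        assert np.isclose(te.loc["u1", "te_wt"], 0.5 / 100.5)

    def test_geometric_mean_over_replicates(self):
        t = _design_table({"T1:morf": [100, 100, 100, 100, 100, 100, 100, 100],
                           "u1": [4, 16, 4, 16, 0, 0, 0, 0]})
        te = compute_te(t, {"u1": "T1"}, factors=pd.Series(1.0, index=t.counts.columns), pseudocount=0.0)
        assert np.isclose(te.loc["u1", "te_wt"], np.sqrt(0.04 * 0.16))


class TestFilterFeatures:
    def test_mrna_threshold_is_128(self):
        t = _design_table({
            "T1:morf": [9, 9, 9, 9, 32, 32, 32, 31],   # mRNA total 127
            "T2:morf": [9, 9, 9, 9, 32, 32, 32, 32],   # mRNA total 128
        })
        retained = filter_features(t, {})
        assert retained == {"T2:morf"}

    def test_uorf_rpf_threshold_is_8(self):
        t = _design_table({
            "T1:morf": [100, 100, 100, 100, 32, 32, 32, 32],
            "u_lo": [2, 2, 2, 1, 0, 0, 0, 0],   # RPF total 7
            "u_hi": [2, 2, 2, 2, 0, 0, 0, 0],   # RPF total 8
        })
        retained = filter_features(t, {"u_lo": "T1", "u_hi": "T1"})
        assert "u_hi" in retained and "u_lo" not in retained

    def test_all_zero_table_retains_nothing(self):
        t = _design_table({"T1:morf": [0] * 8, "u1": [0] * 8})
        assert filter_features(t, {"u1": "T1"}) == set()


class TestDifferentialTe:
    def test_null_identity(self):
        t = _design_table({f"T{i}:morf": [200 + 10 * i] * 8 for i in range(8)})
        res = differential_te(t, factors=pd.Series(1.0, index=t.counts.columns))
        assert np.allclose(res["log2_dte"], 0.0, atol=1e-6)
        assert (res["pvalue"] > 0.5).all()

    def test_two_fold_rpf_increase_recovered(self, rng):
        rows = {}
        for i in range(60):
            base = int(rng.integers(500, 4000))
            rpf_wt = rng.poisson(base, 2)
            rpf_mut = rng.poisson(2 * base, 2)
            mrna = rng.poisson(base, 4)
            rows[f"T{i}:morf"] = list(rpf_wt) + list(rpf_mut) + list(mrna)
        t = _design_table(rows)
        res = differential_te(t, factors=pd.Series(1.0, index=t.counts.columns))
        assert abs(res["log2_dte"].median() - 1.0) < 0.1

    def test_fdr_within_families(self):
        rows = {f"T{i}:morf": [200] * 8 for i in range(4)}
        rows.update({f"u{i}": [50] * 8 for i in range(4)})
        t = _design_table(rows)
        res = differential_te(t, uorf_hosts={f"u{i}": f"T{i}" for i in range(4)},
                              factors=pd.Series(1.0, index=t.counts.columns))
        assert set(res["family"]) == {"morf", "uorf_utr5"}


class TestClassifyDependence:
    @pytest.mark.parametrize(
        "log2_dte,fdr,fold,fdr_cut,expected",
        [
            (-1.2, 0.001, 1.5, 0.05, "HYPER"),
            (-1.2, 0.2, 1.5, 0.05, "UNCHANGED"),
            (-0.9, 0.001, 2.0, 0.01, "UNCHANGED"),  # |log2| < 1 at the 2-fold rule
            (1.1, 0.001, 2.0, 0.01, "HYPO"),
            (np.nan, np.nan, 1.5, 0.05, "FILTERED"),
        ],
    )
    def test_classes(self, log2_dte, fdr, fold, fdr_cut, expected):
        df = pd.DataFrame({"log2_dte": [log2_dte], "fdr": [fdr]}, index=["f"])
        assert classify_dependence(df, fold, fdr_cut).iloc[0] == expected


class TestCrd:
    def test_point_mass(self):
        track = np.zeros(20, dtype=int)
        track[7] = 10
        assert compute_crd(track) == 7

    def test_uniform_ten_positions(self):
        track = np.zeros(10, dtype=int)
        track[:10] = 1
        assert compute_crd(track) == 4

    def test_two_reads(self):
        track = np.zeros(10, dtype=int)
        track[2] = track[8] = 1
        assert compute_crd(track) == 2

    def test_empty_track_undefined(self):
        assert np.isnan(compute_crd(np.zeros(10, dtype=int)))

    @given(st.lists(st.integers(0, 5), min_size=1, max_size=60))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_cumulative_scan_oracle(self, counts):
        track = np.asarray(counts)
        total = track.sum()
        if total == 0:
            assert np.isnan(compute_crd(track))
            return
        running = 0
        for p, c in enumerate(track):  # brute-force scan
            running += c
            if running >= total / 2:
                expected = p
                break
        assert compute_crd(track) == expected


class TestDeltaCrd:
    def test_identical_replicates_zero(self):
        assert delta_crd([50, 50], [50, 50], 100) == 0.0

    def test_downstream_shift_positive(self):
        assert np.isclose(delta_crd([60, 70], [50, 50], 100), 0.15)

    def test_upstream_shift_negative(self):
        assert np.isclose(delta_crd([40], [50], 100), -0.10)

    def test_nan_replicate_propagates(self):
        assert np.isnan(delta_crd([np.nan, 50], [50], 100))

    def test_unnormalized_option(self):
        assert np.isclose(delta_crd([40], [50], 100, normalize=False), -10.0)


class TestMetagene:
    def _transcripts(self, n=5):
        return {f"T{i}": TranscriptModel(f"T{i}", 400, Span(0, 100), Span(100, 340), Span(340, 400))
                for i in range(n)}

    def test_uniform_density_gives_flat_profile(self):
        trs = self._transcripts()
        tracks = {tid: np.full(400, 3, dtype=int) for tid in trs}
        pos, prof = metagene_profile(tracks, trs, window=(-20, 40))
        assert pos[0] == -20 and pos[-1] == 40
        assert np.allclose(prof, 1.0)

    def test_anchor_spike_peaks_at_zero(self, rng):
        trs = self._transcripts()
        tracks = {}
        for tid in trs:
            t = rng.poisson(5.0, 400)
            t[100] += 60  # 3x-style spike at the mORF start
            tracks[tid] = t
        pos, prof = metagene_profile(tracks, trs, window=(-20, 40))
        assert prof[np.where(pos == 0)[0][0]] > prof[pos != 0].mean() * 2

    def test_single_transcript_equals_own_normalized_density(self, rng):
        trs = self._transcripts(1)
        track = rng.poisson(4.0, 400)
        pos, prof = metagene_profile({"T0": track}, trs, window=(-10, 10))
        seg = track[90:111].astype(float)
        assert np.allclose(prof, seg / seg.mean())

    def test_no_qualifying_transcripts_errors(self):
        trs = self._transcripts(1)
        with pytest.raises(ValueError, match="qualify"):
            metagene_profile({"T0": np.zeros(400, dtype=int)}, trs, window=(-10, 10))
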