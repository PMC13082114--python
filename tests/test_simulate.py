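import numpy as np
import pandas as pd
import pytest

from uorfded.annotation import validate_annotation
from uorfded.facs import estimate_reporter_expression, summarize_library
from uorfded.riboseq import count_features, metagene_profile
from uorfded.simulate import (
    FacsSimConfig,
    RiboSimConfig,
    figure4a_scenario,
    generate_annotation,
    simulate_facs,
    simulate_pars,
    simulate_riboseq,
)
from uorfded.structure import window_score


class TestGenerateAnnotation:
    def test_deterministic_for_fixed_seed(self):
        cfg = RiboSimConfig(seed=1, n_transcripts=100)
        t1, u1, truth1 = generate_annotation(cfg)
        t2, u2, truth2 = generate_annotation(cfg)
        assert t1 == t2
        assert u1.records == u2.records
        pd.testing.assert_frame_equal(truth1, truth2)

    def test_zero_uorf_fraction(self):
        cfg = RiboSimConfig(seed=2, n_transcripts=50, uorf_fraction=0.0)
        _, comp, _ = generate_annotation(cfg)
        assert len(comp) == 0

    def test_uorf_bearing_fraction_within_binomial_bounds(self):
        cfg = RiboSimConfig(seed=3, n_transcripts=1000, uorf_fraction=0.4)
        _, comp, _ = generate_annotation(cfg)
        n_bearing = len({r.transcript_id for r in comp})
        half_width = 2.58 * np.sqrt(1000 * 0.4 * 0.6)  # 99% binomial interval
        assert abs(n_bearing - 400) <= half_width

    def test_generated_annotation_is_valid(self):
        cfg = RiboSimConfig(seed=4, n_transcripts=200)
        transcripts, comp, _ = generate_annotation(cfg)
        assert validate_annotation(transcripts, comp) == []

    def test_seed_mandatory_and_config_validated(self):
        with pytest.raises(ValueError):
            RiboSimConfig(seed=None)
        with pytest.raises(ValueError):
            RiboSimConfig(seed=1, dispersion=-1.0)
        with pytest.raises(ValueError):
            RiboSimConfig(seed=1, frac_morf_down=0.7, frac_morf_up=0.7)


class TestSimulateRiboseq:
    def test_table_consistent_with_tracks(self):
        """With tracks on, the returned table is exactly count_features of them."""
        cfg = RiboSimConfig(seed=5, n_transcripts=30)
        transcripts, comp, truth = generate_annotation(cfg)
        res = simulate_riboseq(transcripts, comp, truth, cfg)
        by_tid = comp.by_transcript()
        sid = "rpf_wt_1"
        tid = list(transcripts)[0]
        expected = count_features(res.rpf_tracks[sid][tid], transcripts[tid], by_tid.get(tid, []), "RPF")
        for fid, c in expected.items():
            assert res.table.counts.loc[fid, sid] == c

    def test_deterministic(self):
        cfg = RiboSimConfig(seed=6, n_transcripts=20)
        a = simulate_riboseq(*generate_annotation(cfg), cfg)
        b = simulate_riboseq(*generate_annotation(cfg), cfg)
        pd.testing.assert_frame_equal(a.table.counts, b.table.counts)

    def test_chx_artifact_creates_start_codon_peak(self):
        def profile(chx):
            cfg = RiboSimConfig(seed=7, n_transcripts=60, uorf_fraction=0.0, chx_artifact=chx)
            transcripts, comp, truth = generate_annotation(cfg)
            res = simulate_riboseq(transcripts, comp, truth, cfg)
            pooled = {
                tid: sum(res.rpf_tracks[s][tid] for s in res.rpf_tracks)
                for tid in transcripts
            }
            return metagene_profile(pooled, transcripts, window=(-20, 40))

        pos, on = profile(True)
        _, off = profile(False)
        peak_zone = (pos >= 0) & (pos < 15)
        flank = pos > 20
        assert on[peak_zone].mean() >= 2 * on[flank].mean()
        assert off[peak_zone].mean() < 1.5 * off[flank].mean()


class TestSimulatePars:
    def test_planted_blocks_separate_window_scores(self):
        cfg = RiboSimConfig(seed=8, n_transcripts=400, uorf_fraction=0.6, utr5_median=120)
        transcripts, comp, _ = generate_annotation(cfg)
        ids = [r.uorf_id for r in comp]
        planted = ids[: len(ids) // 2]
        profiles, truth = simulate_pars(transcripts, comp, planted, seed=9)
        scores = {}
        for rec in comp:
            ws = window_score(profiles[rec.transcript_id], rec.span.start, (16, 45))
            scores[rec.uorf_id] = ws.score
        applied = truth[truth["applied"]].index
        unplanted = truth[~truth["planted"]].index
        med_p = np.nanmedian([scores[u] for u in applied])
        med_n = np.nanmedian([scores[u] for u in unplanted])
        assert med_p - med_n >= 60  # 30 nt x +3 minus noise margin
        assert abs(med_n) < 5

    def test_no_blocks_mean_score_near_zero(self):
        cfg = RiboSimConfig(seed=10, n_transcripts=300, uorf_fraction=0.8, utr5_median=120)
        transcripts, comp, _ = generate_annotation(cfg)
        profiles, _ = simulate_pars(transcripts, comp, [], seed=11)
        vals = [
            window_score(profiles[r.transcript_id], r.span.start, (16, 45)).score for r in comp
        ]
        vals = np.asarray(vals, dtype=float)
        assert abs(np.nanmean(vals)) < 0.2 * np.sqrt(500 / np.isfinite(vals).sum() * 30)

    def test_deterministic(self):
        cfg = RiboSimConfig(seed=12, n_transcripts=20)
        transcripts, comp, _ = generate_annotation(cfg)
        p1, _ = simulate_pars(transcripts, comp, [], seed=13)
        p2, _ = simulate_pars(transcripts, comp, [], seed=13)
        for tid in p1:
            assert np.array_equal(p1[tid], p2[tid])


class TestSimulateFacs:
    def test_bin_occupancy_near_uniform(self):
        cfg = FacsSimConfig(seed=14, n_uorfs=200)
        mats, _ = simulate_facs(cfg)
        for mat in mats[:2]:
            frac = mat.counts.to_numpy().sum(axis=0) / mat.counts.to_numpy().sum()
            assert np.all(np.abs(frac - 0.125) < 0.02)

    def test_effect_recovery_without_interaction(self):
        """True effect 0.5 in both strains: estimates within 0.1 on
        fluorescence-valued bins (index bins compress toward 1), ratios ~1
        on either scale because the compression cancels."""
        base = dict(
            seed=15, n_uorfs=40, fraction_repressive=1.0, repressive_effect=0.5,
            cells_per_reporter=4000, reads_per_reporter=4000,
        )
        mats, truth = simulate_facs(FacsSimConfig(**base, bin_value_mode="fluorescence"))
        table, _ = summarize_library(mats)
        est_wt = table["effect_wt_strain"].to_numpy()
        assert np.nanmedian(np.abs(est_wt - 0.5)) < 0.1
        assert abs(np.nanmedian(table["effect_ratio"]) - 1.0) < 0.1
        mats_idx, _ = simulate_facs(FacsSimConfig(**base))
        table_idx, _ = summarize_library(mats_idx)
        assert abs(np.nanmedian(table_idx["effect_ratio"]) - 1.0) < 0.1

    def test_monotone_in_interaction_strength(self):
        """Stronger planted interactions yield weakly more suppressed calls."""
        counts = []
        for ratio in (1.0, 0.7, 0.4):
            cfg = FacsSimConfig(
                seed=16, n_uorfs=60, fraction_repressive=1.0, repressive_effect=0.6,
                fraction_suppressed=0.5, suppressed_ratio=ratio,
            )
            mats, truth = simulate_facs(cfg)
            table, _ = summarize_library(mats)
            counts.append(int((table["modulation"] == "ded1_suppressed").sum()))
        assert counts[0] <= counts[1] <= counts[2]

    def test_truth_records_classes(self):
        cfg = FacsSimConfig(seed=17, n_uorfs=100, fraction_suppressed=0.2, fraction_enhanced=0.1)
        _, truth = simulate_facs(cfg)
        assert (truth["modulation"] == "ded1_suppressed").sum() == 20
        assert (truth["modulation"] == "ded1_enhanced").sum() == 10
        sup = truth[truth["modulation"] == "ded1_suppressed"]
        assert np.allclose(sup["true_effect_ratio"], 0.5)

    def test_deterministic(self):
        cfg = FacsSimConfig(seed=18, n_uorfs=30)
        m1, t1 = simulate_facs(cfg)
        m2, t2 = simulate_facs(cfg)
        pd.testing.assert_frame_equal(m1[0].counts, m2[0].counts)
        pd.testing.assert_frame_equal(t1, t2)


class TestFigure4aScenario:
    def test_planted_truth_matches_schema(self):
        cfg = figure4a_scenario(seed=19)
        _, truth = simulate_facs(
            FacsSimConfig(**{**cfg.__dict__, "cells_per_reporter": 100, "reads_per_reporter": 100})
        )
        row = truth.iloc[0]
        assert row["true_effect_wt_strain"] == 0.5
        assert np.isclose(row["true_effect_mut_strain"], 0.5 / 1.8, atol=1e-12)
        assert np.isclose(row["true_effect_ratio"], (0.5 / 1.8) / 0.5)
        assert row["modulation"] == "ded1_suppressed"
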