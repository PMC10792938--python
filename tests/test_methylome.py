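"""Smoothing, DMR calling (with brute-force oracle), summaries, metaprofiles."""

import numpy as np
import pandas as pd
import pytest

from epirevert.methylome import (
    DMRCallParams,
    MethylomeTrack,
    call_dmrs,
    metaprofile,
    smooth_methylation,
    summarize_dmrs,
    validate_amplicon,
)
from tests.conftest import make_track


def brute_force_dmrs(joined_pos, diffs_by_line, min_cpgs=4, min_delta=0.4):
    """Exhaustive scan over all CpG runs; independent oracle for call_dmrs.

    ``diffs_by_line``: list of per-line smoothed (resistant - parental)
    arrays on the shared CpG universe of one chromosome.  Returns maximal
    qualifying runs as (start_index, end_index_inclusive, sign).
    """
    n = len(joined_pos)
    sign = np.sign(diffs_by_line[0])
    qual = sign != 0
    for d in diffs_by_line:
        qual &= (np.abs(d) >= min_delta) & (np.sign(d) == sign)
    s = np.where(qual, sign, 0)  # per-CpG qualifying sign, 0 = not qualifying

    def run_ok(i, j):
        return s[i] != 0 and all(s[k] == s[i] for k in range(i, j + 1))

    maximal = []
    for i in range(n):
        for j in range(i, n):
            if j - i + 1 >= min_cpgs and run_ok(i, j):
                left_ok = i == 0 or s[i - 1] != s[i]
                right_ok = j == n - 1 or s[j + 1] != s[j]
                if left_ok and right_ok:
                    maximal.append((i, j, int(s[i])))
    return maximal


def _four_tracks(pos, diff_a, diff_b, base=0.2, cov=30):
    """Build parental/resistant tracks for two lines with given R-P diffs."""
    tracks = {}
    for line, diff in (("A", diff_a), ("B", diff_b)):
        p = np.full(len(pos), base)
        r = np.clip(p + diff, 0, 1)
        tracks[(line, "parental")] = make_track(pos, p, line=line, state="parental")
        tracks[(line, "resistant")] = make_track(pos, r, line=line, state="resistant")
    return tracks


class TestSmoothing:
    def test_constant_track_unchanged(self):
        t = make_track(np.arange(0, 1000, 10), np.full(100, 0.8))
        for w in (1, 3, 7):
            s = smooth_methylation(t, w)
            np.testing.assert_allclose(s.records["meth"], 0.8)

    def test_window_one_is_identity(self):
        rng = np.random.default_rng(0)
        t = make_track(np.arange(0, 500, 5), rng.random(100))
        s = smooth_methylation(t, 1)
        pd.testing.assert_frame_equal(s.records, t.records)

    def test_hand_computed_weighted_mean(self):
        t = make_track([10, 20, 30], [0.0, 1.0, 0.0], covs=[10, 10, 10])
        s = smooth_methylation(t, 3)
        assert s.records["meth"].iloc[1] == pytest.approx(1 / 3)

    def test_coverage_weighting(self):
        t = make_track([10, 20, 30], [0.0, 1.0, 0.0], covs=[10, 20, 10])
        s = smooth_methylation(t, 3)
        assert s.records["meth"].iloc[1] == pytest.approx(20 / 40)

    def test_empty_track_returns_empty(self):
        t = make_track([], [])
        assert len(smooth_methylation(t, 5)) == 0

    def test_even_window_rejected(self):
        t = make_track([1], [0.5])
        with pytest.raises(ValueError):
            smooth_methylation(t, 4)


class TestCallDmrs:
    params = DMRCallParams(smoothing_window=1)  # raw levels for exact control

    def test_three_cpg_run_not_called(self):
        pos = np.arange(0, 100, 10)
        diff = np.zeros(10)
        diff[3:6] = 0.5
        dmrs = call_dmrs(_four_tracks(pos, diff, diff), self.params)
        assert dmrs == []

    def test_four_cpg_run_called_with_bounds(self):
        pos = np.arange(0, 100, 10)
        diff = np.zeros(10)
        diff[3:7] = 0.5
        dmrs = call_dmrs(_four_tracks(pos, diff, diff), self.params)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert (d.start, d.end, d.n_cpgs, d.direction) == (30, 62, 4, "hyper")

    def test_single_line_signal_not_called(self):
        pos = np.arange(0, 100, 10)
        diff = np.zeros(10)
        diff[2:8] = 0.5
        dmrs = call_dmrs(_four_tracks(pos, diff, np.zeros(10)), self.params)
        assert dmrs == []

    def test_direction_disagreement_not_called(self):
        pos = np.arange(0, 100, 10)
        diff = np.zeros(10)
        diff[2:8] = 0.5
        tracks = _four_tracks(pos, diff, -diff, base=0.6)
        assert call_dmrs(tracks, self.params) == []

    def test_hypo_direction_reported(self):
        pos = np.arange(0, 100, 10)
        diff = np.zeros(10)
        diff[2:8] = -0.5
        dmrs = call_dmrs(_four_tracks(pos, diff, diff, base=0.7), self.params)
        assert len(dmrs) == 1 and dmrs[0].direction == "hypo"

    def test_runs_split_by_single_non_qualifying_cpg(self):
        pos = np.arange(0, 130, 10)
        diff = np.full(13, 0.5)
        diff[6] = 0.0  # one gap: two runs of 6, not merged
        dmrs = call_dmrs(_four_tracks(pos, diff, diff), self.params)
        assert len(dmrs) == 2
        assert [d.n_cpgs for d in dmrs] == [6, 6]

    def test_mismatched_chromosomes_raise(self):
        pos = np.arange(0, 100, 10)
        tracks = _four_tracks(pos, np.zeros(10), np.zeros(10))
        bad = make_track(pos, np.full(10, 0.2), chrom="chrX", line="B",
                         state="parental")
        tracks[("B", "parental")] = bad
        with pytest.raises(ValueError, match="chr"):
            call_dmrs(tracks, self.params)

    def test_record_order_permutation_invariant(self):
        rng = np.random.default_rng(1)
        pos = np.arange(0, 2000, 10)
        diff = np.where(rng.random(200) < 0.3, 0.5, 0.0)
        tracks = _four_tracks(pos, diff, diff)
        dmrs_sorted = call_dmrs(tracks, self.params)
        shuffled = {
            k: MethylomeTrack(
                t.line_id, t.state, t.records.sample(frac=1, random_state=3)
            )
            for k, t in tracks.items()
        }
        dmrs_shuf = call_dmrs(shuffled, self.params)
        assert [(d.chrom, d.start, d.end) for d in dmrs_sorted] == [
            (d.chrom, d.start, d.end) for d in dmrs_shuf
        ]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_brute_force_oracle_equality(self, seed):
        rng = np.random.default_rng(seed)
        n = 150
        pos = np.sort(rng.choice(5000, size=n, replace=False))
        # random piecewise diffs with both qualifying and non-qualifying CpGs
        diff_a = rng.choice([0.0, 0.45, 0.6, -0.5, 0.2], size=n)
        diff_b = np.where(rng.random(n) < 0.8, diff_a, 0.0)
        base = np.full(n, 0.3)
        tracks = {}
        for line, diff in (("A", diff_a), ("B", diff_b)):
            p = base.copy()
            r = np.clip(base + diff, 0, 1)
            tracks[(line, "parental")] = make_track(pos, p, line=line, state="parental")
            tracks[(line, "resistant")] = make_track(pos, r, line=line, state="resistant")
        dmrs = call_dmrs(tracks, self.params)
        # recompute effective diffs after clipping, as the caller sees them
        eff_a = np.clip(base + diff_a, 0, 1) - base
        eff_b = np.clip(base + diff_b, 0, 1) - base
        expected = brute_force_dmrs(pos, [eff_a, eff_b])
        assert len(dmrs) == len(expected)
        for d, (i, j, sgn) in zip(dmrs, expected):
            assert d.start == pos[i]
            want_end = pos[j] + 2 if j + 1 >= n else min(pos[j] + 2, pos[j + 1])
            assert d.end == want_end
            assert d.direction == ("hyper" if sgn > 0 else "hypo")

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        pos = np.arange(0, 3000, 10)
        diff = rng.choice([0.0, 0.42, 0.55, 0.7], size=300)
        tracks = _four_tracks(pos, diff, diff)
        n_called = {}
        for delta in (0.6, 0.5, 0.4):
            p = DMRCallParams(min_delta=delta, smoothing_window=1)
            n_called[delta] = len(call_dmrs(tracks, p))
        assert n_called[0.4] >= n_called[0.5] >= n_called[0.6]
        for mc in (6, 4, 2):
            p = DMRCallParams(min_cpgs=mc, smoothing_window=1)
            n_called[("mc", mc)] = len(call_dmrs(tracks, p))
        assert n_called[("mc", 2)] >= n_called[("mc", 4)] >= n_called[("mc", 6)]

    def test_state_means_attached_for_all_supplied_states(self, small_methylomes,
                                                          small_config):
        tracks, _ = small_methylomes
        dmrs = call_dmrs(tracks, DMRCallParams())
        assert dmrs
        for d in dmrs:
            for line in small_config.lines:
                for st in ("parental", "resistant", "P5", "P12"):
                    assert (line, st) in d.mean_methylation


class TestSummaries:
    def test_single_dmr_summary(self):
        from epirevert.methylome import DMR

        s = summarize_dmrs([DMR("chr1", 100, 200, 5, "hyper")])
        assert s["count"] == 1
        assert s["hyper_fraction"] == 1.0
        assert s["mean_length"] == 100

    def test_all_hypo_fraction_zero(self):
        from epirevert.methylome import DMR

        dmrs = [DMR("chr1", i * 100, i * 100 + 50, 4, "hypo") for i in range(3)]
        assert summarize_dmrs(dmrs)["hyper_fraction"] == 0.0

    def test_empty_summary_flagged(self):
        s = summarize_dmrs([])
        assert s["empty"] is True and s["count"] == 0

    def test_generator_hyper_fraction_near_planted(self):
        from epirevert.simulate import SimulationConfig, generate_genome, generate_methylomes

        c = SimulationConfig(seed=13, n_chroms=2, chrom_length=800_000,
                             n_planted_dmrs=60, frac_hyper=0.96, noiseless=True,
                             n_cpg_islands=6, n_genes=5)
        g = generate_genome(c)
        tracks, truth = generate_methylomes(g, c)
        dmrs = call_dmrs(tracks, DMRCallParams(smoothing_window=1))
        s = summarize_dmrs(dmrs)
        # binomial 3 sigma around 0.96 with n = 60
        assert abs(s["hyper_fraction"] - 0.96) < 3 * np.sqrt(0.96 * 0.04 / 60) + 1e-9


class TestAmpliconValidation:
    @pytest.mark.parametrize(
        "mp,mr,direction,expected",
        [
            (0.1, 0.4, None, True),
            (0.5, 0.6, None, False),
            (0.3, 0.1, "hyper", False),
            (0.3, 0.1, "hypo", True),
            (0.2, 0.4, "hyper", True),
        ],
    )
    def test_rule(self, mp, mr, direction, expected):
        assert validate_amplicon(mp, mr, wgbs_direction=direction) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            validate_amplicon(1.2, 0.5)


class TestMetaprofile:
    def test_constant_track_gives_constant_profile(self):
        t = make_track(np.arange(0, 10_000, 50), np.full(200, 0.7))
        prof = metaprofile([("chr1", 4000, 5000)], t, flank=2000, n_bins=30)
        valid = ~np.isnan(prof)
        np.testing.assert_allclose(prof[valid], 0.7)

    def test_step_track_separates_body_and_flanks(self):
        pos = np.arange(0, 10_000, 20)
        meth = np.where((pos >= 4000) & (pos < 5000), 1.0, 0.0)
        t = make_track(pos, meth)
        prof = metaprofile([("chr1", 4000, 5000)], t, flank=2000, n_bins=30)
        k = 10
        np.testing.assert_allclose(prof[:k], 0.0)
        np.testing.assert_allclose(prof[k : 2 * k], 1.0)
        np.testing.assert_allclose(prof[2 * k :], 0.0)

    def test_missing_flank_bins_are_nan(self):
        t = make_track(np.arange(5000, 6000, 50), np.full(20, 0.5))
        prof = metaprofile([("chr1", 5000, 6000)], t, flank=2000, n_bins=9)
        assert np.isnan(prof[:3]).all()
        assert np.isnan(prof[6:]).all()
        assert np.allclose(prof[3:6], 0.5)

    def test_chromosome_edge_not_an_error(self):
        t = make_track(np.arange(0, 1000, 10), np.full(100, 0.4))
        prof = metaprofile([("chr1", 0, 500)], t, flank=2000, n_bins=6)
        assert np.nanmax(prof) <= 1.0
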