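import numpy as np
import pytest

from fastnr import (
    CallConfig,
    PValueTrack,
    SimConfig,
    call_silencers,
    extend_window,
    find_anchors,
    fraction_filter,
    resolve_overlaps,
    simulate_pair,
    window_pvalue,
)
from fastnr.window_detection import AnchorSite, CandidateWindow


def ptrack(pvals, origin=0, contig="c"):
    return PValueTrack(contig=contig, origin=origin, pvalues=np.asarray(pvals, float))


def window(start, end, p, contig="c"):
    return CandidateWindow(contig=contig, start=start, end=end, window_p=p,
                           passing_fraction=1.0)


class TestFindAnchors:
    def test_conjunction_of_mask_and_pvalue(self):
        track = ptrack(np.full(10, 1e-6))
        mask = np.zeros(10, bool)
        mask[[5, 6]] = True
        anchors = find_anchors(track, mask)
        assert [a.position for a in anchors] == [5, 6]

    def test_all_false_mask_gives_no_anchors(self):
        track = ptrack(np.full(10, 1e-9))
        assert find_anchors(track, np.zeros(10, bool)) == []

    def test_matches_position_by_position_oracle(self, rng):
        pv = 10.0 ** rng.uniform(-8, 0, size=500)
        mask = rng.random(500) < 0.4
        anchors = find_anchors(ptrack(pv), mask, p_thresh=1e-4)
        brute = [i for i in range(500) if mask[i] and pv[i] < 1e-4]
        assert [a.position for a in anchors] == brute


class TestExtendWindow:
    def test_centered_601(self):
        assert extend_window(10_000, 601, 1_000_000) == (9_700, 10_301)

    def test_left_clamp(self):
        assert extend_window(100, 601, 1_000_000) == (0, 401)

    def test_right_clamp_ends_at_contig(self):
        assert extend_window(999, 601, 1_000) == (699, 1_000)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            extend_window(50, 600, 1_000)


class TestFractionFilter:
    def _track_with_passing(self, n_pass, n_total=601):
        pv = np.ones(n_total)
        pv[:n_pass] = 1e-7
        return ptrack(pv)

    def test_three_quarters_boundary_kept(self):
        keep, frac = fraction_filter((0, 601), self._track_with_passing(451))
        assert keep and frac == pytest.approx(451 / 601)

    def test_just_below_three_quarters_discarded(self):
        keep, frac = fraction_filter((0, 601), self._track_with_passing(450))
        assert not keep and frac == pytest.approx(450 / 601)

    def test_all_passing(self):
        keep, frac = fraction_filter((0, 601), self._track_with_passing(601))
        assert keep and frac == 1.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            fraction_filter((5, 5), self._track_with_passing(0))


class TestWindowPvalue:
    def test_constant_track_both_methods(self):
        track = ptrack(np.full(100, 1e-6))
        assert window_pvalue((0, 100), track, "min") == pytest.approx(1e-6)
        assert window_pvalue((0, 100), track, "median") == pytest.approx(1e-6)

    def test_min_picks_sharpest_base(self):
        pv = np.full(100, 1e-5)
        pv[42] = 1e-8
        assert window_pvalue((0, 100), ptrack(pv), "min") == pytest.approx(1e-8)

    def test_min_matches_brute_force(self, rng):
        pv = rng.random(1000)
        track = ptrack(pv)
        for _ in range(20):
            s = int(rng.integers(0, 900))
            e = s + int(rng.integers(1, 100))
            assert window_pvalue((s, e), track, "min") == pv[s:e].min()

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            window_pvalue((0, 10), ptrack(np.ones(10)), "harmonic")


class TestResolveOverlaps:
    def test_smaller_p_wins_shared_region(self):
        a, b = window(0, 601, 1e-8), window(300, 901, 1e-7)
        assert resolve_overlaps([b, a]) == [a]

    def test_disjoint_windows_both_kept(self):
        a, b = window(0, 601, 1e-8), window(1000, 1601, 1e-7)
        assert resolve_overlaps([b, a]) == [a, b]

    def test_chain_keeps_middle_when_it_is_best(self):
        a = window(0, 601, 1e-7)
        b = window(500, 1101, 1e-9)  # overlaps both a and c
        c = window(1000, 1601, 1e-8)
        assert resolve_overlaps([a, b, c]) == [b]

    def test_chain_keeps_flanks_when_middle_is_worst(self):
        a = window(0, 601, 1e-9)
        b = window(500, 1101, 1e-7)
        c = window(1000, 1601, 1e-8)
        assert resolve_overlaps([a, b, c]) == [a, c]

    def test_output_disjoint_and_sorted_on_random_input(self, rng):
        wins = [
            window(s, s + 601, float(p))
            for s, p in zip(rng.integers(0, 20_000, 300), rng.random(300))
        ]
        kept = resolve_overlaps(wins)
        starts = [w.start for w in kept]
        assert starts == sorted(starts)
        assert all(x.end <= y.start for x, y in zip(kept, kept[1:]))
        # best window overall always survives
        best = min(wins, key=lambda w: (w.window_p, w.contig, w.start, w.end))
        assert best in kept


@pytest.fixture(scope="module")
def small_benchmark():
    config = SimConfig(contig_length=40_000, n_regions=2, removal_fraction=0.9, seed=5)
    treat, control, truth = simulate_pair(config)
    return config, treat, control, truth


class TestCallSilencers:
    def test_recovers_spiked_regions(self, small_benchmark):
        config, treat, control, truth = small_benchmark
        calls = call_silencers(treat, control, contig_length=config.contig_length)
        assert calls, "expected calls on a 90%-removal benchmark"
        for t in truth:
            assert any(c.start < t.end and t.start < c.end for c in calls)
        # depletion direction: treat below control over every call
        for c in calls:
            assert c.strength_ratio > 0

    def test_identical_libraries_give_no_calls(self, small_benchmark):
        config, _, control, _ = small_benchmark
        assert call_silencers(control, control, contig_length=config.contig_length) == []

    def test_calls_are_disjoint_sorted_and_deterministic(self, small_benchmark):
        config, treat, control, _ = small_benchmark
        a = call_silencers(treat, control, contig_length=config.contig_length)
        b = call_silencers(treat, control, contig_length=config.contig_length)
        assert a == b
        assert all(x.end <= y.start for x, y in zip(a, a[1:]))

    def test_mismatched_contigs_rejected(self, small_benchmark):
        _, treat, control, _ = small_benchmark
        other = type(control)(contig="other", fragments=control.fragments,
                              total_count=control.total_count)
        with pytest.raises(ValueError):
            call_silencers(treat, other)

    @pytest.mark.parametrize(
        "tighter",
        [
            {"p_thresh": 1e-7},
            {"min_fraction": 0.85},
            {"similarity_threshold": 0.5},
            {"report_thresh": 1e-8},
            {"min_diff": 40},
        ],
    )
    def test_tightening_thresholds_never_adds_calls(self, small_benchmark, tighter):
        config, treat, control, _ = small_benchmark
        base = call_silencers(treat, control, CallConfig(),
                              contig_length=config.contig_length)
        tight = call_silencers(treat, control, CallConfig(**tighter),
                               contig_length=config.contig_length)
        assert len(tight) <= len(base)

    def test_bonferroni_never_yields_more_calls_than_bh(self, small_benchmark):
        config, treat, control, _ = small_benchmark
        bh = call_silencers(treat, control, CallConfig(correction="bh"),
                            contig_length=config.contig_length)
        bonf = call_silencers(treat, control, CallConfig(correction="bonferroni"),
                              contig_length=config.contig_length)
        assert len(bonf) <= len(bh)

    def test_every_call_contains_an_anchor(self, small_benchmark):
        config, treat, control, _ = small_benchmark
        from fastnr.coverage_io import compute_coverage
        from fastnr.nb_stats import prescreen_mask, pvalue_track

        calls = call_silencers(treat, control, contig_length=config.contig_length)
        interval = (0, config.contig_length)
        tcov = compute_coverage(treat, interval)
        ccov = compute_coverage(control, interval)
        track = pvalue_track(tcov, ccov, treat.total_count, control.total_count)
        mask = prescreen_mask(tcov, ccov)
        anchor_pos = np.array([a.position for a in find_anchors(track, mask)])
        for c in calls:
            assert np.any((anchor_pos >= c.start) & (anchor_pos < c.end))
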