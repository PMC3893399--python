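"""Haplotype-origin painting: windowing, frequency tables, the b ratio and its
classification, and the allele-group contrast.  Oracles are brute-force
recomputations written independently of the module under test."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tauroscan.ancestry import (
    INDICUS,
    NO_CALL,
    TAURUS,
    UNDETERMINED,
    allele_group_profile,
    build_windows,
    classify,
    haplotype_frequencies,
    paint_all,
    paint_animal,
    taurine_proportion,
    taurus_probability,
)
from tauroscan.io import MISSING

from conftest import make_gm


def brute_force_paint(target_row, panel_t, panel_i, window_size=10):
    """Independent recomputation: enumerate, count, ratio, threshold."""
    n = len(target_row)
    out = []
    for start in range(0, n - n % window_size, window_size):
        hap = tuple(target_row[start:start + window_size])
        t_haps = [tuple(r) for r in panel_t[:, start:start + window_size]]
        i_haps = [tuple(r) for r in panel_i[:, start:start + window_size]]
        p_bt = Counter(t_haps)[hap] / len(t_haps)
        p_bi = Counter(i_haps)[hap] / len(i_haps)
        if p_bt + p_bi == 0:
            out.append((None, NO_CALL))
            continue
        b = p_bt / (p_bt + p_bi)
        cls = TAURUS if b > 0.6 else INDICUS if b < 0.4 else UNDETERMINED
        out.append((b, cls))
    return out


class TestBuildWindows:
    @pytest.mark.parametrize("n_markers,expected", [(25, 2), (10, 1), (9, 0), (30, 3)])
    def test_floor_division_window_count(self, n_markers, expected):
        windows = build_windows(100 * (1 + np.arange(n_markers)))
        assert len(windows) == expected
        if expected:
            assert windows[0].start == 0 and windows[0].stop == 10
            assert windows[-1].stop == expected * 10

    def test_trailing_markers_warned(self, caplog):
        with caplog.at_level("WARNING"):
            build_windows(100 * (1 + np.arange(25)))
        assert "trailing" in caplog.text

    def test_window_bp_span_uses_first_and_last_marker(self):
        positions = np.array([100, 200, 300, 400])
        (w,) = build_windows(positions, window_size=4)
        assert (w.bp_start, w.bp_end) == (100, 400)


class TestHaplotypeFrequencies:
    def test_counting_example_two_marker_window(self):
        panel_t = make_gm([[0, 0], [0, 1], [0, 1], [1, 1]])
        panel_i = make_gm([[0, 0], [0, 0], [1, 1], [1, 1]])
        (w,) = build_windows(panel_t.positions, window_size=2)
        tab = haplotype_frequencies(panel_t, panel_i, w)
        assert tab.entries["00"] == (0.25, 0.5)
        assert tab.entries["01"] == (0.5, 0.0)
        assert tab.entries["11"] == (0.25, 0.5)

    def test_haplotype_only_in_indicine_panel_gets_zero_taurine_freq(self):
        panel_t = make_gm([[0, 0]])
        panel_i = make_gm([[1, 0]])
        (w,) = build_windows(panel_t.positions, window_size=2)
        tab = haplotype_frequencies(panel_t, panel_i, w)
        assert tab.entries["10"] == (0.0, 1.0)

    def test_missing_haplotypes_excluded_and_empty_panel_errors(self):
        panel_t = make_gm([[0, 0], [MISSING, 1]])
        panel_i = make_gm([[1, 1]])
        (w,) = build_windows(panel_t.positions, window_size=2)
        tab = haplotype_frequencies(panel_t, panel_i, w)
        assert tab.entries["00"][0] == 1.0  # the missing row dropped
        all_missing = make_gm([[MISSING, MISSING]])
        with pytest.raises(ValueError, match="empty"):
            haplotype_frequencies(all_missing, panel_i, w)

    def test_frequencies_sum_to_one_per_panel(self):
        rng = np.random.default_rng(5)
        panel_t = make_gm(rng.integers(0, 2, (50, 10)))
        panel_i = make_gm(rng.integers(0, 2, (50, 10)))
        (w,) = build_windows(panel_t.positions, window_size=10)
        tab = haplotype_frequencies(panel_t, panel_i, w)
        assert sum(v[0] for v in tab.entries.values()) == pytest.approx(1.0)
        assert sum(v[1] for v in tab.entries.values()) == pytest.approx(1.0)

    def test_matches_independent_tally_on_random_panels(self):
        rng = np.random.default_rng(11)
        t = rng.integers(0, 2, (50, 4))
        i = rng.integers(0, 2, (50, 4))
        panel_t, panel_i = make_gm(t), make_gm(i)
        (w,) = build_windows(panel_t.positions, window_size=4)
        tab = haplotype_frequencies(panel_t, panel_i, w)
        for hap, (p_bt, p_bi) in tab.entries.items():
            key = tuple(int(c) for c in hap)
            assert p_bt == pytest.approx(Counter(map(tuple, t))[key] / 50)
            assert p_bi == pytest.approx(Counter(map(tuple, i))[key] / 50)


class TestTaurusProbabilityAndClassify:
    @pytest.mark.parametrize("p_bt,p_bi,expected", [
        (0.3, 0.1, 0.75),
        (0.5, 0.5, 0.5),
        (0.0, 0.4, 0.0),
    ])
    def test_ratio_arithmetic(self, p_bt, p_bi, expected):
        assert taurus_probability(p_bt, p_bi) == pytest.approx(expected)

    def test_unseen_in_both_panels_is_undefined(self):
        assert taurus_probability(0.0, 0.0) is None
        assert classify(None) == NO_CALL

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            taurus_probability(-0.1, 0.5)

    @pytest.mark.parametrize("b,expected", [
        (0.75, TAURUS), (0.61, TAURUS),
        (0.39, INDICUS), (0.0, INDICUS),
        (0.4, UNDETERMINED), (0.6, UNDETERMINED), (0.5, UNDETERMINED),
    ])
    def test_strict_threshold_classification(self, b, expected):
        assert classify(b) == expected

    @given(p=st.floats(0.01, 1.0))
    @settings(deadline=None)
    def test_equal_frequencies_give_half(self, p):
        assert taurus_probability(p, p) == pytest.approx(0.5)

    @given(p_bt=st.floats(0.0, 1.0), p_bi=st.floats(0.01, 1.0),
           delta=st.floats(0.01, 0.5))
    @settings(deadline=None)
    def test_b_monotone_in_taurine_frequency(self, p_bt, p_bi, delta):
        lo = taurus_probability(p_bt, p_bi)
        hi = taurus_probability(min(p_bt + delta, 1.0), p_bi)
        assert hi >= lo


class TestPaint:
    def test_all_windows_indicus_when_b_zero(self):
        panel_t = make_gm([[0, 0, 1, 1]])
        panel_i = make_gm([[1, 1, 0, 0]])
        target = make_gm([[1, 1, 0, 0]])
        paintings = paint_all(target, panel_t, panel_i, window_size=2)
        assert [c.cls for c in paintings["an0"]] == [INDICUS, INDICUS]

    def test_missing_genotype_gives_no_call_only_there(self):
        panel_t = make_gm([[0, 0, 0, 0]])
        panel_i = make_gm([[1, 1, 1, 1]])
        target = make_gm([[MISSING, 1, 1, 1]])
        paintings = paint_all(target, panel_t, panel_i, window_size=2)
        assert [c.cls for c in paintings["an0"]] == [NO_CALL, INDICUS]

    def test_diploid_animal_rejected(self):
        tables = []
        with pytest.raises(ValueError, match="haploid"):
            paint_animal("x", np.array([0, 1]), 2, tables)

    @pytest.mark.parametrize("seed", range(5))
    def test_whole_pipeline_matches_bruteforce_on_small_panels(self, seed):
        """Exact oracle equivalence: <=6 markers, <=20 haplotypes."""
        rng = np.random.default_rng(seed)
        n_markers = rng.integers(2, 7)
        ws = int(rng.integers(1, n_markers + 1))
        t = rng.integers(0, 2, (rng.integers(2, 21), n_markers))
        i = rng.integers(0, 2, (rng.integers(2, 21), n_markers))
        targ = rng.integers(0, 2, (10, n_markers))
        paintings = paint_all(make_gm(targ), make_gm(t), make_gm(i), window_size=ws)
        for row, aid in zip(targ, paintings):
            expected = brute_force_paint(row, t, i, window_size=ws)
            got = [(c.b, c.cls) for c in paintings[aid]]
            assert len(got) == len(expected)
            for (gb, gc), (eb, ec) in zip(got, expected):
                assert gc == ec
                if eb is None:
                    assert gb is None
                else:
                    assert gb == pytest.approx(eb, abs=1e-12)

    def test_tract_windows_called_taurus_in_fully_swept_scenario(self, small_config):
        """tract_taurine_freq = 1: nearly all in-tract windows paint taurine."""
        from dataclasses import replace
        from tauroscan.simulate import simulate_dataset
        cfg = replace(small_config, tract_taurine_freq=1.0, seed=13)
        ds = simulate_dataset(cfg)
        paintings = paint_all(ds.targets, ds.panel_taurus, ds.panel_indicus)
        lo, hi = cfg.tract_interval[0] // 10, cfg.tract_interval[1] // 10
        calls = [c.cls for v in paintings.values() for c in v[lo:hi]]
        frac = sum(c == TAURUS for c in calls) / len(calls)
        assert frac >= 0.8


class TestTaurineProportion:
    def _calls(self, classes):
        from tauroscan.ancestry import AncestryCall, Window
        w = Window(0, 0, 10, "X", 100, 1000)
        return [AncestryCall("a", w, None if c == NO_CALL else 0.9, c)
                for c in classes]

    def test_classified_only_denominator(self):
        calls = self._calls([TAURUS, TAURUS, INDICUS, UNDETERMINED])
        assert taurine_proportion(calls, "classified_only") == pytest.approx(2 / 3)

    def test_all_windows_denominator_counts_undetermined(self):
        calls = self._calls([TAURUS, TAURUS, INDICUS, UNDETERMINED])
        assert taurine_proportion(calls, "all_windows") == pytest.approx(0.5)

    def test_all_no_call_is_flagged_undefined(self):
        assert taurine_proportion(self._calls([NO_CALL, NO_CALL])) is None

    def test_empty_call_list_rejected(self):
        with pytest.raises(ValueError):
            taurine_proportion([])


class TestAlleleGroupProfile:
    def _paintings(self):
        panel_t = make_gm([[0, 0, 1, 1]])
        panel_i = make_gm([[1, 1, 0, 0]])
        rng = np.random.default_rng(2)
        targ = make_gm(rng.integers(0, 2, (6, 4)))
        return paint_all(targ, panel_t, panel_i, window_size=2)

    def test_permutation_invariance_over_animals(self):
        paintings = self._paintings()
        genos = {a: i % 2 for i, a in enumerate(paintings)}
        prof1, summ1 = allele_group_profile(paintings, genos)
        shuffled = dict(reversed(list(paintings.items())))
        prof2, summ2 = allele_group_profile(shuffled, genos)
        assert prof1.equals(prof2)
        assert summ1.drop(columns="n_animals").equals(summ2.drop(columns="n_animals"))

    def test_single_group_returns_that_profile(self):
        paintings = self._paintings()
        genos = {a: 1 for a in paintings}
        prof, summ = allele_group_profile(paintings, genos)
        assert list(prof.columns) == ["allele_1"]
        assert summ.loc[1, "n_animals"] == len(paintings)

    def test_missing_candidate_genotype_rejected(self):
        paintings = self._paintings()
        genos = {a: 0 for a in list(paintings)[:-1]}
        with pytest.raises(ValueError):
            allele_group_profile(paintings, genos)
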