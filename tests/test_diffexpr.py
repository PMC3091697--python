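"""The statistic chain: Welch t, BH step-up, signed FC, calling, summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_dataset
from gillzinc.diffexpr import (
    bh_adjust,
    call_regulated,
    collapse_to_genes,
    signed_fold_change,
    temporal_summary,
    welch_t_test,
)
from gillzinc.preprocess import ConfigurationError, filter_expressed


def hand_step_up(p):
    """Independent BH oracle: sort, multiply by m/i, cumulative min from top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    q = np.empty(m)
    q[order] = np.minimum(scaled, 1.0)
    return q


class TestWelch:
    def test_identical_groups(self):
        t, p, _ = welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_hand_evaluated_example(self):
        t, p, df = welch_t_test([1, 2, 3], [2, 4, 6])
        assert t == pytest.approx(-1.549, abs=1e-3)
        assert df == pytest.approx(2.941, abs=1e-3)

    def test_degenerate_conventions(self):
        assert welch_t_test([5, 5], [5, 5])[1] == 1.0
        assert welch_t_test([5, 5], [6, 6])[1] == 0.0

    def test_too_small_group_errors(self):
        with pytest.raises(ConfigurationError):
            welch_t_test([1.0], [1, 2, 3])

    @pytest.mark.parametrize("pooled", [False, True])
    def test_matches_scipy_on_random_data(self, pooled):
        rng = np.random.default_rng(42)
        for _ in range(20):
            a, b = rng.normal(size=5), rng.normal(1, 2, size=7)
            t, p, _ = welch_t_test(a, b, pooled=pooled)
            ref = stats.ttest_ind(a, b, equal_var=pooled)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)


class TestBH:
    def test_all_ones(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_hand_step_up_example(self):
        q = bh_adjust([0.01, 0.04, 0.03, 0.005])
        assert np.allclose(q, [0.02, 0.04, 0.04, 0.02])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_missing_p_propagates_outside_family(self):
        q = bh_adjust([0.02, np.nan, 0.04])
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], hand_step_up([0.02, 0.04]))

    def test_out_of_range_errors(self):
        with pytest.raises(ConfigurationError):
            bh_adjust([0.5, 1.5])

    def test_all_permutations_of_five_match_hand_oracle(self):
        base = [0.003, 0.04, 0.19, 0.6, 0.97]
        for perm in itertools.permutations(base):
            assert np.allclose(bh_adjust(list(perm)), hand_step_up(perm))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_properties(self, p):
        q = bh_adjust(p)
        assert ((q >= np.asarray(p) - 1e-12) & (q <= 1.0)).all()
        assert np.allclose(q, hand_step_up(p))


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "dep, ctl, expected",
        [([1.0], [0.0], 2.0), ([0.0], [1.0], -2.0), ([0.5, 0.7], [0.5, 0.7], 1.0)],
    )
    def test_convention(self, dep, ctl, expected):
        assert signed_fold_change(dep, ctl) == pytest.approx(expected)

    def test_empty_group_errors(self):
        with pytest.raises(ConfigurationError):
            signed_fold_change([], [1.0])


def _two_group_dataset(effects_log2, n=5, noise=0.0, seed=0, time=1.0):
    """Single-time-point dataset with given per-reporter planted log2 effects."""
    rng = np.random.default_rng(seed)
    k = len(effects_log2)
    design = [(f"d{i}", "depleted", time, i) for i in range(n)] + [
        (f"c{i}", "control", time, i) for i in range(n)
    ]
    M = np.zeros((k, 2 * n))
    M[:, :n] += np.asarray(effects_log2)[:, None]
    M += rng.normal(0, noise, size=M.shape)
    return make_dataset(M, design)


class TestCallRegulated:
    def test_threshold_rule_strict_conjunction(self):
        # noise-free: r0 has FC 1.9 and q ~ 0 -> called up; r1 sits exactly on
        # the 1.8 boundary (strict >) and r2 on the null -> neither called
        ds = _two_group_dataset([np.log2(1.9), np.log2(1.8), -np.log2(2.5), 0.0], noise=0.0)
        ds = filter_expressed(ds)
        calls = call_regulated(ds).set_index("reporter")
        assert calls.loc["r0", "called"] and calls.loc["r0", "direction"] == "up"
        assert calls.loc["r2", "called"] and calls.loc["r2", "direction"] == "down"
        assert calls.loc["r1", "fc"] == pytest.approx(1.8)
        assert not calls.loc["r1", "called"]
        assert not calls.loc["r3", "called"]

    def test_q_is_bh_within_time_point(self):
        ds = _two_group_dataset([0.0] * 6, noise=0.3, seed=2)
        ds = filter_expressed(ds)
        calls = call_regulated(ds)
        assert np.allclose(
            np.sort(calls["q"]), np.sort(hand_step_up(calls["p"].to_numpy()))
        )

    def test_condition_swap_negates_fc_and_keeps_p(self):
        ds = _two_group_dataset([1.2, -0.4, 0.1], noise=0.2, seed=3)
        swapped = ds.copy()
        swapped.design["condition"] = swapped.design["condition"].map(
            {"depleted": "control", "control": "depleted"}
        )
        a = call_regulated(filter_expressed(ds)).set_index("reporter")
        b = call_regulated(filter_expressed(swapped)).set_index("reporter")
        for r in a.index:
            assert a.loc[r, "fc"] == pytest.approx(-b.loc[r, "fc"])
            assert a.loc[r, "p"] == pytest.approx(b.loc[r, "p"])

    def test_unfiltered_dataset_rejected(self):
        ds = _two_group_dataset([0.0])
        with pytest.raises(ConfigurationError, match="filter"):
            call_regulated(ds)


def _toy_calls(rows):
    return pd.DataFrame(rows, columns=["reporter", "time", "fc", "p", "q", "direction", "called"])


class TestTemporalSummary:
    def test_percentages_over_called_events(self):
        rows = [
            ("a", 1.0, 2.0, 0.01, 0.02, "up", True),
            ("b", 1.0, 2.0, 0.01, 0.02, "up", True),
            ("c", 1.0, -2.0, 0.01, 0.02, "down", True),
            ("c", 4.0, -2.0, 0.01, 0.02, "down", True),
            ("d", 4.0, -2.0, 0.01, 0.02, "down", True),
            ("e", 4.0, -1.1, 0.5, 0.9, "none", False),
        ]
        s = temporal_summary(_toy_calls(rows))
        assert s.pct_up == pytest.approx(40.0)
        assert s.pct_down == pytest.approx(60.0)
        assert s.per_time.loc[1.0, "n_total"] == 3
        assert s.per_time.loc[4.0, "n_up"] == 0

    def test_single_direction_gene_at_every_time_point_is_persistent(self):
        times = [0.3, 1.0, 4.0, 7.0, 14.0]
        rows = [("mt2", t, -3.0, 0.001, 0.01, "down", True) for t in times]
        rows += [("x", 1.0, 2.0, 0.01, 0.02, "up", True)]
        s = temporal_summary(_toy_calls(rows))
        assert s.persistent == ["mt2"]

    def test_direction_flip_breaks_persistence(self):
        rows = [("g", 1.0, 2.0, 0.01, 0.02, "up", True),
                ("g", 4.0, -2.0, 0.01, 0.02, "down", True)]
        assert temporal_summary(_toy_calls(rows)).persistent == []

    def test_empty_calls_reported_as_undefined(self):
        s = temporal_summary(_toy_calls([]))
        assert np.isnan(s.pct_up) and np.isnan(s.pct_down)
        assert s.persistent == []


def test_collapse_keeps_most_significant_reporter_per_gene():
    rows = [
        ("p1", 1.0, 2.5, 0.001, 0.01, "up", True),
        ("p2", 1.0, -1.2, 0.5, 0.8, "none", False),
    ]
    out = collapse_to_genes(_toy_calls(rows), {"p1": "mt2", "p2": "mt2"})
    assert len(out) == 1
    assert out.iloc[0]["reporter"] == "p1"
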