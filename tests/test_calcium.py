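"""dF/F0 arithmetic, the windowed response rule, AUC, and exact tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hypergeom

from thirststate.calcium import (
    FRAME_RATE,
    auc,
    classify_response,
    compute_dff,
    frames_for,
    proportion_shift_test,
    response_contingency,
)
from thirststate.errors import DataError


def _trace(f0=100.0, plateau=None, onset_s=20.0, total_s=75.0, rate=FRAME_RATE):
    n = int(total_s * rate)
    v = np.full(n, f0)
    if plateau is not None:
        i1 = int(round(onset_s * rate))
        v[i1:] = plateau
    return v


class TestComputeDff:
    def test_constant_trace_gives_zero(self):
        dff = compute_dff(_trace(), onset_s=20.0)
        assert np.allclose(dff, 0.0)

    def test_plateau_half(self):
        dff = compute_dff(_trace(plateau=150.0), onset_s=20.0)
        assert dff[-1] == pytest.approx(0.5)

    def test_baseline_window_is_83_frames(self):
        assert frames_for(14.0) == 83
        assert frames_for(25.0) == 148

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(DataError, match="baseline"):
            compute_dff(_trace(f0=0.0), onset_s=20.0)

    def test_baseline_must_fit(self):
        with pytest.raises(DataError):
            compute_dff(_trace(), onset_s=5.0)  # < 14 s of pre-drug frames


class TestClassifyResponse:
    def _dff(self, pre_noise_sd, post_level, seed=0, onset_s=20.0):
        rng = np.random.default_rng(seed)
        n = int(75.0 * FRAME_RATE)
        d = rng.normal(0.0, pre_noise_sd, n) if pre_noise_sd else np.zeros(n)
        i1 = int(round(onset_s * FRAME_RATE))
        d[i1:] += post_level
        return d

    def test_strong_positive_step_activated(self):
        call = classify_response(self._dff(0.1, 0.5), onset_s=20.0)
        assert call.category == "activated"
        assert call.mu_post > call.sigma_pre

    def test_strong_negative_step_inhibited(self):
        call = classify_response(self._dff(0.1, -0.5), onset_s=20.0)
        assert call.category == "inhibited"

    def test_within_sigma_band_no_change(self):
        call = classify_response(self._dff(0.1, 0.05), onset_s=20.0)
        assert call.category == "no_change"

    def test_zero_variance_tie_is_no_change(self):
        call = classify_response(np.zeros(int(75 * FRAME_RATE)), onset_s=20.0)
        assert call.category == "no_change"

    def test_pre_window_mean_normalized_to_zero(self):
        d = self._dff(0.05, 0.4) + 3.0  # arbitrary per-cell baseline offset
        call = classify_response(d, onset_s=20.0)
        assert call.mu_pre == 0.0
        assert call.category == "activated"

    @given(st.floats(0.1, 50.0))
    def test_scale_equivariance(self, scale):
        """Multiplying raw fluorescence by a constant never changes the
        category because dF/F0 is ratio-based."""
        rng = np.random.default_rng(7)
        n = int(75 * FRAME_RATE)
        raw = 100.0 * (1 + rng.normal(0, 0.05, n))
        i1 = int(round(20.0 * FRAME_RATE))
        raw[i1:] *= 1.2
        c1 = classify_response(compute_dff(raw, 20.0), 20.0)
        c2 = classify_response(compute_dff(raw * scale, 20.0), 20.0)
        assert c1.category == c2.category


class TestAuc:
    def test_zero_series(self):
        assert auc(np.zeros(500), 20.0, 45.0) == 0.0

    def test_constant_one_over_25s(self):
        d = np.ones(int(75 * FRAME_RATE))
        got = auc(d, 20.0, 45.0)
        assert abs(got - 25.0) <= 1.0 / FRAME_RATE

    def test_linear_ramp(self):
        rate = FRAME_RATE
        n = int(20 * rate)
        t = np.arange(n) / rate
        d = np.clip(t / 10.0, 0, 1)  # 0 -> 1 over 10 s
        got = auc(d, 0.0, 10.0, rate)
        assert abs(got - 5.0) <= 1.0 / rate

    def test_additivity_exact(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0, 1, int(80 * FRAME_RATE))
        whole = auc(d, 20.0, 70.0)
        parts = auc(d, 20.0, 45.0) + auc(d, 45.0, 70.0)
        assert whole == pytest.approx(parts, abs=1e-12)

    def test_onset_normalization(self):
        d = np.ones(int(75 * FRAME_RATE)) * 0.3
        got = auc(d, 20.0, 45.0, normalize_at_onset=True, onset_s=20.0)
        assert got == pytest.approx(0.0, abs=1e-12)

    def test_empty_window_rejected(self):
        with pytest.raises(DataError):
            auc(np.ones(100), 5.0, 5.0)


def _fisher_oracle(t):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    a, b = t[0]
    c, d = t[1]
    n, K, N = a + b + c + d, a + b, a + c
    kmin, kmax = max(0, K + N - n), min(K, N)
    pmf = hypergeom.pmf(np.arange(kmin, kmax + 1), n, K, N)
    cutoff = hypergeom.pmf(a, n, K, N) * (1 + 1e-7)
    return pmf[pmf <= cutoff].sum()


class TestResponseContingency:
    def _calls(self, t):
        a, b = [], []
        for (ca, cb), k in zip(
            [("activated", "activated"), ("activated", "inhibited"),
             ("inhibited", "activated"), ("inhibited", "inhibited")],
            [t[0][0], t[0][1], t[1][0], t[1][1]],
        ):
            a += [ca] * k
            b += [cb] * k
        return a, b

    def test_matched_table_or_and_p(self):
        a, b = self._calls([[30, 10], [10, 30]])
        res = response_contingency(a, b)
        assert res["odds_ratio"] == pytest.approx(9.0)
        assert res["p"] == pytest.approx(_fisher_oracle([[30, 10], [10, 30]]), rel=1e-9)
        assert res["matched"] == 60 and res["mismatched"] == 20

    def test_independence_table(self):
        a, b = self._calls([[25, 25], [25, 25]])
        res = response_contingency(a, b)
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1.0)

    def test_no_change_cells_excluded_from_2x2(self):
        a = ["activated", "no_change", "inhibited"]
        b = ["activated", "activated", "inhibited"]
        res = response_contingency(a, b)
        assert res["n"] == 2

    def test_zero_margin_haldane_flagged(self):
        a, b = self._calls([[10, 0], [0, 10]])
        res = response_contingency(a, b)
        assert res["haldane"]
        assert np.isfinite(res["odds_ratio"])
        assert res["p"] == pytest.approx(_fisher_oracle([[10, 0], [0, 10]]), rel=1e-9)

    def test_fisher_matches_enumeration_on_random_tables(self):
        """Implementation p equals brute-force hypergeometric enumeration
        for tables with n <= 200."""
        rng = np.random.default_rng(3)
        for _ in range(60):
            t = rng.integers(0, 50, size=(2, 2))
            if t.sum() == 0 or t.sum() > 200:
                continue
            a, b = self._calls(t.tolist())
            if not a:
                continue
            res = response_contingency(a, b)
            assert res["p"] == pytest.approx(_fisher_oracle(t), rel=1e-9, abs=1e-12)

    def test_3x3_agreement_mode(self):
        a = ["activated"] * 30 + ["inhibited"] * 30 + ["no_change"] * 30
        b = ["activated"] * 25 + ["inhibited"] * 35 + ["no_change"] * 30
        res = response_contingency(a, b, mode="3x3")
        assert res["table"].sum() == 90
        assert res["matched"] + res["mismatched"] == 90


class TestProportionShift:
    def test_identical_proportions_not_significant(self):
        counts = pd.DataFrame(
            {"activated": [40, 40], "no_change": [140, 140], "inhibited": [20, 20]},
            index=["sated", "thirsty"],
        )
        res = proportion_shift_test(counts)
        assert (res["p_bonferroni"] > 0.9).all()

    def test_bonferroni_multiplies_and_caps(self):
        counts = pd.DataFrame(
            {"activated": [30, 31, 60], "no_change": [70, 69, 40]},
            index=["a", "b", "c"],
        )
        res = proportion_shift_test(counts)
        assert len(res) == 3  # all state pairs
        assert np.allclose(res["p_bonferroni"], np.minimum(res["p"] * 3, 1.0))

    def test_planted_shift_detected(self):
        """A 18% -> 34% activated shift at n=200/state is significant
        after correction in most seeds."""
        rng = np.random.default_rng(4)
        hits = 0
        n_seeds = 50
        for _ in range(n_seeds):
            k1 = rng.binomial(200, 0.18)
            k2 = rng.binomial(200, 0.34)
            counts = pd.DataFrame(
                {"activated": [k1, k2], "no_change": [200 - k1, 200 - k2]},
                index=["sated", "thirsty"],
            )
            res = proportion_shift_test(counts)
            hits += (res["p_bonferroni"] < 0.05).iloc[0]
        assert hits >= 0.8 * n_seeds

    def test_empty_state_skipped(self):
        counts = pd.DataFrame(
            {"activated": [30, 0, 25], "no_change": [70, 0, 75]},
            index=["a", "empty", "b"],
        )
        res = proportion_shift_test(counts)
        assert set(res["state_a"]) | set(res["state_b"]) == {"a", "b"}
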