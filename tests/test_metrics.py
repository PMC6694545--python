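import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dynapred as dp
from dynapred.exceptions import UndefinedMetricError
from dynapred.metrics import (
    NRIComponents,
    auc_ipcw,
    brier_ipcw,
    censoring_km,
    chisq_pvalue,
    combine_nri,
    hl_statistic,
    ipcw_weights,
    nri_components,
)

from conftest import make_frame


# ---------------------------------------------------------------------------
# independent brute-force oracles (uncensored data)
# ---------------------------------------------------------------------------

def auc_bruteforce(p, X, D, t0, tau):
    cases = [i for i in range(len(X)) if D[i] == 1 and t0 < X[i] <= tau]
    ctrls = [j for j in range(len(X)) if X[j] > tau]
    num = total = 0.0
    for i in cases:
        for j in ctrls:
            total += 1
            if p[i] < p[j]:
                num += 1
            elif p[i] == p[j]:
                num += 0.5
    return num / total


def brier_bruteforce(p, X, tau):
    ind = (np.asarray(X) > tau).astype(float)
    return float(np.mean((ind - np.asarray(p)) ** 2))


def nri_bruteforce(p_d, p_s, X, D, t0, tau):
    events = [i for i in range(len(X)) if D[i] == 1 and t0 < X[i] <= tau]
    nonevents = [j for j in range(len(X)) if X[j] > tau]

    def pct(group):
        rd = 1 - np.asarray(p_d)[group]
        rs = 1 - np.asarray(p_s)[group]
        return (
            100 * np.mean(rd > rs),
            100 * np.mean(rd < rs),
            100 * np.mean(rd == rs),
        )

    return pct(events), pct(nonevents)


class TestCensoringKM:
    def test_no_censoring_gives_one(self):
        frame = make_frame([1, 2, 3], [1, 1, 1])
        G = censoring_km(frame)
        assert G(0.5) == 1.0 and G(3.0) == 1.0

    def test_single_censored_subject(self):
        G = censoring_km(np.array([2.0]), np.array([0]))
        assert G(1.9) == 1.0
        assert G(2.0) == 0.0

    def test_hand_product_limit(self):
        # X: 1(c), 2(e), 3(c), 4(e), 5(c), 6(c); censoring KM:
        # t=1: 1 - 1/6 = 5/6; t=3: *(1 - 1/4); t=5: *(1 - 1/2); t=6: 0
        X = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        D = np.array([0, 1, 0, 1, 0, 0])
        G = censoring_km(X, D)
        np.testing.assert_allclose(G(1.0), 5 / 6)
        np.testing.assert_allclose(G(3.0), 5 / 6 * 3 / 4)
        np.testing.assert_allclose(G(5.0), 5 / 6 * 3 / 4 * 1 / 2)
        np.testing.assert_allclose(G(6.0), 0.0)

    def test_tied_event_and_censoring(self):
        # event kept in the risk set of the censoring at the same time
        X = np.array([2.0, 2.0, 3.0])
        D = np.array([1, 0, 0])
        G = censoring_km(X, D)
        np.testing.assert_allclose(G(2.0), 1 - 1 / 3)


class TestIPCWWeights:
    def test_uncensored_weights_are_one(self):
        X = np.array([0.5, 1.5, 3.0, 4.0])
        D = np.array([1, 1, 1, 1])
        G = censoring_km(X, D)
        w = ipcw_weights(X, D, G, t0=0.0, tau=2.0)
        np.testing.assert_array_equal(w, [1.0, 1.0, 1.0, 1.0])

    def test_censored_in_window_zero(self):
        X = np.array([1.0, 1.5, 3.0])
        D = np.array([1, 0, 0])
        G = censoring_km(X, D)
        w = ipcw_weights(X, D, G, t0=0.0, tau=2.0)
        assert w[1] == 0.0
        assert np.all(w >= 0)

    def test_event_before_t0_zero(self):
        X = np.array([0.5, 3.0])
        D = np.array([1, 0])
        G = censoring_km(X, D)
        w = ipcw_weights(X, D, G, t0=1.0, tau=2.0)
        assert w[0] == 0.0


class TestAUC:
    def test_perfect_separation(self):
        frame = make_frame([1, 1.5, 3, 4], [1, 1, 0, 0], t0=0, horizon=2)
        p = np.array([0.2, 0.3, 0.8, 0.9])
        assert auc_ipcw(p, frame, 2.0).value == 1.0

    def test_all_tied_predictions(self):
        frame = make_frame([1, 1.5, 3, 4], [1, 1, 0, 0], t0=0, horizon=2)
        assert auc_ipcw(np.full(4, 0.5), frame, 2.0).value == 0.5

    def test_uncensored_fixture_equals_bruteforce(self):
        X = [0.5, 1.0, 1.8, 2.5, 3.0, 4.0]
        D = [1, 1, 1, 1, 1, 1]
        p = [0.3, 0.7, 0.4, 0.6, 0.5, 0.9]
        frame = make_frame(X, D, t0=0, horizon=2)
        assert auc_ipcw(np.array(p), frame, 2.0).value == pytest.approx(
            auc_bruteforce(p, X, D, 0.0, 2.0)
        )

    def test_no_cases_error(self):
        frame = make_frame([3, 4], [0, 0], t0=0, horizon=2)
        with pytest.raises(UndefinedMetricError, match="events"):
            auc_ipcw(np.array([0.5, 0.6]), frame, 2.0)

    def test_no_controls_error(self):
        frame = make_frame([1, 1.5], [1, 1], t0=0, horizon=2)
        with pytest.raises(UndefinedMetricError, match="survivors"):
            auc_ipcw(np.array([0.5, 0.6]), frame, 2.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0.2, 5, 30)
        D = rng.integers(0, 2, 30)
        D[X > 2.0] = D[X > 2.0]  # arbitrary pattern fine
        frame = make_frame(X, np.ones(30, int), t0=0, horizon=2)
        p = rng.uniform(size=30)
        a1 = auc_ipcw(p, frame, 2.0).value
        a2 = auc_ipcw(p ** 3, frame, 2.0).value  # strictly monotone on [0,1]
        a3 = auc_ipcw(0.1 + 0.8 * p, frame, 2.0).value
        assert a1 == pytest.approx(a2) == pytest.approx(a3)


class TestBrier:
    def test_perfect_predictions_zero(self):
        X = [1.0, 1.5, 3.0, 4.0]
        frame = make_frame(X, [1, 1, 1, 1], t0=0, horizon=2)
        p = (np.array(X) > 2.0).astype(float)
        assert brier_ipcw(p, frame, 2.0).value == 0.0

    def test_constant_prediction_arithmetic(self):
        # 10 uncensored subjects, 4 events by tau, constant p = c:
        # BS = q c^2 + (1 - q)(1 - c)^2 with q = 0.4
        X = [0.5, 1.0, 1.2, 1.9, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0]
        frame = make_frame(X, np.ones(10, int), t0=0, horizon=2)
        c, q = 0.7, 0.4
        expected = q * c ** 2 + (1 - q) * (1 - c) ** 2
        assert brier_ipcw(np.full(10, c), frame, 2.0).value == pytest.approx(expected)

    def test_maximal_error(self):
        frame = make_frame([1.0, 1.5], [1, 1], t0=0, horizon=2)
        assert brier_ipcw(np.array([1.0, 1.0]), frame, 2.0).value == 1.0

    def test_flip_symmetry(self):
        # BS(p; I(T > tau)) == BS(1 - p; I(T <= tau)) -- check via arithmetic
        rng = np.random.default_rng(2)
        X = rng.uniform(0.2, 5, 20)
        frame = make_frame(X, np.ones(20, int), t0=0, horizon=2)
        p = rng.uniform(size=20)
        ind = (X > 2.0).astype(float)
        direct = brier_ipcw(p, frame, 2.0).value
        flipped = float(np.mean(((1 - ind) - (1 - p)) ** 2))
        assert direct == pytest.approx(flipped)

    def test_zero_weight_error(self):
        # everyone censored inside the window
        X = np.array([1.0, 1.5])
        frame = make_frame(X, [0, 0], t0=0, horizon=2)
        with pytest.raises(UndefinedMetricError):
            brier_ipcw(np.array([0.5, 0.5]), frame, 2.0)


class TestHosmerLemeshow:
    def test_perfect_calibration_zero(self):
        # 5 strata x 10 subjects; in stratum g the risk is r_g and exactly
        # r_g * 10 subjects have events inside the window
        X, p = [], []
        for r in (0.1, 0.2, 0.3, 0.4, 0.5):
            k = int(round(r * 10))
            X.extend([1.0] * k + [3.0] * (10 - k))
            p.extend([1 - r] * 10)
        frame = make_frame(X, np.ones(50, int), t0=0, horizon=2)
        est = hl_statistic(np.array(p), frame, 2.0, g=5)
        assert est.value == pytest.approx(0.0, abs=1e-12)
        assert est.p_value == pytest.approx(1.0)

    def test_two_stratum_hand_arithmetic(self):
        # stratum A: risks 0.2, n=4, 2 events -> O=.5 E=.2
        # stratum B: risks 0.8, n=4, 2 events -> O=.5 E=.8
        X = [1.0, 1.0, 3.0, 3.0, 1.0, 1.0, 3.0, 3.0]
        p = [0.8, 0.8, 0.8, 0.8, 0.2, 0.2, 0.2, 0.2]
        frame = make_frame(X, np.ones(8, int), t0=0, horizon=2)
        est = hl_statistic(np.array(p), frame, 2.0, g=2)
        hand = 4 * (0.5 - 0.2) ** 2 / (0.2 * 0.8) + 4 * (0.5 - 0.8) ** 2 / (0.8 * 0.2)
        assert est.value == pytest.approx(hand)
        assert est.p_value == pytest.approx(chisq_pvalue(hand, 1))

    def test_requires_distinct_predictions(self):
        frame = make_frame([1, 2, 3, 4, 5], [1, 1, 1, 1, 1], t0=0, horizon=2)
        with pytest.raises(UndefinedMetricError, match="distinct"):
            hl_statistic(np.full(5, 0.5), frame, 2.0, g=5)


class TestChisqPvalue:
    def test_zero_statistic(self):
        assert chisq_pvalue(0.0, 4) == 1.0

    def test_closed_form_df4(self):
        # for df = 4 the survival function is exp(-x/2) (1 + x/2)
        for x in (2.0, 7.43, 11.03, 16.40):
            closed = np.exp(-x / 2) * (1 + x / 2)
            assert chisq_pvalue(x, 4) == pytest.approx(closed, rel=1e-12)

    def test_printed_values(self):
        assert round(chisq_pvalue(11.03, 4), 2) == 0.03
        assert round(chisq_pvalue(7.43, 4), 2) == 0.11
        assert round(chisq_pvalue(7.95, 4), 2) == 0.09

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            chisq_pvalue(1.0, 0)
        with pytest.raises(ValueError):
            chisq_pvalue(-1.0, 4)


class TestNRI:
    def test_identical_models_all_ties(self):
        frame = make_frame([1, 1.5, 3, 4], [1, 1, 1, 1], t0=0, horizon=2)
        p = np.array([0.2, 0.3, 0.8, 0.9])
        comp = nri_components(p, p, frame, 2.0)
        assert comp.nri == 0.0
        assert comp.tie_events == 100.0 and comp.tie_nonevents == 100.0
        assert comp.up_events == comp.down_events == 0.0

    def test_perfect_reclassification(self):
        frame = make_frame([1, 1.5, 3, 4], [1, 1, 1, 1], t0=0, horizon=2)
        p_s = np.array([0.5, 0.5, 0.5, 0.5])
        p_d = np.array([0.2, 0.3, 0.8, 0.9])  # events riskier, survivors safer
        comp = nri_components(p_d, p_s, frame, 2.0)
        assert (comp.up_events, comp.down_events) == (100.0, 0.0)
        assert (comp.up_nonevents, comp.down_nonevents) == (0.0, 100.0)
        assert comp.nri == 200.0

    def test_eight_subject_enumeration(self):
        X = [0.5, 1.0, 1.5, 1.9, 2.5, 3.0, 4.0, 5.0]
        D = [1, 1, 1, 1, 1, 1, 1, 1]
        rng = np.random.default_rng(5)
        p_d = rng.uniform(size=8)
        p_s = rng.uniform(size=8)
        frame = make_frame(X, D, t0=0, horizon=2)
        comp = nri_components(p_d, p_s, frame, 2.0)
        (ue, de, te), (un, dn, tn) = nri_bruteforce(p_d, p_s, X, D, 0.0, 2.0)
        assert comp.up_events == pytest.approx(ue)
        assert comp.down_events == pytest.approx(de)
        assert comp.up_nonevents == pytest.approx(un)
        assert comp.down_nonevents == pytest.approx(dn)

    def test_antisymmetry_under_model_swap(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0.2, 5, 16)
        frame = make_frame(X, np.ones(16, int), t0=0, horizon=2)
        p_d = rng.uniform(size=16)
        p_s = rng.uniform(size=16)
        a = nri_components(p_d, p_s, frame, 2.0).nri
        b = nri_components(p_s, p_d, frame, 2.0).nri
        assert a == pytest.approx(-b)


class TestCombineNRI:
    @pytest.mark.parametrize(
        "components,expected",
        [
            ((26.5, 73.5, 28.4, 71.6), -3.8),
            ((40.4, 59.6, 38.1, 61.9), 4.6),
            ((50.0, 50.0, 50.0, 50.0), 0.0),
        ],
    )
    def test_values(self, components, expected):
        assert combine_nri(*components) == pytest.approx(expected)

    def test_range_check(self):
        with pytest.raises(ValueError):
            combine_nri(-1.0, 50, 50, 50)
        with pytest.raises(ValueError):
            combine_nri(101.0, 50, 50, 50)


# ---------------------------------------------------------------------------
# property: with zero censoring IPCW metrics reduce to unweighted counterparts
# ---------------------------------------------------------------------------

@st.composite
def uncensored_fixture(draw):
    n = draw(st.integers(min_value=4, max_value=12))
    X = draw(
        st.lists(
            st.floats(min_value=0.1, max_value=5.0, allow_nan=False),
            min_size=n, max_size=n,
        )
    )
    p = draw(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=n, max_size=n,
        )
    )
    return np.asarray(X), np.asarray(p)


@given(uncensored_fixture())
@settings(max_examples=60, deadline=None)
def test_uncensored_auc_equals_enumeration(data):
    X, p = data
    tau = 2.0
    D = np.ones(len(X), dtype=int)
    has_case = np.any((X > 0) & (X <= tau))
    has_ctrl = np.any(X > tau)
    frame = make_frame(X, D, t0=0, horizon=tau)
    if not (has_case and has_ctrl):
        with pytest.raises(UndefinedMetricError):
            auc_ipcw(p, frame, tau)
        return
    assert auc_ipcw(p, frame, tau).value == pytest.approx(
        auc_bruteforce(p, X, D, 0.0, tau)
    )


@given(uncensored_fixture())
@settings(max_examples=60, deadline=None)
def test_uncensored_brier_equals_mean_square(data):
    X, p = data
    frame = make_frame(X, np.ones(len(X), int), t0=0, horizon=2.0)
    assert brier_ipcw(p, frame, 2.0).value == pytest.approx(
        brier_bruteforce(p, X, 2.0)
    )


def test_proper_score_behavior():
    # the true conditional survival minimizes the Brier score: perturbed
    # predictions cannot do better (up to Monte-Carlo noise)
    rng = np.random.default_rng(9)
    n = 20000
    lam = rng.uniform(0.1, 0.6, size=n)  # subject-specific known hazards
    T = rng.exponential(1 / lam)
    frame = make_frame(T, np.ones(n, int), t0=0, horizon=2.0)
    p_true = np.exp(-lam * 2.0)
    b_true = brier_ipcw(p_true, frame, 2.0).value
    for scale in (0.5, 0.8, 1.3):
        p_bad = np.clip(p_true * scale, 0, 1)
        assert brier_ipcw(p_bad, frame, 2.0).value >= b_true - 1e-3


def test_ipcw_corrects_for_censoring_bias():
    # heavy independent censoring: IPCW Brier of the true model stays close
    # to the uncensored truth while the naive complete-case estimate drifts
    rng = np.random.default_rng(10)
    n = 40000
    lam = 0.35
    T = rng.exponential(1 / lam, size=n)
    C = rng.exponential(1 / 0.4, size=n)
    X = np.minimum(T, C)
    D = (T <= C).astype(int)
    p_const = np.full(n, np.exp(-lam * 2.0))
    truth = float(np.mean(((T > 2.0) - p_const) ** 2))
    frame = make_frame(X, D, t0=0, horizon=2.0)
    est = brier_ipcw(p_const, frame, 2.0).value
    assert abs(est - truth) < 0.01
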