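"""ROC statistics against brute-force oracles and closed forms."""

import numpy as np
import pytest

from fundusgru import (UndefinedMetricError, auc, bootstrap_ci, delong_ci,
                       delong_test, roc_analysis, youden_optimal)


# -- independent oracles ----------------------------------------------

def auc_bruteforce(labels, scores):
    """Mean over all positive-negative pairs, ties counted half."""
    y = np.asarray(labels)
    s = np.asarray(scores, float)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def youden_bruteforce(labels, scores):
    """Exhaustive scan over observed thresholds (rule: score >= thr)."""
    y = np.asarray(labels)
    s = np.asarray(scores, float)
    best = None
    for t in sorted(set(s)):
        sens = np.mean(s[y == 1] >= t)
        spec = np.mean(s[y == 0] < t)
        j = sens + spec - 1
        # tie-break: higher specificity, then lower threshold
        key = (round(j, 12), round(spec, 12), -t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    return best[1], best[2], best[3]


def delong_var_longhand(labels, scores):
    """Structural-components variance straight from the definitions."""
    y = np.asarray(labels)
    s = np.asarray(scores, float)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10.var(ddof=1) / m + v01.var(ddof=1) / n


# -- AUC and Youden ----------------------------------------------------

def test_auc_examples():
    assert auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0
    assert auc([1, 0], [0.5, 0.5]) == 0.5
    labels, scores = [1, 0, 1, 0, 0], [0.8, 0.7, 0.6, 0.5, 0.9]
    assert auc(labels, scores) == auc_bruteforce(labels, scores) == 0.5


def test_single_class_raises():
    with pytest.raises(UndefinedMetricError):
        auc([1, 1, 1], [0.1, 0.2, 0.3])


def _random_instances(n_trials=1000, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n_trials):
        n = int(rng.integers(4, 21))
        y = np.zeros(n, int)
        y[: int(rng.integers(1, n))] = 1
        rng.shuffle(y)
        if y.sum() in (0, n):
            continue
        # coarse grid forces plenty of ties
        s = rng.integers(0, 6, size=n) / 5.0
        yield y, s


def test_auc_equals_bruteforce_on_random_instances():
    for y, s in _random_instances():
        assert abs(auc(y, s) - auc_bruteforce(y, s)) < 1e-12


def test_youden_equals_exhaustive_scan_on_random_instances():
    for y, s in _random_instances(seed=1):
        t, sens, spec = youden_optimal(y, s)
        t0, sens0, spec0 = youden_bruteforce(y, s)
        assert (t, sens, spec) == (t0, sens0, spec0)


def test_auc_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(7)
    for _ in range(50):
        n = int(rng.integers(10, 200))
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            continue
        s = np.round(rng.normal(size=n) + y, 1)  # ties likely
        assert abs(auc(y, s) - roc_auc_score(y, s)) < 1e-12


def test_youden_perfect_and_degenerate():
    t, sens, spec = youden_optimal([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
    assert (sens, spec) == (1.0, 1.0)
    t, sens, spec = youden_optimal([0, 1, 0, 1], [0.4, 0.4, 0.4, 0.4])
    assert sens + spec - 1 == 0.0
    assert t == 0.4  # the lowest (only) candidate threshold


def test_roc_result_monotone():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 50)
    s = rng.normal(size=50)
    r = roc_analysis(y, s)
    assert np.all(np.diff(r.sens) >= 0)        # thresholds descend
    assert np.all(np.diff(r.spec) <= 0)
    assert 0 <= r.auc <= 1
    assert r.youden_sens + r.youden_spec - 1 >= -1e-12


# -- De Long -----------------------------------------------------------

def test_delong_variance_matches_longhand_small_n():
    cases = [
        ([1, 1, 0, 0, 0], [3.0, 1.5, 2.0, 1.0, 0.5]),
        ([1, 1, 1, 0, 0, 0], [0.9, 0.7, 0.4, 0.8, 0.3, 0.1]),
        ([1, 1, 0, 0], [2.0, 1.0, 1.5, 0.5]),
    ]
    from fundusgru.evaluate import _delong_variance, _placements

    for y, s in cases:
        v10, v01, theta = _placements(y, s)
        assert abs(theta - auc_bruteforce(y, s)) < 1e-12
        assert abs(_delong_variance(v10, v01)
                   - delong_var_longhand(y, s)) < 1e-12


def test_delong_ci_contract_and_perfect_separation():
    ci = delong_ci([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
    assert ci.estimate == 1.0 and (ci.lower, ci.upper) == (1.0, 1.0)
    rng = np.random.default_rng(5)
    y = rng.integers(0, 2, 200)
    s = rng.normal(size=200) + 0.5 * y
    ci = delong_ci(y, s)
    assert 0.0 <= ci.lower <= ci.estimate <= ci.upper <= 1.0


def test_delong_ci_needs_two_per_class():
    with pytest.raises(UndefinedMetricError):
        delong_ci([1, 0, 0, 0], [0.4, 0.3, 0.2, 0.1])


def test_delong_test_identity_and_power():
    rng = np.random.default_rng(8)
    y = rng.integers(0, 2, 100)
    s = rng.normal(size=100)
    z, p = delong_test(y, s, s)
    assert z == 0.0 and p == 1.0
    # strong model vs noise on n=500: overwhelming evidence
    y = np.r_[np.ones(100, int), np.zeros(400, int)]
    strong = y + 0.1 * rng.normal(size=500)
    noise = rng.normal(size=500)
    z, p = delong_test(y, strong, noise)
    assert p < 0.001


def test_delong_test_consistent_with_ci_of_difference():
    """CI excludes zero difference iff p < alpha (same variance estimate)."""
    from scipy.stats import norm

    from fundusgru.evaluate import _placements

    rng = np.random.default_rng(9)
    for _ in range(20):
        y = rng.integers(0, 2, 120)
        if y.sum() < 2 or y.sum() > 118:
            continue
        a = rng.normal(size=120) + 0.8 * y
        b = rng.normal(size=120) + 0.3 * y
        z, p = delong_test(y, a, b)
        ta = _placements(y, a)[2]
        tb = _placements(y, b)[2]
        diff = ta - tb
        if z == 0:
            continue
        se = abs(diff / z)
        zc = norm.ppf(0.975)
        excludes = (diff - zc * se > 0) or (diff + zc * se < 0)
        assert excludes == (p < 0.05)


# -- bootstrap ---------------------------------------------------------

def test_bootstrap_deterministic_given_seed():
    rng = np.random.default_rng(10)
    y = rng.integers(0, 2, 80)
    s = rng.normal(size=80) + y
    a = bootstrap_ci(y, s, "sens_at_youden", B=300, seed=4)
    b = bootstrap_ci(y, s, "sens_at_youden", B=300, seed=4)
    assert (a.lower, a.upper) == (b.lower, b.upper)
    c = bootstrap_ci(y, s, "sens_at_youden", B=300, seed=5)
    assert (a.lower, a.upper) != (c.lower, c.upper)


def test_bootstrap_perfect_classifier():
    y = np.r_[np.ones(20, int), np.zeros(30, int)]
    s = y.astype(float)
    ci = bootstrap_ci(y, s, "sens_at_youden", B=200, seed=0)
    assert (ci.lower, ci.upper, ci.estimate) == (1.0, 1.0, 1.0)


def test_bootstrap_coverage_binormal():
    """Percentile interval covers the known sensitivity at the Youden
    point at roughly the nominal rate (scaled-down study)."""
    rng = np.random.default_rng(11)
    mu = 1.6832424494  # separation giving binormal AUC ~0.883
    # population Youden threshold for equal-variance binormal is mu/2;
    # true sensitivity there is 1 - Phi(mu/2 - mu)
    from scipy.stats import norm

    true_sens = 1 - norm.cdf(mu / 2 - mu)
    hits = 0
    reps = 40
    for r in range(reps):
        s = np.r_[rng.normal(mu, 1, 400), rng.normal(0, 1, 400)]
        y = np.r_[np.ones(400, int), np.zeros(400, int)]
        ci = bootstrap_ci(y, s, "sens_at_youden", B=400, seed=r)
        hits += ci.lower <= true_sens <= ci.upper
    assert 0.80 <= hits / reps <= 1.0
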