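"""Active-gene rule, normalization, dispersion and the NB Wald test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats, optimize

from heteroseq import diffexpr
from heteroseq.io import CountsMatrix

from conftest import make_counts


# ---------------------------------------------------------------------------
# active genes
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("reps,active", [
    ([2, 2, 0], True), ([1, 1, 1], False), ([5, 0, 0], False),
    ([2, 2, 2], True), ([0, 0, 0], False), ([3, 2, 1], True),
])
def test_active_gene_rule_examples(reps, active):
    cm = make_counts(np.array([reps + reps]))  # same counts both groups
    got = diffexpr.call_active_genes(cm, cm.sample_ids(role="maternal"))
    assert (len(got) == 1) == active


def test_active_gene_rule_exhaustive_grid():
    grid = list(itertools.product(range(4), repeat=3))
    counts = np.array([list(g) * 2 for g in grid])
    cm = make_counts(counts)
    got = diffexpr.call_active_genes(cm, cm.sample_ids(role="maternal"))
    for gid, g in zip(cm.counts.index, grid):
        expected = sum(c >= 2 for c in g) >= 2
        assert (gid in got) == expected, g


def test_active_gene_rule_needs_replicates():
    cm = make_counts(np.ones((2, 6), dtype=int))
    with pytest.raises(ValueError):
        diffexpr.call_active_genes(cm, cm.sample_ids()[:1])


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def test_size_factors_identical_columns_are_one():
    col = np.array([[5], [10], [100]])
    cm = make_counts(np.repeat(col, 6, axis=1))
    sf = diffexpr.size_factors(cm)
    assert np.allclose(sf, 1.0)


def test_size_factors_single_gene_two_samples():
    counts = pd.DataFrame({"s1": [10], "s2": [20]}, index=pd.Index(["g"], name="gene_id"))
    sf = diffexpr.size_factors(counts)
    assert sf["s1"] == pytest.approx(10 / np.sqrt(200))
    assert sf["s2"] == pytest.approx(20 / np.sqrt(200))
    # doubling one column's counts doubles its factor relative to the other
    doubled = diffexpr.size_factors(counts.assign(s2=[40]))
    assert doubled["s2"] / doubled["s1"] == pytest.approx(2 * sf["s2"] / sf["s1"])


def test_size_factors_require_reference_gene():
    counts = pd.DataFrame({"s1": [0, 3], "s2": [4, 0]},
                          index=pd.Index(["a", "b"], name="gene_id"))
    with pytest.raises(ValueError):
        diffexpr.size_factors(counts)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def test_dispersion_poisson_near_zero():
    rng = np.random.default_rng(12)
    cm = make_counts(rng.poisson(200.0, size=(2000, 6)))
    groups = [cm.sample_ids(role="maternal"), cm.sample_ids(role="hybrid")]
    alpha = diffexpr.estimate_dispersion(cm, groups)
    assert alpha.mean() <= 0.02


def test_dispersion_recovers_true_value():
    rng = np.random.default_rng(13)
    a_true, mu = 0.2, 500.0
    y = rng.negative_binomial(1 / a_true, 1 / (1 + a_true * mu), size=(2000, 6))
    cm = make_counts(y)
    alpha = diffexpr.estimate_dispersion(cm, [cm.sample_ids()])
    assert 0.1 <= np.median(alpha) <= 0.3


def test_dispersion_clamps_underdispersed_to_trend_only():
    # variance below the mean: raw MOM clamps at zero
    counts = np.tile([10, 10, 10, 10, 10, 10], (5, 1))
    cm = make_counts(counts)
    alpha = diffexpr.estimate_dispersion(cm, [cm.sample_ids(role="maternal"),
                                              cm.sample_ids(role="hybrid")])
    assert np.allclose(alpha, 0.0)


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------

def test_identical_groups_give_symmetric_null():
    counts = np.tile([7, 11, 20], (4, 2))
    cm = make_counts(counts)
    res = diffexpr.nb_wald_test(cm, cm.sample_ids(role="maternal"),
                                cm.sample_ids(role="hybrid"))
    assert np.allclose(res["log2fc"], 0.0)
    assert np.allclose(res["stat"], 0.0)
    assert np.allclose(res["p"], 1.0)


def test_label_swap_antisymmetry():
    rng = np.random.default_rng(5)
    cm = make_counts(rng.poisson(80, size=(50, 6)) + 1)
    a, b = cm.sample_ids(role="maternal"), cm.sample_ids(role="hybrid")
    r1 = diffexpr.nb_wald_test(cm, a, b)
    r2 = diffexpr.nb_wald_test(cm, b, a)
    assert np.allclose(r1["log2fc"], -r2["log2fc"], atol=1e-9)
    assert np.allclose(r1["p"], r2["p"], atol=1e-9)


def test_bh_monotone_and_fdr_at_least_p():
    rng = np.random.default_rng(6)
    cm = make_counts(rng.poisson(50, size=(300, 6)))
    res = diffexpr.nb_wald_test(cm, cm.sample_ids(role="maternal"),
                                cm.sample_ids(role="hybrid")).dropna(subset=["p"])
    assert (res["fdr"] >= res["p"] - 1e-12).all()
    s = res.sort_values("p")
    assert (np.diff(s["fdr"]) >= -1e-12).all()


def test_deg_flag_matches_thresholds():
    rng = np.random.default_rng(7)
    y = rng.poisson(100, size=(200, 6))
    y[:40, 3:] *= 8
    cm = make_counts(y)
    res = diffexpr.nb_wald_test(cm, cm.sample_ids(role="maternal"),
                                cm.sample_ids(role="hybrid"))
    expect = (res["fdr"] <= 0.01) & (res["log2fc"].abs() >= 1)
    assert (res["is_deg"] == expect.fillna(False)).all()
    assert res.loc[res["is_deg"], "direction"].isin(["up", "down"]).all()
    assert (res.loc[~res["is_deg"], "direction"] == "ns").all()


def test_size_factor_absorption_is_exact_and_calls_stable():
    """Scaling one sample's counts by an integer is absorbed by the size
    factors: normalized counts, dispersions and base means are identical,
    and DEG calls on a well-separated instance do not change."""
    rng = np.random.default_rng(8)
    y = rng.poisson(100, size=(200, 6))
    y[:30, 3:] *= 16
    cm1 = make_counts(y)
    y2 = y.copy()
    y2[:, 2] *= 3
    cm2 = make_counts(y2)
    a = [s for s in cm1.counts.columns[:3]]
    b = [s for s in cm1.counts.columns[3:]]
    sf1 = diffexpr.size_factors(cm1)
    sf2 = diffexpr.size_factors(cm2)
    # the scaled sample's factor absorbs the 3x relative to the others
    assert sf2.iloc[2] / sf2.iloc[0] == pytest.approx(3 * sf1.iloc[2] / sf1.iloc[0])
    # normalized matrices agree up to one common scalar
    n1 = diffexpr.normalize(cm1, sf1).to_numpy()
    n2 = diffexpr.normalize(cm2, sf2).to_numpy()
    ratio = n2 / n1
    assert np.allclose(ratio, ratio.flat[0], rtol=1e-12)
    r1 = diffexpr.nb_wald_test(cm1, a, b)
    r2 = diffexpr.nb_wald_test(cm2, a, b)
    assert np.allclose(r1["log2fc"], r2["log2fc"], atol=0.1)
    assert (r1["is_deg"] == r2["is_deg"]).all()


def _oracle_wald_p(ya, yb, alpha):
    """Independent single-gene NB Wald p: profile the two group means on a
    grid, then use expected information at the grid MLE."""
    def nll(mu, y):
        return -stats.nbinom.logpmf(y, 1 / alpha, 1 / (1 + alpha * mu)).sum()

    def grid_mle(y):
        lo, hi = np.log(max(y.mean(), 0.1)) - 2, np.log(max(y.mean(), 0.1)) + 2
        grid = np.exp(np.linspace(lo, hi, 8001))
        vals = [nll(m, y) for m in grid]
        return grid[int(np.argmin(vals))]

    ma, mb = grid_mle(ya), grid_mle(yb)
    beta1 = np.log(mb / ma)
    info_a = len(ya) * ma / (1 + alpha * ma)
    info_b = len(yb) * mb / (1 + alpha * mb)
    se = np.sqrt(1 / info_a + 1 / info_b)
    return 2 * stats.norm.sf(abs(beta1 / se))


@pytest.mark.parametrize("ya,yb,alpha", [
    ([23, 31, 27], [55, 61, 49], 0.05),
    ([120, 100, 95], [130, 110, 98], 0.1),
    ([12, 9, 15], [6, 4, 7], 0.2),
])
def test_wald_p_matches_profile_likelihood_oracle(ya, yb, alpha):
    cm = make_counts(np.array([ya + yb]))
    sf = pd.Series(1.0, index=cm.counts.columns)
    res = diffexpr.nb_wald_test(cm, cm.sample_ids(role="maternal"),
                                cm.sample_ids(role="hybrid"), sf=sf,
                                alpha=pd.Series([alpha], index=cm.counts.index))
    p_oracle = _oracle_wald_p(np.array(ya), np.array(yb), alpha)
    assert res["p"].iloc[0] == pytest.approx(p_oracle, rel=0.01)


def test_null_calibration_and_power():
    from heteroseq import simdata

    cfg = simdata.SimConfig(seed=1, n_genes=5000, frac_de=0.0, dispersion=0.1,
                            sd_log_expression=0.0, tissues=("leaf",))
    cm, _ = simdata.simulate_trio_counts(cfg)
    res = diffexpr.nb_wald_test(cm, cm.sample_ids(role="maternal", tissue="leaf"),
                                cm.sample_ids(role="hybrid", tissue="leaf"))
    frac = (res["p"].dropna() < 0.05).mean()
    assert 0.03 <= frac <= 0.07

    cfg = simdata.SimConfig(seed=4, n_genes=1000, frac_de=0.3, dispersion=0.05,
                            sd_log_expression=0.0, tissues=("leaf",))
    cm, truth = simdata.simulate_trio_counts(cfg)
    res = diffexpr.nb_wald_test(cm, cm.sample_ids(role="paternal", tissue="leaf"),
                                cm.sample_ids(role="maternal", tissue="leaf"))
    de = set(truth.loc[truth["de_status"], "gene_id"])
    called = set(res.loc[res["is_deg"], "gene_id"])
    assert len(de & called) / len(de) >= 0.8


def test_sample_correlation_identity_and_scaling():
    rng = np.random.default_rng(9)
    y = rng.poisson(60, size=(500, 6))
    y[:, 1] = y[:, 0] * 2  # scaled copy
    cm = make_counts(y)
    r2 = diffexpr.sample_correlation(cm)
    assert np.allclose(np.diag(r2), 1.0)
    assert r2.iloc[0, 1] == pytest.approx(1.0)


def test_replicates_sharing_means_correlate_higher_than_independent():
    rng = np.random.default_rng(10)
    mu = np.exp(rng.normal(4, 1, size=2000))
    reps = rng.poisson(np.tile(mu, (3, 1)).T)       # share gene means
    indep = rng.poisson(np.full((2000, 3), mu.mean()))  # no shared structure
    cm = make_counts(np.concatenate([reps, indep], axis=1))
    r2 = diffexpr.sample_correlation(cm)
    assert r2.iloc[0, 1] > r2.iloc[3, 4]
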