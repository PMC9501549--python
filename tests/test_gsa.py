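import numpy as np
import pandas as pd
import pytest
from scipy import stats

from camsignal.gsa import (GSAConfig, ks_regionalized, lhs_sample,
                           monotonicity_screen, prcc, run_gsa)


def oracle_partial_rank_corr(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent PRCC oracle: partial correlations from the inverse of the
    joint rank-correlation matrix (precision-matrix identity), no
    residualization anywhere."""
    ranks = np.column_stack([stats.rankdata(c) for c in
                             np.column_stack([x, y]).T])
    corr = np.corrcoef(ranks, rowvar=False)
    prec = np.linalg.inv(corr)
    k = x.shape[1]
    return np.array([-prec[j, k] / np.sqrt(prec[j, j] * prec[k, k])
                     for j in range(k)])


# ---------------------------------------------------------------- LHS


def test_lhs_stratification_is_exact():
    s = lhs_sample({"x": (0.0, 1.0)}, 4, seed=3)["x"].to_numpy()
    assert sorted(np.floor(s * 4).astype(int)) == [0, 1, 2, 3]


def test_lhs_marginals_uniform():
    s = lhs_sample({"a": (2.0, 6.0), "b": (-1.0, 1.0)}, 5000, seed=0)
    for name, (lo, hi) in (("a", (2, 6)), ("b", (-1, 1))):
        u = (s[name] - lo) / (hi - lo)
        assert stats.kstest(u, "uniform").pvalue > 0.01


def test_lhs_seeds_differ_but_stratify_identically():
    r1 = lhs_sample({"x": (0.0, 1.0)}, 100, seed=1)["x"].to_numpy()
    r2 = lhs_sample({"x": (0.0, 1.0)}, 100, seed=2)["x"].to_numpy()
    assert not np.array_equal(r1, r2)
    for r in (r1, r2):
        assert sorted(np.floor(r * 100).astype(int)) == list(range(100))


# ------------------------------------------------------- monotonic screen


def test_screen_keeps_full_monotone_range():
    x = np.linspace(0, 1, 21)
    assert monotonicity_screen(x, x**2) == (0.0, 1.0)
    assert monotonicity_screen(x, -x) == (0.0, 1.0)


def test_screen_truncates_unimodal_to_longer_limb():
    x = np.linspace(0, 1, 21)
    bump = -((x - 0.3) ** 2)           # peak at 0.3: right limb longer
    lo, hi = monotonicity_screen(x, bump)
    assert (lo, hi) == (pytest.approx(0.3), 1.0)
    bump = -((x - 0.5) ** 2)           # symmetric: tie breaks to lower side
    lo, hi = monotonicity_screen(x, bump)
    assert (lo, hi) == (0.0, pytest.approx(0.5))


def test_screen_excludes_flat_keeps_only_short_limb_of_oscillation():
    x = np.linspace(0, 1, 21)
    assert monotonicity_screen(x, np.full(21, 3.3)) is None
    # a fast oscillation has no long monotone limb: either excluded or
    # truncated to a small fraction of the range
    out = monotonicity_screen(x, np.sin(40 * x))
    assert out is None or (out[1] - out[0]) <= 0.25


# ---------------------------------------------------------------- PRCC


def test_prcc_matches_precision_matrix_oracle(rng):
    n, k = 50, 3
    x = rng.uniform(size=(n, k))
    y = 2 * x[:, 0] - x[:, 1] ** 2 + rng.normal(0, 0.2, n)
    table = prcc(pd.DataFrame(x, columns=list("abc")), y)
    expected = oracle_partial_rank_corr(x, y)
    got = table.table["prcc"].to_numpy(float)
    assert got == pytest.approx(expected, abs=1e-10)


def test_prcc_dominant_and_null_parameters(rng):
    n = 400
    x = rng.uniform(size=(n, 4))
    y = x[:, 0]
    table = prcc(pd.DataFrame(x, columns=list("wxyz")), y)
    assert table["w"] > 0.99
    assert table.table.loc["w", "significant"]
    for other in "xyz":
        assert abs(table[other]) < 0.2
    # response independent of all inputs: nothing significant
    null = prcc(pd.DataFrame(x, columns=list("wxyz")), rng.normal(size=n))
    assert not null.table["significant"].any()
    assert null.table["prcc"].abs().max() < 0.2


def test_prcc_invariant_under_monotone_input_transforms(rng):
    n = 120
    x = rng.uniform(0.1, 1, (n, 3))
    y = x[:, 0] - 0.5 * x[:, 2] + rng.normal(0, 0.1, n)
    base = prcc(pd.DataFrame(x, columns=list("abc")), y).table["prcc"]
    warped = x.copy()
    warped[:, 0] = np.exp(warped[:, 0])
    warped[:, 1] = warped[:, 1] ** 3
    again = prcc(pd.DataFrame(warped, columns=list("abc")), y).table["prcc"]
    assert again.to_numpy() == pytest.approx(base.to_numpy(), abs=1e-12)


def test_prcc_sign_convention(rng):
    n = 300
    x = rng.uniform(size=(n, 2))
    y = 3 * x[:, 0] - 2 * x[:, 1] + rng.normal(0, 0.05, n)
    t = prcc(pd.DataFrame(x, columns=["up", "down"]), y)
    assert t["up"] > 0.8
    assert t["down"] < -0.8


def test_prcc_rejects_degenerate_inputs(rng):
    x = pd.DataFrame({"a": np.ones(30), "b": rng.uniform(size=30)})
    with pytest.raises(ValueError, match="a"):
        prcc(x, rng.uniform(size=30))
    small = pd.DataFrame(rng.uniform(size=(4, 3)), columns=list("abc"))
    with pytest.raises(ValueError):
        prcc(small, rng.uniform(size=4))


def test_prcc_stable_across_sample_sizes(rng):
    """Strong PRCCs agree within 0.1 between n=500 and n=5000."""
    def draw(n):
        x = rng.uniform(size=(n, 3))
        y = x[:, 0] + 0.5 * x[:, 1] + rng.normal(0, 0.3, n)
        return prcc(pd.DataFrame(x, columns=list("abc")), y).table["prcc"]

    small, large = draw(500), draw(5000)
    for name in "ab":
        assert abs(large[name]) > 0.3
        assert small[name] == pytest.approx(large[name], abs=0.1)


# ---------------------------------------------------------------- KS


def test_ks_flags_planted_parameters_only(rng):
    n = 5000
    samples = pd.DataFrame(rng.uniform(size=(n, 4)), columns=list("abcd"))
    accepted = ((samples["a"] > 0.5) & (samples["c"] < 0.7)).to_numpy()
    out = ks_regionalized(samples, accepted)
    assert bool(out.loc["a", "sensitive"]) and bool(out.loc["c", "sensitive"])
    assert not out.loc["b", "sensitive"] and not out.loc["d", "sensitive"]
    # a>0.5 is a hard cut: KS distance ≈ P(rejected a < 0.5) is large
    assert out.loc["a", "ks_statistic"] > 0.5


def test_ks_requires_contrast(rng):
    samples = pd.DataFrame({"a": rng.uniform(size=50)})
    with pytest.raises(ValueError):
        ks_regionalized(samples, np.ones(50, dtype=bool))


# ---------------------------------------------------------------- pipeline


def test_run_gsa_deterministic_and_ranks_dominant_rate(params):
    """A two-parameter campaign on the fast 10 Hz protocol: the CaMKII pool
    dominates total CaM₄ relative to a dephosphorylation Michaelis constant,
    and reruns with the same seed are identical."""
    cfg = GSAConfig(parameters=("CaMKII_T", "Km16"), n_samples=30,
                    protocol="HZ10", seed=5)
    t1 = run_gsa(cfg, params, screen=False)
    t2 = run_gsa(cfg, params, screen=False)
    assert t1.table["prcc"].equals(t2.table["prcc"])
    assert abs(t1["CaMKII_T"]) > abs(t1["Km16"])
    assert abs(t1["CaMKII_T"]) > 0.5


def test_gsa_config_warns_when_undersampled(params):
    cfg = GSAConfig(parameters=("CaMKII_T", "Km16"), n_samples=12)
    with pytest.warns(UserWarning, match="noisy"):
        cfg.resolved_ranges(params)
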