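"""Canonical correlation core: oracles, invariants, significance testing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.stats import chi2

from seedling_observer.blocks import (
    DegenerateInputError,
    DimensionError,
    MeasurementBlock,
)
from seedling_observer.cca import (
    RetentionConfig,
    canonical_loadings,
    chi2_critical,
    fit_cca,
    q_statistic,
    retained_pairs,
    with_retention,
)


def _block(name, values):
    values = np.asarray(values, dtype=float)
    ids = tuple(f"{name.lower()}{j + 1}" for j in range(values.shape[1]))
    return MeasurementBlock(name=name, parameter_ids=ids, values=values)


def test_identical_blocks_give_unit_canonical_correlations(rng):
    x = _block("X", rng.normal(size=(10, 3)))
    res = fit_cca(x, x)
    assert np.allclose(res.lambdas, 1.0, atol=1e-8)


@pytest.mark.parametrize("seed", range(5))
def test_first_lambda_squared_equals_ols_r2_when_q_is_one(seed):
    """With a single response, CCA reduces to multiple regression: lambda_1^2
    is the coefficient of determination of y on X (independent lstsq oracle)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(30, 2))
    y = (x @ [1.0, -0.5] + rng.normal(scale=0.8, size=30)).reshape(-1, 1)

    xc = np.column_stack([np.ones(30), x])
    beta, *_ = np.linalg.lstsq(xc, y, rcond=None)
    resid = y - xc @ beta
    r2 = 1.0 - resid.var() / y.var()

    res = fit_cca(_block("X", x), _block("Y", y))
    assert res.lambdas[0] ** 2 == pytest.approx(r2, abs=1e-8)


def _grid_max_corr(x, y, steps=1440):
    """Brute-force maximum of corr(a'X, b'Y) over unit directions (p=q=2)."""
    angles = np.linspace(0.0, np.pi, steps, endpoint=False)
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    u = x @ dirs.T  # (n, steps)
    v = y @ dirs.T
    u = (u - u.mean(axis=0)) / u.std(axis=0)
    v = (v - v.mean(axis=0)) / v.std(axis=0)
    return np.abs(u.T @ v / len(x)).max()


@pytest.mark.parametrize("seed", range(3))
def test_first_lambda_matches_grid_maximisation(seed):
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=(8, 2)), rng.normal(size=(8, 2))
    res = fit_cca(_block("X", x), _block("Y", y))
    assert res.lambdas[0] == pytest.approx(_grid_max_corr(x, y), abs=1e-2)


def test_canonical_correlations_match_statsmodels(rng):
    """Cross-check the whitened-SVD solution against an independent
    implementation on a larger block pair."""
    cancorr = pytest.importorskip("statsmodels.multivariate.cancorr")
    x, y = rng.normal(size=(40, 5)), rng.normal(size=(40, 3))
    res = fit_cca(_block("X", x), _block("Y", y))
    ref = cancorr.CanCorr(y, x).cancorr
    assert np.allclose(res.lambdas, ref, atol=1e-8)


def test_loadings_are_marginal_correlations_with_variates(rng):
    x, y = rng.normal(size=(25, 4)), rng.normal(size=(25, 3))
    xb, yb = _block("X", x), _block("Y", y)
    res = fit_cca(xb, yb)
    for i in range(res.m):
        for j in range(4):
            direct = np.corrcoef(x[:, j], res.x_scores[:, i])[0, 1]
            assert res.cl_xu[j, i] == pytest.approx(direct, abs=1e-10)
    cl_xu, cl_yv = canonical_loadings(res, xb, yb)
    assert np.allclose(np.abs(cl_xu), np.abs(res.cl_xu), atol=1e-10)
    assert np.allclose(np.abs(cl_yv), np.abs(res.cl_yv), atol=1e-10)


def test_single_column_block_loads_fully_on_its_variate(rng):
    x = _block("X", rng.normal(size=(15, 1)))
    y = _block("Y", rng.normal(size=(15, 3)))
    res = fit_cca(x, y)
    assert abs(res.cl_xu[0, 0]) == pytest.approx(1.0, abs=1e-10)


def test_sign_convention_largest_x_loading_positive(rng):
    res = fit_cca(
        _block("X", rng.normal(size=(20, 4))), _block("Y", rng.normal(size=(20, 3)))
    )
    for i in range(res.m):
        j = np.argmax(np.abs(res.cl_xu[:, i]))
        assert res.cl_xu[j, i] > 0


@given(
    scale=st.floats(0.01, 100.0),
    shift=st.floats(-50.0, 50.0),
    col=st.integers(0, 3),
    seed=st.integers(0, 10),
)
def test_affine_rescaling_of_a_column_changes_nothing(scale, shift, col, seed):
    """The analysis is correlation-based: units and offsets cancel."""
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=(20, 4)), rng.normal(size=(20, 3))
    base = fit_cca(_block("X", x), _block("Y", y))
    x2 = x.copy()
    x2[:, col] = scale * x2[:, col] + shift
    res = fit_cca(_block("X", x2), _block("Y", y))
    assert np.allclose(res.lambdas, base.lambdas, atol=1e-9)
    assert np.allclose(np.abs(res.cl_xu), np.abs(base.cl_xu), atol=1e-8)
    assert np.allclose(res.m_u, base.m_u, atol=1e-8)
    assert np.allclose(res.q_stats, base.q_stats, atol=1e-6)


@pytest.mark.parametrize("seed", range(5))
def test_first_lambda_dominates_marginal_correlations(seed):
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=(30, 3)), rng.normal(size=(30, 2))
    res = fit_cca(_block("X", x), _block("Y", y))
    marginals = np.abs(np.corrcoef(x.T, y.T)[:3, 3:])
    assert res.lambdas[0] >= marginals.max() - 1e-12


def test_y_proportions_sum_to_one_when_q_is_min(rng):
    x, y = rng.normal(size=(30, 6)), rng.normal(size=(30, 3))
    res = fit_cca(_block("X", x), _block("Y", y))
    assert res.n_v.sum() == pytest.approx(1.0, abs=1e-9)


def test_lambdas_sorted_and_bounded(rng):
    res = fit_cca(
        _block("X", rng.normal(size=(25, 5))), _block("Y", rng.normal(size=(25, 4)))
    )
    assert np.all(res.lambdas[:-1] >= res.lambdas[1:] - 1e-12)
    assert np.all((res.lambdas >= 0) & (res.lambdas <= 1))
    assert np.all(np.abs(res.cl_xu) <= 1 + 1e-12)
    assert np.all(np.abs(res.cl_yv) <= 1 + 1e-12)


# ---------------------------------------------------------------- Q statistic

def test_q_statistic_zero_iff_all_lambdas_zero():
    lam = np.zeros(3)
    for i in (1, 2, 3):
        assert q_statistic(lam, 50, 4, 3, i) == 0.0
    lam2 = np.array([0.5, 0.0, 0.0])
    assert q_statistic(lam2, 50, 4, 3, 1) > 0.0
    assert q_statistic(lam2, 50, 4, 3, 2) == 0.0


@given(
    lams=st.lists(st.floats(0.0, 0.99), min_size=3, max_size=3),
    i=st.integers(1, 3),
)
def test_q_statistic_non_negative(lams, i):
    lam = np.sort(np.asarray(lams))[::-1]
    assert q_statistic(lam, 100, 5, 3, i) >= 0.0


def test_q_statistic_infinite_at_unit_lambda():
    lam = np.array([1.0, 0.5, 0.2])
    assert np.isinf(q_statistic(lam, 50, 4, 3, 1))


def test_q_statistic_warns_when_sample_count_too_small():
    lam = np.array([0.5, 0.3])
    with pytest.warns(UserWarning, match="applicability"):
        q_statistic(lam, 5, 3, 2, 1)


def test_q_statistic_rejects_bad_pair_index():
    with pytest.raises(ValueError):
        q_statistic(np.array([0.5, 0.3]), 50, 3, 2, 3)


# ------------------------------------------------------------- chi2 criticals

def test_chi2_critical_matches_numeric_cdf_inversion():
    for alpha, dof in [(0.05, 1), (0.05, 12), (0.01, 7)]:
        inverted = brentq(
            lambda x: chi2.cdf(x, dof) - (1 - alpha), 1e-12, 1e3, xtol=1e-10
        )
        assert chi2_critical(alpha, dof) == pytest.approx(inverted, abs=1e-6)


@pytest.mark.parametrize(
    "alpha,dof", [(0.0, 5), (1.0, 5), (0.05, 0), (0.05, 2.5)]
)
def test_chi2_critical_rejects_invalid_arguments(alpha, dof):
    with pytest.raises(ValueError):
        chi2_critical(alpha, dof)


# ------------------------------------------------------------------ retention

def test_all_significant_balanced_pairs_are_retained(rng):
    # strongly coupled blocks: every pair significant and balanced
    z = rng.normal(size=(60, 3))
    x = z + 0.1 * rng.normal(size=(60, 3))
    y = z + 0.1 * rng.normal(size=(60, 3))
    res = fit_cca(_block("X", x), _block("Y", y))
    assert res.concerned_pairs == (1, 2, 3)


def test_retention_respects_manual_drops_and_floor(rng):
    z = rng.normal(size=(60, 3))
    x = z + 0.1 * rng.normal(size=(60, 3))
    y = z + 0.1 * rng.normal(size=(60, 3))
    res = fit_cca(_block("X", x), _block("Y", y))
    cfg = RetentionConfig(manual_drops=frozenset({2}))
    assert retained_pairs(res, cfg) == (1, 3)
    cfg = RetentionConfig(proportion_floor=0.99)
    assert retained_pairs(res, cfg) == ()


def test_with_retention_switches_convention():
    from seedling_observer.reference import reference_result

    res = reference_result(("E", "G1"), q_convention="squared")
    out = with_retention(res, RetentionConfig(q_convention="unsquared"))
    assert not np.allclose(out.q_stats, res.q_stats)


# ------------------------------------------------------------------- errors

def test_mismatched_row_counts_raise_dimension_error(rng):
    with pytest.raises(DimensionError, match="rows"):
        fit_cca(
            _block("X", rng.normal(size=(10, 2))),
            _block("Y", rng.normal(size=(12, 2))),
        )


def test_constant_column_raises_naming_the_column(rng):
    x = rng.normal(size=(10, 3))
    x[:, 1] = 7.0
    with pytest.raises(DegenerateInputError, match="x2"):
        fit_cca(_block("X", x), _block("Y", rng.normal(size=(10, 2))))


def test_collinear_block_is_ridged_with_warning(rng, caplog):
    x = rng.normal(size=(20, 2))
    x = np.column_stack([x, x[:, 0] + x[:, 1]])  # exactly rank-deficient
    with caplog.at_level("WARNING", logger="seedling_observer.cca"):
        res = fit_cca(_block("X", x), _block("Y", rng.normal(size=(20, 2))))
    assert "near-singular" in caplog.text
    assert np.all(np.isfinite(res.lambdas))
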