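"""Canonical correlation analysis with significance testing and retention.

Given two measurement blocks X (n x p) and Y (n x q), CCA finds pairs of
canonical variates U_i = a_i'X, V_i = b_i'Y maximising corr(U_i, V_i)
subject to unit variance and orthogonality to earlier pairs.  The analysis
here is correlation-based: columns are standardised first, so the canonical
correlations, loadings and downstream statistics are invariant to the units
and offsets of the raw measurements.

Beyond the canonical correlations lambda_1 >= ... >= lambda_m (m = min(p,q))
the module computes, for each pair i:

* canonical loadings: corr(x_j, U_i) and corr(y_k, V_i), the screening
  quantity used to judge which original parameters a variate represents;
* explanation proportions: mean squared loading of a variate over its
  block, i.e. the share of the block's (standardised) variance the variate
  carries;
* a Bartlett-type significance statistic
  ``Q_i = -(l - i - (p+q+1)/2) * ln(prod_{j>=i} (1 - lambda_j^2))``
  which is approximately chi-square with (p-i+1)(q-i+1) degrees of freedom
  under the null that pair i and all later pairs are uncorrelated.  An
  alternate convention with factors ``(1 - lambda_j)`` is provided for
  tables whose printed values are squared canonical correlations;
* a retention rule: pair i is kept for interpretation when Q_i exceeds the
  upper-alpha chi-square critical value AND both of its explanation
  proportions reach a floor (a significant but one-sidedly tiny pair
  explains too little of one block to be meaningful), minus any explicitly
  excluded pairs.

Pair indices are 1-based throughout, matching the usual tabular convention
(lambda_1 is the leading pair).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, stats

from .blocks import DegenerateInputError, DimensionError, MeasurementBlock

logger = logging.getLogger(__name__)

__all__ = [
    "RetentionConfig",
    "CCAResult",
    "fit_cca",
    "canonical_loadings",
    "explanation_proportions",
    "q_statistic",
    "chi2_critical",
    "retained_pairs",
]


@dataclass(frozen=True)
class RetentionConfig:
    """Settings for significance testing and canonical-pair retention.

    alpha
        Test level for the chi-square criterion (default 0.05).
    proportion_floor
        Minimum explanation proportion required on *both* sides for a pair
        to be considered balanced enough to interpret (default 0.05).
    manual_drops
        Pair indices (1-based) excluded by explicit judgment; retention
        never drops a pair silently for reasons the printed statistics do
        not express.
    q_convention
        ``"squared"`` uses factors (1 - lambda_j^2) in the Q product (the
        standard Bartlett form); ``"unsquared"`` uses (1 - lambda_j), for
        reference tables whose correlation entries are already squared.
    ridge
        Diagonal ridge added to a near-singular within-block correlation
        matrix before whitening.
    """

    alpha: float = 0.05
    proportion_floor: float = 0.05
    manual_drops: frozenset[int] = frozenset()
    q_convention: str = "squared"
    ridge: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 <= self.proportion_floor < 1.0:
            raise ValueError("proportion_floor must lie in [0, 1)")
        if self.q_convention not in ("squared", "unsquared"):
            raise ValueError("q_convention must be 'squared' or 'unsquared'")
        object.__setattr__(self, "manual_drops", frozenset(self.manual_drops))


@dataclass
class CCAResult:
    """Canonical correlation analysis output for one block pair."""

    x_name: str
    y_name: str
    x_params: tuple[str, ...]
    y_params: tuple[str, ...]
    n_samples: int
    lambdas: np.ndarray          # (m,) canonical correlations, non-increasing
    a_coeffs: np.ndarray         # (p, m) standard coefficients, var(U_i) = 1
    b_coeffs: np.ndarray         # (q, m) standard coefficients, var(V_i) = 1
    cl_xu: np.ndarray            # (p, m) loadings corr(x_j, U_i)
    cl_yv: np.ndarray            # (q, m) loadings corr(y_k, V_i)
    m_u: np.ndarray              # (m,) explanation proportions of U for X
    n_v: np.ndarray              # (m,) explanation proportions of V for Y
    q_stats: np.ndarray          # (m,) significance statistics Q_i
    dofs: np.ndarray             # (m,) integer degrees of freedom
    crit_values: np.ndarray      # (m,) chi-square upper-alpha criticals
    concerned_pairs: tuple[int, ...]  # retained pair indices, 1-based
    config: RetentionConfig = field(default_factory=RetentionConfig)
    x_scores: np.ndarray | None = None   # (n, m) canonical variates U
    y_scores: np.ndarray | None = None   # (n, m) canonical variates V

    @property
    def m(self) -> int:
        return len(self.lambdas)

    def to_dict(self) -> dict:
        """JSON-serialisable summary (scores omitted)."""
        return {
            "x_block": self.x_name,
            "y_block": self.y_name,
            "x_params": list(self.x_params),
            "y_params": list(self.y_params),
            "n_samples": self.n_samples,
            "lambdas": self.lambdas.tolist(),
            "a_coeffs": self.a_coeffs.tolist(),
            "b_coeffs": self.b_coeffs.tolist(),
            "cl_xu": self.cl_xu.tolist(),
            "cl_yv": self.cl_yv.tolist(),
            "m_u": self.m_u.tolist(),
            "n_v": self.n_v.tolist(),
            "q_stats": [float(q) for q in self.q_stats],
            "dofs": self.dofs.tolist(),
            "crit_values": self.crit_values.tolist(),
            "alpha": self.config.alpha,
            "q_convention": self.config.q_convention,
            "concerned_pairs": list(self.concerned_pairs),
        }


def _standardize(block: MeasurementBlock) -> np.ndarray:
    """Zero-mean, unit-variance columns; a constant column is degenerate."""
    v = block.values
    sd = v.std(axis=0, ddof=1)
    bad = [pid for j, pid in enumerate(block.parameter_ids) if sd[j] == 0.0]
    if bad:
        raise DegenerateInputError(
            f"block {block.name!r}: constant column(s) {bad} have zero variance"
        )
    return (v - v.mean(axis=0)) / sd


def _inv_sqrt(corr: np.ndarray, ridge: float, label: str) -> np.ndarray:
    """Inverse symmetric square root, ridged when near-singular."""
    evals, evecs = linalg.eigh(corr)
    if evals.min() < 1e-10:
        logger.warning(
            "correlation matrix of %s is near-singular (min eigenvalue %.3g); "
            "adding ridge %.3g", label, evals.min(), ridge
        )
        evals, evecs = linalg.eigh(corr + ridge * np.eye(corr.shape[0]))
    return (evecs * evals**-0.5) @ evecs.T


def fit_cca(
    x_block: MeasurementBlock,
    y_block: MeasurementBlock,
    config: RetentionConfig | None = None,
) -> CCAResult:
    """Fit correlation-based CCA between two blocks sharing samples.

    Solved by singular value decomposition of the whitened cross-correlation
    matrix ``Rxx^{-1/2} Rxy Ryy^{-1/2}``; the singular values are the
    canonical correlations.  Coefficients are scaled so each variate has
    unit sample variance, and each pair's signs are fixed so that the
    largest-magnitude X-side loading is positive (interpretation uses
    absolute loadings only, so any consistent convention is valid; this one
    makes outputs deterministic).
    """
    cfg = config or RetentionConfig()
    if x_block.n_samples != y_block.n_samples:
        raise DimensionError(
            f"blocks {x_block.name!r} ({x_block.n_samples} samples) and "
            f"{y_block.name!r} ({y_block.n_samples} samples) differ in rows"
        )
    n = x_block.n_samples
    p, q = x_block.n_params, y_block.n_params
    zx, zy = _standardize(x_block), _standardize(y_block)

    rxx = zx.T @ zx / (n - 1)
    ryy = zy.T @ zy / (n - 1)
    rxy = zx.T @ zy / (n - 1)
    kx = _inv_sqrt(rxx, cfg.ridge, x_block.name)
    ky = _inv_sqrt(ryy, cfg.ridge, y_block.name)

    u, s, vt = linalg.svd(kx @ rxy @ ky, full_matrices=False)
    m = min(p, q)
    lambdas = np.clip(s[:m], 0.0, 1.0)
    a = kx @ u[:, :m]
    b = ky @ vt[:m].T

    # Enforce unit sample variance of the variates exactly (the whitening
    # guarantees it up to the ridge perturbation).
    ux, vy = zx @ a, zy @ b
    a /= ux.std(axis=0, ddof=1)
    b /= vy.std(axis=0, ddof=1)
    ux, vy = zx @ a, zy @ b

    cl_xu, cl_yv = _loadings(zx, ux), _loadings(zy, vy)

    # Sign convention: largest-|loading| on the X side positive per pair.
    for i in range(m):
        j = int(np.argmax(np.abs(cl_xu[:, i])))
        if cl_xu[j, i] < 0:
            a[:, i] *= -1
            b[:, i] *= -1
            ux[:, i] *= -1
            vy[:, i] *= -1
            cl_xu[:, i] *= -1
            cl_yv[:, i] *= -1

    m_u, n_v = explanation_proportions(cl_xu, cl_yv)
    q_stats = np.array(
        [q_statistic(lambdas, n, p, q, i, cfg.q_convention) for i in range(1, m + 1)]
    )
    dofs = np.array([(p - i + 1) * (q - i + 1) for i in range(1, m + 1)], dtype=int)
    crit = np.array([chi2_critical(cfg.alpha, int(d)) for d in dofs])

    result = CCAResult(
        x_name=x_block.name, y_name=y_block.name,
        x_params=x_block.parameter_ids, y_params=y_block.parameter_ids,
        n_samples=n, lambdas=lambdas, a_coeffs=a, b_coeffs=b,
        cl_xu=cl_xu, cl_yv=cl_yv, m_u=m_u, n_v=n_v,
        q_stats=q_stats, dofs=dofs, crit_values=crit,
        concerned_pairs=(), config=cfg, x_scores=ux, y_scores=vy,
    )
    result.concerned_pairs = retained_pairs(result, cfg)
    return result


def _loadings(z: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Correlations of standardised columns with (near unit-var) scores."""
    sc = scores - scores.mean(axis=0)
    sc = sc / sc.std(axis=0, ddof=1)
    return z.T @ sc / (len(z) - 1)


def canonical_loadings(
    result: CCAResult,
    x_block: MeasurementBlock,
    y_block: MeasurementBlock,
) -> tuple[np.ndarray, np.ndarray]:
    """Recompute loadings from scratch for a fitted result.

    Entry (j, i) of the first matrix is the sample correlation of variable
    x_j with variate U_i; with standardised variables and unit-variance
    variates this equals cov(x_j, U_i).
    """
    zx, zy = _standardize(x_block), _standardize(y_block)
    return _loadings(zx, zx @ result.a_coeffs), _loadings(zy, zy @ result.b_coeffs)


def explanation_proportions(
    cl_xu: np.ndarray, cl_yv: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean squared loading per variate: the variance share it explains.

    ``m_u[i] = sum_j cl_xu[j, i]^2 / p`` and analogously for ``n_v``.  When
    q = min(p, q) the Y-side proportions sum to 1: the q variates span the
    standardised Y block exactly.
    """
    cl_xu = np.asarray(cl_xu, dtype=float)
    cl_yv = np.asarray(cl_yv, dtype=float)
    return (cl_xu**2).mean(axis=0), (cl_yv**2).mean(axis=0)


def q_statistic(
    lambdas: np.ndarray,
    l: int,
    p: int,
    q: int,
    i: int,
    convention: str = "squared",
) -> float:
    """Bartlett-type significance statistic for canonical pair i.

    ``Q_i = -(l - i - (p+q+1)/2) * ln(prod_{j=i..m} f_j)`` with
    ``f_j = 1 - lambda_j^2`` (``convention="squared"``) or
    ``f_j = 1 - lambda_j`` (``convention="unsquared"``); l is the number of
    samples that entered the CCA.  Approximately chi-square with
    (p-i+1)(q-i+1) degrees of freedom when l is large enough
    (l > (p+q+1)/2 + min(p,q)); smaller l triggers a warning but the
    statistic is still computed.  A canonical correlation of exactly 1
    yields an infinite statistic.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    m = min(p, q)
    if not 1 <= i <= m:
        raise ValueError(f"pair index i={i} outside 1..{m}")
    if len(lambdas) < m:
        raise DimensionError(f"need {m} canonical correlations, got {len(lambdas)}")
    if l <= (p + q + 1) / 2 + m:
        warnings.warn(
            f"sample count l={l} violates the chi-square applicability "
            f"condition l > (p+q+1)/2 + {m}; Q is computed anyway",
            stacklevel=2,
        )
    factors = 1.0 - (lambdas[i - 1 : m] ** 2 if convention == "squared"
                     else lambdas[i - 1 : m])
    if np.any(factors <= 0.0):
        return float("inf")
    return float(-(l - i - (p + q + 1) / 2) * np.log(np.prod(factors)))


def chi2_critical(alpha: float, dof: int) -> float:
    """Upper-alpha quantile of the chi-square distribution."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if not (isinstance(dof, (int, np.integer)) and dof >= 1):
        raise ValueError("dof must be an integer >= 1")
    return float(stats.chi2.ppf(1.0 - alpha, dof))


def retained_pairs(
    result: CCAResult, config: RetentionConfig | None = None
) -> tuple[int, ...]:
    """Pairs kept for interpretation, in ascending 1-based order.

    Pair i is retained iff its Q statistic exceeds the chi-square critical
    value, both explanation proportions reach ``proportion_floor`` (a pair
    whose variate explains almost nothing of one block is too unbalanced to
    interpret), and i is not manually excluded.
    """
    cfg = config or result.config
    kept = []
    for i in range(1, result.m + 1):
        if i in cfg.manual_drops:
            continue
        if not result.q_stats[i - 1] > result.crit_values[i - 1]:
            continue
        if min(result.m_u[i - 1], result.n_v[i - 1]) < cfg.proportion_floor:
            continue
        kept.append(i)
    return tuple(kept)


def with_retention(result: CCAResult, config: RetentionConfig) -> CCAResult:
    """Copy of ``result`` with statistics and retention under ``config``."""
    p, q = len(result.x_params), len(result.y_params)
    q_stats = np.array([
        q_statistic(result.lambdas, result.n_samples, p, q, i, config.q_convention)
        for i in range(1, result.m + 1)
    ])
    crit = np.array([chi2_critical(config.alpha, int(d)) for d in result.dofs])
    out = replace(result, q_stats=q_stats, crit_values=crit, config=config)
    out.concerned_pairs = retained_pairs(out, config)
    return out
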