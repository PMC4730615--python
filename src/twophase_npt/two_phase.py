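"""The two-phase procedure: model selection, size adjustment, full test.

Phase 1 classifies the mode of inheritance with the rank statistic
``Z1`` against a threshold ``xi`` (default the 90% standard-normal
quantile): dominant if ``Z1 > xi``, recessive if ``Z1 < -xi``, additive
otherwise.  Phase 2 applies the trend test matched to the selected model
at an *adjusted* level ``alpha_star`` so the overall type I error stays
at the nominal ``alpha``.  Under the null, (Z1, Zx) is asymptotically
bivariate normal with correlation ``rho_x``; ``alpha_star`` solves

    alpha = sum_x  int_{Omega_x} [ Phi((-c - rho_x u)/s_x)
                                 + Phi((-c + rho_x u)/s_x) ] dPhi(u),

with c = z(1 - alpha_star/2), s_x = sqrt(1 - rho_x^2), and the regions
Omega_R = {u < -xi}, Omega_A = {|u| <= xi}, Omega_D = {u > xi}.  The
right-hand side is strictly increasing in alpha_star, so the root is
unique; solved alpha_star is below alpha in every configuration met in
practice because the two phases are positively dependent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize, stats

from .rank_stats import (
    MODELS,
    DegenerateStatisticError,
    GroupedTrait,
    InputError,
    Model,
    TestResult,
    Ties,
    WinProbEstimates,
    _normal_result,
    _z1_from_estimates,
    _npt_from_estimates,
    group_by_genotype,
    numerator_weights,
    win_prob,
    win_prob_estimates,
    win_prob_variance,
)

logger = logging.getLogger("twophase_npt")

DEFAULT_XI = float(stats.norm.ppf(0.90))  # ~1.2816


@dataclass(frozen=True)
class SelectionRule:
    """Phase-1 threshold; ``xi`` is a positive standard-normal quantile."""

    xi: float = DEFAULT_XI

    def __post_init__(self):
        if not (self.xi > 0):
            raise InputError("selection threshold xi must be positive")

    @classmethod
    def from_quantile(cls, q: float) -> "SelectionRule":
        """Rule with ``xi`` the ``q``-th standard-normal quantile (q > 0.5)."""
        if not (0.5 < q < 1):
            raise InputError("quantile must be in (0.5, 1)")
        return cls(xi=float(stats.norm.ppf(q)))


@dataclass(frozen=True)
class JointNullCorrelations:
    """Null correlations of Z1 with each phase-2 trend statistic."""

    rho_R: float
    rho_A: float
    rho_D: float

    def __iter__(self):
        return iter((self.rho_R, self.rho_A, self.rho_D))


@dataclass(frozen=True)
class TwoPhaseResult:
    """Outcome of the two-phase test on one SNP."""

    z1: float | None
    selected_model: Model
    phase2: TestResult
    alpha_nominal: float
    alpha_star: float
    reject: bool
    rho: JointNullCorrelations | None = None
    fallback: bool = False


def select_model(z1: float, rule: SelectionRule = SelectionRule()) -> Model:
    """Classify the genetic model from Z1: DOM if Z1 > xi, REC if Z1 < -xi,
    otherwise ADD (boundary |Z1| = xi is additive)."""
    if not np.isfinite(z1):
        raise InputError("Z1 must be finite")
    if z1 > rule.xi:
        return "DOM"
    if z1 < -rule.xi:
        return "REC"
    return "ADD"


RhoMethod = Literal["adjacent", "pooled"]


def estimate_rho(
    g: GroupedTrait, ties: Ties = "strict", method: RhoMethod = "adjacent"
) -> JointNullCorrelations:
    """Estimate the null correlations of (Z1, Zx) for x in {R, A, D}.

    Z1 and the phase-2 statistics are linear forms in (f01, f12, f02)
    up to centering, so the plug-in covariance of the three win
    probabilities propagates through weight vectors by the delta method
    (ADD's inverse-SE weights treated as constants at their observed
    values).

    ``method="adjacent"`` (default) represents each phase-2 statistic
    by its adjacent two-group contrast — REC by f12, DOM by f01, ADD by
    the weighted (f01, f12) combination — the representation under
    which the size adjustment was derived; it yields the strongest
    phase coupling and hence the most conservative alpha_star.
    ``method="pooled"`` uses the full pooled numerator weights of
    ZR/ZA/ZD and consistently estimates the literal corr(Z1, Zx)
    (it matches the Monte-Carlo correlation of the two statistics).
    """
    est = win_prob_estimates(g, ties)
    return _rho_from_estimates(g, est, method)


def _correlation_weights(
    g: GroupedTrait, est: WinProbEstimates, model: Model, method: RhoMethod
) -> np.ndarray:
    if method == "pooled":
        return numerator_weights(g, est, model)
    if method != "adjacent":
        raise InputError(f"unknown rho method {method!r}")
    if model == "REC":
        return np.array([0.0, 1.0, 0.0])
    if model == "DOM":
        return np.array([1.0, 0.0, 0.0])
    return numerator_weights(g, est, "ADD")


def _rho_from_estimates(
    g: GroupedTrait, est: WinProbEstimates, method: RhoMethod = "adjacent"
) -> JointNullCorrelations:
    sigma = est.cov_matrix()
    a = np.array([1.0, -1.0, 0.0])  # Z1 numerator weights
    var_a = float(a @ sigma @ a)
    if var_a <= 0:
        raise DegenerateStatisticError("degenerate covariance")
    rhos = {}
    for model in MODELS:
        b = _correlation_weights(g, est, model, method)
        var_b = float(b @ sigma @ b)
        if var_b <= 0:
            raise DegenerateStatisticError("degenerate covariance")
        r = float(a @ sigma @ b) / np.sqrt(var_a * var_b)
        rhos[model] = float(np.clip(r, -1.0, 1.0))
    return JointNullCorrelations(rhos["REC"], rhos["ADD"], rhos["DOM"])


# ---------------------------------------------------------------------------
# size adjustment

_QUAD_CACHE: dict[tuple[float, int], tuple[np.ndarray, ...]] = {}
#: integration truncated at |u| = 8; the neglected normal tail mass < 1e-15
_U_MAX = 8.0


def _region_nodes(xi: float, n_nodes: int = 200):
    """Gauss-Legendre nodes/phi-weights for the three selection regions."""
    key = (round(xi, 12), n_nodes)
    if key not in _QUAD_CACHE:
        x, w = np.polynomial.legendre.leggauss(n_nodes)
        regions = []
        for lo, hi in ((-_U_MAX, -xi), (-xi, xi), (xi, _U_MAX)):
            mid, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
            u = mid + half * x
            regions.append((u, half * w * stats.norm.pdf(u)))
        _QUAD_CACHE[key] = tuple(regions)
    return _QUAD_CACHE[key]


def _overall_size(alpha_star: float, xi: float, rhos) -> float:
    """Overall rejection probability of the two-phase procedure under the
    null when phase 2 tests at level ``alpha_star``."""
    c = stats.norm.ppf(1.0 - alpha_star / 2.0)
    total = 0.0
    regions = _region_nodes(xi)
    for (u, w), rho in zip(regions, rhos):
        if 1.0 - abs(rho) < 1e-9:
            # degenerate limit Zx = sign(rho) * Z1: the region contributes
            # the exact mass of {|u| > c} within itself
            lo, hi = u[0], u[-1]
            if hi <= 0:  # recessive region
                total += float(stats.norm.cdf(-max(xi, c)))
            elif lo >= 0:  # dominant region
                total += float(stats.norm.sf(max(xi, c)))
            else:  # additive region
                total += float(max(0.0, 2.0 * (stats.norm.cdf(xi) - stats.norm.cdf(c))))
            continue
        s = np.sqrt(1.0 - rho**2)
        inner = stats.norm.cdf((-c - rho * u) / s) + stats.norm.cdf((-c + rho * u) / s)
        total += float(w @ inner)
    return total


def adjusted_alpha(
    alpha: float,
    rule: SelectionRule = SelectionRule(),
    rho: JointNullCorrelations | None = None,
) -> float:
    """Solve for the phase-2 level alpha_star giving overall size ``alpha``.

    The overall-size equation is evaluated by Gauss-Legendre quadrature
    over the selection variable and the root located by bracketed
    root-finding (the size is strictly increasing in alpha_star).
    Returns exactly ``alpha`` when all correlations are zero and in the
    |rho| -> 1 degenerate limit.
    """
    if not (0.0 < alpha < 1.0):
        raise InputError("alpha must be in (0, 1)")
    rhos = tuple(rho) if rho is not None else (0.0, 0.0, 0.0)
    if any(abs(r) > 1.0 for r in rhos):
        raise InputError("correlations must lie in [-1, 1]")

    def gap(a_star: float) -> float:
        return _overall_size(a_star, rule.xi, rhos) - alpha

    lo, hi = 1e-13, 1.0 - 1e-13
    if gap(lo) > 0 or gap(hi) < 0:  # pragma: no cover - cannot occur for valid input
        raise RuntimeError("no sign change when bracketing alpha_star")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-12, rtol=8.9e-16))


# ---------------------------------------------------------------------------
# end-to-end procedure


def _fallback_test(g: GroupedTrait, alpha: float, ties: Ties) -> TwoPhaseResult:
    """Two-group win-probability test when a homozygote group is too small.

    The deficient homozygote group is pooled with the heterozygotes and
    Pr(Y_low < Y_high) tested against 1/2 — selection and size
    adjustment are skipped (tested at the unadjusted alpha).
    """
    if g.n2 < 2:
        low, high = g.values0, np.concatenate([g.values1, g.values2])
    else:
        low, high = np.concatenate([g.values0, g.values1]), g.values2
    if low.size < 2 or high.size < 2:
        raise DegenerateStatisticError(
            "cannot form two groups of size >= 2 for the fallback test"
        )
    f = win_prob(low, high, ties)
    var = win_prob_variance(low, high, ties)
    if var <= 1e-12:
        raise DegenerateStatisticError("degenerate variance")
    res = _normal_result((f - 0.5) / np.sqrt(var), "ZA")
    logger.warning(
        "genotype group counts %s too small for model selection; "
        "falling back to the pooled two-group test at unadjusted alpha",
        g.counts,
    )
    return TwoPhaseResult(
        z1=None,
        selected_model="ADD",
        phase2=res,
        alpha_nominal=alpha,
        alpha_star=alpha,
        reject=bool(res.p_value < alpha),
        rho=None,
        fallback=True,
    )


def tpp_from_grouped(
    g: GroupedTrait,
    alpha: float = 0.05,
    rule: SelectionRule = SelectionRule(),
    ties: Ties = "strict",
) -> TwoPhaseResult:
    """Run the two-phase procedure on already-grouped data."""
    if not (0.0 < alpha < 1.0):
        raise InputError("alpha must be in (0, 1)")
    if min(g.counts) < 2:
        return _fallback_test(g, alpha, ties)
    est = win_prob_estimates(g, ties)
    z1 = _z1_from_estimates(est).statistic
    model = select_model(z1, rule)
    phase2 = _npt_from_estimates(g, est, model)
    rho = _rho_from_estimates(g, est)
    a_star = adjusted_alpha(alpha, rule, rho)
    critical = stats.norm.ppf(1.0 - a_star / 2.0)
    return TwoPhaseResult(
        z1=float(z1),
        selected_model=model,
        phase2=phase2,
        alpha_nominal=alpha,
        alpha_star=a_star,
        reject=bool(abs(phase2.statistic) > critical),
        rho=rho,
    )


def tpp_test(
    traits,
    genotypes,
    alpha: float = 0.05,
    rule: SelectionRule = SelectionRule(),
    ties: Ties = "strict",
) -> TwoPhaseResult:
    """Two-phase association test between a trait and one SNP.

    Step 1 selects the genetic model with Z1; step 2 applies the matched
    trend test at the adjusted level alpha_star derived from the
    estimated (Z1, Zx) null correlation.  ``reject`` is True iff
    |Zx| exceeds the alpha_star-level two-sided normal critical value.
    For a different nominal threshold (e.g. a genome-wide 5e-5), feed it
    through :func:`adjusted_alpha` with this result's ``rho``.
    """
    g = group_by_genotype(traits, genotypes)
    return tpp_from_grouped(g, alpha=alpha, rule=rule, ties=ties)


def adjusted_threshold(
    traits,
    genotypes,
    nominal: float,
    rule: SelectionRule = SelectionRule(),
    ties: Ties = "strict",
) -> float:
    """Per-SNP adjusted p-value threshold for an arbitrary nominal level."""
    g = group_by_genotype(traits, genotypes)
    g.require_min_group_size(2)
    return adjusted_alpha(nominal, rule, estimate_rho(g, ties))


# ---------------------------------------------------------------------------
# covariate adjustment


def residualize(traits, covariates=None) -> np.ndarray:
    """OLS residuals of the trait on [intercept | covariates].

    With no covariates this is mean-centering.  Raises on a rank
    deficiency, naming the first collinear column.
    """
    y = np.asarray(traits, dtype=float)
    if covariates is None or (np.asarray(covariates).size == 0):
        return y - y.mean()
    x = np.atleast_2d(np.asarray(covariates, dtype=float))
    if x.shape[0] != y.size:
        if x.shape[1] == y.size:
            x = x.T
        else:
            raise InputError(
                f"covariate rows ({x.shape[0]}) do not match traits ({y.size})"
            )
    design = np.column_stack([np.ones(y.size), x])
    # detect the first column that adds no rank (collinear with predecessors)
    _, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    scale = diag.max() * max(design.shape) * np.finfo(float).eps
    bad = np.flatnonzero(diag <= scale)
    if bad.size:
        raise InputError(
            f"covariate column {int(bad[0]) - 1} is collinear with the "
            "preceding columns (design not full rank)"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta
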