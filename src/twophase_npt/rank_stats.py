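"""Win-probability estimators and rank-based association statistics.

For a biallelic SNP the ``n`` subjects split into three genotype groups
(minor-allele counts 0, 1, 2) with trait values ``Y0``, ``Y1``, ``Y2``.
All statistics here are built from pairwise *win probabilities*

    f_ab = Pr(Y_a < Y_b),

which equal 1/2 when the two groups share a distribution.  The module
provides

* plug-in estimators of ``f01``, ``f12``, ``f02`` and of their
  variances/covariances (Mann-Whitney two-sample projections),
* the model-selection statistic ``Z1`` contrasting ``f01`` and ``f12``
  (positive leans dominant, negative leans recessive),
* the nonparametric trend test ``ZR`` / ``ZA`` / ``ZD`` optimal under the
  recessive / additive / dominant mode of inheritance,
* the Kruskal-Wallis comparator and MAX3 = max(|ZR|, |ZA|, |ZD|).

All statistics depend on the data only through within-pair rank
indicators, so they are invariant under strictly increasing transforms
of the trait.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

Model = Literal["REC", "ADD", "DOM"]
MODELS: tuple[Model, ...] = ("REC", "ADD", "DOM")

#: denominators below this are treated as degenerate, never divided through
_EPS = 1e-12


class InputError(ValueError):
    """Malformed input: mismatched lengths, bad genotype codes, empty groups."""


class DegenerateStatisticError(ValueError):
    """A variance plug-in is numerically zero/undefined for this sample."""


# ---------------------------------------------------------------------------
# grouped data container


@dataclass(frozen=True)
class GroupedTrait:
    """Trait values partitioned by genotype (minor-allele count 0/1/2).

    Within-group order is irrelevant to every downstream statistic.
    """

    values0: np.ndarray
    values1: np.ndarray
    values2: np.ndarray

    @property
    def n0(self) -> int:
        return self.values0.size

    @property
    def n1(self) -> int:
        return self.values1.size

    @property
    def n2(self) -> int:
        return self.values2.size

    @property
    def n(self) -> int:
        return self.n0 + self.n1 + self.n2

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n0, self.n1, self.n2)

    def groups(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.values0, self.values1, self.values2)

    def require_min_group_size(self, k: int) -> None:
        if min(self.counts) < k:
            raise DegenerateStatisticError(
                f"each genotype group must have at least {k} subjects; "
                f"got counts {self.counts}"
            )


def group_by_genotype(traits, genotypes) -> GroupedTrait:
    """Partition trait values by genotype code 0/1/2.

    Raises :class:`InputError` on length mismatch or a genotype outside
    {0, 1, 2}, naming the offending index.
    """
    y = np.asarray(traits, dtype=float)
    g = np.asarray(genotypes)
    if y.ndim != 1 or g.ndim != 1 or y.size != g.size:
        raise InputError(
            f"traits and genotypes must be 1-d of equal length; "
            f"got {y.size} traits and {g.size} genotypes"
        )
    valid = np.isin(g, (0, 1, 2))
    if not valid.all():
        idx = int(np.flatnonzero(~valid)[0])
        raise InputError(
            f"genotype outside {{0,1,2}} at index {idx}: {g[idx]!r}"
        )
    if y.size < 3:
        raise InputError("need at least 3 subjects")
    gi = g.astype(int)
    return GroupedTrait(y[gi == 0], y[gi == 1], y[gi == 2])


# ---------------------------------------------------------------------------
# win probabilities and their variance/covariance plug-ins

Ties = Literal["strict", "midrank"]


def _pair_fractions(a, b, ties: Ties = "strict"):
    """Per-element comparison fractions between two groups.

    Returns ``(p, q)`` with ``p[i]`` the fraction of ``b`` exceeding
    ``a[i]`` and ``q[j]`` the fraction of ``a`` below ``b[j]``.  With
    ``ties="midrank"`` equal values count 1/2.  O((na+nb) log) via sorting.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("empty genotype group")
    a_sorted = np.sort(a)
    b_sorted = np.sort(b)
    if ties == "strict":
        p = (b.size - np.searchsorted(b_sorted, a, side="right")) / b.size
        q = np.searchsorted(a_sorted, b, side="left") / a.size
    elif ties == "midrank":
        hi = np.searchsorted(b_sorted, a, side="right")
        lo = np.searchsorted(b_sorted, a, side="left")
        p = (b.size - 0.5 * (hi + lo)) / b.size
        hi = np.searchsorted(a_sorted, b, side="right")
        lo = np.searchsorted(a_sorted, b, side="left")
        q = 0.5 * (hi + lo) / a.size
    else:  # pragma: no cover - guarded by Literal typing
        raise InputError(f"unknown ties mode {ties!r}")
    return p, q


def win_prob(a, b, ties: Ties = "strict") -> float:
    """Estimate Pr(A < B): the fraction of pairs (a_i, b_j) with a_i < b_j.

    Strict inequality by default (ties contribute 0); ``ties="midrank"``
    scores ties as 1/2.
    """
    _, q = _pair_fractions(a, b, ties)
    return float(q.mean())


def win_prob_variance(a, b, ties: Ties = "strict") -> float:
    """Plug-in variance of the win probability estimator.

    Two projection sums-of-squares plus the constant 1/(4 na nb); always
    strictly positive.  Requires both groups of size >= 2 (the (n-1)
    prefactors vanish otherwise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("variance undefined for group of size < 2")
    na, nb = a.size, b.size
    p, q = _pair_fractions(a, b, ties)
    term_a = (nb - 1) / (na**2 * nb) * np.sum((p - 0.5) ** 2)
    term_b = (na - 1) / (na * nb**2) * np.sum((q - 0.5) ** 2)
    return float(term_a + term_b + 1.0 / (4 * na * nb))


_TOPOLOGIES = ("shared-middle-01-12", "shared-right-02-12", "shared-left-01-02")


def win_prob_cov(left, shared, right, topology: str, ties: Ties = "strict") -> float:
    """Plug-in covariance of two win probabilities sharing one group.

    The average, over the shared group, of the product of the two
    centered opposite-group comparison fractions:

    * ``"shared-middle-01-12"`` — cov(f(left, shared), f(shared, right));
      the shared group sits on the large side of one probability and the
      small side of the other (as for f01 and f12 sharing group 1).
    * ``"shared-right-02-12"`` — cov(f(left, shared), f(right, shared));
      both probabilities point into the shared group (f02 and f12
      sharing group 2).
    * ``"shared-left-01-02"`` — cov(f(shared, left), f(shared, right));
      both probabilities point out of the shared group (f01 and f02
      sharing group 0).
    """
    s = np.asarray(shared, dtype=float)
    ns = s.size
    if ns == 0:
        raise InputError("empty genotype group")
    if topology == "shared-middle-01-12":
        _, q = _pair_fractions(left, s, ties)   # fraction of `left` below each s
        p, _ = _pair_fractions(s, right, ties)  # fraction of `right` above each s
        return float(np.sum((q - 0.5) * (p - 0.5)) / ns**2)
    if topology == "shared-right-02-12":
        _, qa = _pair_fractions(left, s, ties)
        _, qb = _pair_fractions(right, s, ties)
        return float(np.sum((qa - 0.5) * (qb - 0.5)) / ns**2)
    if topology == "shared-left-01-02":
        pa, _ = _pair_fractions(s, left, ties)
        pb, _ = _pair_fractions(s, right, ties)
        return float(np.sum((pa - 0.5) * (pb - 0.5)) / ns**2)
    raise InputError(f"unknown topology {topology!r}; expected one of {_TOPOLOGIES}")


@dataclass(frozen=True)
class WinProbEstimates:
    """The three win probabilities and their variance/covariance plug-ins."""

    f01: float
    f12: float
    f02: float
    var01: float
    var12: float
    var02: float
    cov01_12: float
    cov02_12: float
    cov01_02: float

    def cov_matrix(self) -> np.ndarray:
        """Plug-in 3x3 covariance of (f01, f12, f02), in that order."""
        return np.array(
            [
                [self.var01, self.cov01_12, self.cov01_02],
                [self.cov01_12, self.var12, self.cov02_12],
                [self.cov01_02, self.cov02_12, self.var02],
            ]
        )


def win_prob_estimates(g: GroupedTrait, ties: Ties = "strict") -> WinProbEstimates:
    """All nine win-probability plug-ins for a three-group sample.

    Requires every genotype group of size >= 2.
    """
    g.require_min_group_size(2)
    y0, y1, y2 = g.groups()
    return WinProbEstimates(
        f01=win_prob(y0, y1, ties),
        f12=win_prob(y1, y2, ties),
        f02=win_prob(y0, y2, ties),
        var01=win_prob_variance(y0, y1, ties),
        var12=win_prob_variance(y1, y2, ties),
        var02=win_prob_variance(y0, y2, ties),
        cov01_12=win_prob_cov(y0, y1, y2, "shared-middle-01-12", ties),
        cov02_12=win_prob_cov(y0, y2, y1, "shared-right-02-12", ties),
        cov01_02=win_prob_cov(y1, y0, y2, "shared-left-01-02", ties),
    )


# ---------------------------------------------------------------------------
# test statistics


@dataclass(frozen=True)
class TestResult:
    """A statistic, its asymptotic reference law, and a two-sided p-value."""

    statistic: float
    reference: str
    p_value: float
    label: str


def _normal_result(z: float, label: str) -> TestResult:
    return TestResult(
        statistic=float(z),
        reference="standard-normal",
        p_value=float(2.0 * stats.norm.sf(abs(z))),
        label=label,
    )


def z1_statistic(g: GroupedTrait, ties: Ties = "strict") -> TestResult:
    """Model-selection statistic Z1 = (f01 - f12) / se(f01 - f12).

    Asymptotically N(0, 1) under no association.  Tends negative under a
    recessive and positive under a dominant mode of inheritance.
    """
    est = win_prob_estimates(g, ties)
    return _z1_from_estimates(est)


def _z1_from_estimates(est: WinProbEstimates) -> TestResult:
    denom = est.var01 - 2.0 * est.cov01_12 + est.var12
    if denom <= _EPS:
        raise DegenerateStatisticError("degenerate variance")
    return _normal_result((est.f01 - est.f12) / np.sqrt(denom), "Z1")


def _additive_weights(g: GroupedTrait, est: WinProbEstimates) -> tuple[float, float]:
    """Inverse-standard-error weights (w1, w2) for the additive trend test."""
    if est.var01 <= _EPS or est.var12 <= _EPS:
        raise DegenerateStatisticError("degenerate variance")
    n0, n1, n2 = g.counts
    n = g.n
    w1s = np.sqrt((n0 + n1) / ((n + n1) * est.var01))
    w2s = np.sqrt((n1 + n2) / ((n + n1) * est.var12))
    return float(w1s / (w1s + w2s)), float(w2s / (w1s + w2s))


def numerator_weights(g: GroupedTrait, est: WinProbEstimates, model: Model) -> np.ndarray:
    """Weights b with statistic numerator b . (f01, f12, f02) - 1/2."""
    n0, n1, n2 = g.counts
    if model == "REC":
        return np.array([0.0, n1 / (n0 + n1), n0 / (n0 + n1)])
    if model == "ADD":
        w1, w2 = _additive_weights(g, est)
        return np.array([w1, w2, 0.0])
    if model == "DOM":
        return np.array([n1 / (n1 + n2), 0.0, n2 / (n1 + n2)])
    raise InputError(f"unknown genetic model {model!r}; expected one of {MODELS}")


def _npt_from_estimates(g: GroupedTrait, est: WinProbEstimates, model: Model) -> TestResult:
    b = numerator_weights(g, est, model)
    sigma = est.cov_matrix()
    var = float(b @ sigma @ b)
    if var <= _EPS:
        raise DegenerateStatisticError("degenerate variance")
    f_model = float(b @ (est.f01, est.f12, est.f02))
    return _normal_result((f_model - 0.5) / np.sqrt(var), f"Z{model[0]}")


def npt_statistic(g: GroupedTrait, model: Model, ties: Ties = "strict") -> TestResult:
    """Nonparametric trend test under a given genetic model.

    REC pools groups {0,1} against group 2, DOM pools {1,2} against
    group 0, and ADD combines f01 and f12 with inverse-standard-error
    weights; each is ``(f_model - 1/2) / se`` with the matching plug-in
    variance, standard normal under the null.
    """
    est = win_prob_estimates(g, ties)
    return _npt_from_estimates(g, est, model)


def kruskal_wallis(g: GroupedTrait) -> TestResult:
    """Kruskal-Wallis rank test across the nonempty genotype groups.

    Midrank H with tie correction, chi-squared reference with
    (number of nonempty groups - 1) degrees of freedom.
    """
    groups = [v for v in g.groups() if v.size > 0]
    if g.n < 3 or len(groups) < 2:
        raise InputError("need at least 3 subjects in at least 2 genotype groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise InputError("all observations tied")
    h, p = stats.kruskal(*groups)
    df = len(groups) - 1
    return TestResult(float(h), f"chi-squared(df={df})", float(p), "KW")


# --- MAX3 -------------------------------------------------------------------


def _phase2_correlations(g: GroupedTrait, est: WinProbEstimates) -> np.ndarray:
    """Delta-method correlation matrix of (ZR, ZA, ZD).

    Each statistic's numerator is linear in (f01, f12, f02); the
    plug-in covariance of those three estimates propagates through the
    weight vectors.
    """
    sigma = est.cov_matrix()
    bs = [numerator_weights(g, est, m) for m in MODELS]
    variances = np.array([b @ sigma @ b for b in bs])
    if np.any(variances <= _EPS):
        raise DegenerateStatisticError("degenerate variance")
    corr = np.eye(3)
    for i in range(3):
        for j in range(i + 1, 3):
            r = (bs[i] @ sigma @ bs[j]) / np.sqrt(variances[i] * variances[j])
            corr[i, j] = corr[j, i] = float(np.clip(r, -1.0, 1.0))
    return corr


def _mvn3_box_prob(t: float, corr: np.ndarray, n_nodes: int = 48) -> float:
    """P(|Z1|<=t, |Z2|<=t, |Z3|<=t) for a centered trivariate normal.

    Deterministic tensor Gauss-Legendre quadrature over the first two
    coordinates with the third integrated in closed form conditionally.
    """
    if t <= 0:
        return 0.0
    r12, r13, r23 = corr[0, 1], corr[0, 2], corr[1, 2]
    det2 = 1.0 - r12**2
    if det2 < 1e-12:
        # Z2 is (anti)collinear with Z1: drop to a bivariate box on (Z1, Z3)
        return _mvn2_box_prob(t, r13, n_nodes=4 * n_nodes)
    # conditional Z3 | (Z1, Z2): regression coefficients and residual var
    beta = np.linalg.solve(np.array([[1.0, r12], [r12, 1.0]]), np.array([r13, r23]))
    var3 = 1.0 - np.array([r13, r23]) @ beta
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    u = t * nodes  # map [-1,1] -> [-t,t]
    wu = t * weights
    uu, vv = np.meshgrid(u, u, indexing="ij")
    # bivariate normal density of (Z1, Z2)
    dens = np.exp(-(uu**2 - 2 * r12 * uu * vv + vv**2) / (2 * det2)) / (
        2 * np.pi * np.sqrt(det2)
    )
    mean3 = beta[0] * uu + beta[1] * vv
    if var3 <= 1e-14:
        inner = (np.abs(mean3) <= t).astype(float)
    else:
        s3 = np.sqrt(var3)
        inner = stats.norm.cdf((t - mean3) / s3) - stats.norm.cdf((-t - mean3) / s3)
    return float(np.clip(wu @ (dens * inner) @ wu, 0.0, 1.0))


def _mvn2_box_prob(t: float, r: float, n_nodes: int = 192) -> float:
    """P(|Z1|<=t, |Z2|<=t) for a centered bivariate normal."""
    det = 1.0 - r**2
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    u = t * nodes
    wu = t * weights
    dens = stats.norm.pdf(u)
    if det < 1e-12:
        return float(np.clip(wu @ dens, 0.0, 1.0))
    s = np.sqrt(det)
    inner = stats.norm.cdf((t - r * u) / s) - stats.norm.cdf((-t - r * u) / s)
    return float(np.clip(wu @ (dens * inner), 0.0, 1.0))


def max3(
    g: GroupedTrait,
    null_method: Literal["trivariate-normal", "permutation"] = "trivariate-normal",
    draws: int = 10_000,
    seed: int | None = None,
    ties: Ties = "strict",
) -> TestResult:
    """MAX3 = max(|ZR|, |ZA|, |ZD|), robust to the unknown genetic model.

    The p-value comes either from the asymptotic trivariate normal of the
    three trend statistics (pairwise correlations by the delta method)
    or from permutation of the genotype labels (``draws`` permutations,
    deterministic given ``seed``).
    """
    est = win_prob_estimates(g, ties)
    zs = [_npt_from_estimates(g, est, m).statistic for m in MODELS]
    t = float(np.max(np.abs(zs)))
    if null_method == "trivariate-normal":
        corr = _phase2_correlations(g, est)
        p = 1.0 - _mvn3_box_prob(t, corr)
        return TestResult(t, "max3-null", float(np.clip(p, 0.0, 1.0)), "MAX3")
    if null_method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate(g.groups())
        n0, n1 = g.n0, g.n1
        exceed = 0
        for _ in range(draws):
            perm = pooled[rng.permutation(pooled.size)]
            gp = GroupedTrait(perm[:n0], perm[n0 : n0 + n1], perm[n0 + n1 :])
            est_p = win_prob_estimates(gp, ties)
            zp = [_npt_from_estimates(gp, est_p, m).statistic for m in MODELS]
            if np.max(np.abs(zp)) >= t - 1e-12:
                exceed += 1
        p = (1 + exceed) / (draws + 1)
        return TestResult(t, "max3-null", float(p), "MAX3")
    raise InputError(f"unknown null_method {null_method!r}")
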