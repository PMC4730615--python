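"""Synthetic cohorts and the Monte Carlo experiment drivers.

The generator reproduces the statistical structure used throughout the
package's validation: Hardy-Weinberg genotypes at a given minor allele
frequency and a linear trait model

    Y = beta0 + score(G; model) * beta1 + eps,

with model-specific genotype scoring REC (0,0,2) / ADD (0,1,2) /
DOM (0,2,2) — the two-homozygote contrast equals 2*beta1 under every
model — and a heavy-tailed error ``eps`` drawn from a generalized
extreme value law with shape 0 (a Gumbel), scale ``d``, left-truncated
at 0, as arises for survival-time-like traits.  Centered-t and
untruncated GEV errors are available as variants.

Experiment drivers estimate, over seeded replicates: the true selection
rate of the phase-1 classifier (TSR), the distribution of the adjusted
level alpha_star, empirical type I error, and empirical power, each as
a tidy DataFrame.  A master seed spawns independent per-cell
substreams, so every table is reproducible and cells are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rank_stats import (
    GroupedTrait,
    InputError,
    _npt_from_estimates,
    _z1_from_estimates,
    group_by_genotype,
    kruskal_wallis,
    max3,
    win_prob_estimates,
)
from .two_phase import (
    DEFAULT_XI,
    SelectionRule,
    _rho_from_estimates,
    adjusted_alpha,
    select_model,
    tpp_from_grouped,
)

#: genotype -> trait shift multiplier of beta1 under each mode of inheritance
GENOTYPE_SCORES: dict[str, tuple[float, float, float]] = {
    "REC": (0.0, 0.0, 2.0),
    "ADD": (0.0, 1.0, 2.0),
    "DOM": (0.0, 2.0, 2.0),
    "NULL": (0.0, 0.0, 0.0),
}

TESTS = ("KW", "ZR", "ZA", "MAX3", "TPP")


@dataclass(frozen=True)
class ErrorLaw:
    """Error distribution for the trait model.

    family "tgev": GEV(shape, location, scale) conditioned on exceeding
    ``truncation`` (left truncation; shape 0 is a truncated Gumbel).
    family "gev": the untruncated law.  family "t": a central Student t
    with ``df`` degrees of freedom times ``scale``.
    """

    family: Literal["tgev", "gev", "t"] = "tgev"
    shape: float = 0.0
    location: float = 0.0
    scale: float = 5.0
    truncation: float = 0.0
    df: float = 3.0

    def __post_init__(self):
        if not (self.scale > 0):
            raise InputError("scale must be positive")

    def _gev(self):
        # scipy's genextreme uses c = -shape relative to the usual
        # xi-parameterisation; shape 0 is the Gumbel
        if self.shape == 0.0:
            return stats.gumbel_r(loc=self.location, scale=self.scale)
        return stats.genextreme(c=-self.shape, loc=self.location, scale=self.scale)


def sample_truncated_gev(law: ErrorLaw, count: int, seed) -> np.ndarray:
    """Draws from a GEV left-truncated at ``law.truncation``.

    Inverse-CDF on a uniform restricted to [F(t), 1); deterministic
    given the seed (an int or a numpy Generator).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dist = law._gev()
    f_t = float(dist.cdf(law.truncation))
    if 1.0 - f_t < 1e-12:
        raise InputError("empty truncation region")
    u = f_t + rng.random(count) * (1.0 - f_t)
    return np.asarray(dist.ppf(u), dtype=float)


def sample_error(law: ErrorLaw, count: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``count`` iid errors from the configured law."""
    if law.family == "tgev":
        return sample_truncated_gev(law, count, rng)
    if law.family == "gev":
        return np.asarray(law._gev().ppf(rng.random(count)), dtype=float)
    if law.family == "t":
        return law.scale * np.asarray(stats.t(df=law.df).ppf(rng.random(count)), dtype=float)
    raise InputError(f"unknown error family {law.family!r}")


def simulate_genotypes(n: int, maf: float, seed) -> np.ndarray:
    """Hardy-Weinberg genotypes: minor-allele counts Binomial(2, maf)."""
    if not (0.0 < maf <= 0.5):
        raise InputError("maf must be in (0, 0.5]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.binomial(2, maf, size=n)


def simulate_trait(
    genotypes,
    model: str,
    beta0: float,
    beta1: float,
    error: ErrorLaw,
    seed,
    scores: dict[str, tuple[float, float, float]] | None = None,
) -> np.ndarray:
    """Trait values Y = beta0 + score(g)*beta1 + eps under a genetic model."""
    g = np.asarray(genotypes, dtype=int)
    table = (scores or GENOTYPE_SCORES).get(model)
    if table is None:
        raise InputError(f"unknown genetic model {model!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    eps = sample_error(error, g.size, rng)
    return beta0 + np.asarray(table)[g] * beta1 + eps


@dataclass(frozen=True)
class SimulationSpec:
    """One simulation cell: design parameters, replicate count and seed."""

    n: int = 1500
    maf: float = 0.30
    beta0: float = 0.50
    beta1: float = 0.50
    model: str = "ADD"
    error: ErrorLaw = field(default_factory=ErrorLaw)
    replicates: int = 2000
    seed: int = 0
    xi: float = DEFAULT_XI
    alpha: float = 0.05

    @property
    def effective_beta1(self) -> float:
        return 0.0 if self.model == "NULL" else self.beta1

    @property
    def rule(self) -> SelectionRule:
        return SelectionRule(xi=self.xi)


def simulate_dataset(spec: SimulationSpec, rng: np.random.Generator):
    """One (traits, genotypes) draw from the cell's design."""
    g = simulate_genotypes(spec.n, spec.maf, rng)
    y = simulate_trait(g, spec.model, spec.beta0, spec.effective_beta1, spec.error, rng)
    return y, g


def _cell_rngs(master_seed: int, n_cells: int) -> list[np.random.Generator]:
    """Independent per-cell generators spawned from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(n_cells)
    return [np.random.default_rng(s) for s in children]


# ---------------------------------------------------------------------------
# experiment drivers


def experiment_tsr(
    mafs: Sequence[float],
    models: Sequence[str] = ("REC", "ADD", "DOM"),
    n: int = 1500,
    beta0: float = 0.50,
    beta1: float = 0.50,
    error: ErrorLaw = ErrorLaw(),
    replicates: int = 10_000,
    seed: int = 0,
    xi: float = DEFAULT_XI,
) -> pd.DataFrame:
    """Phase-1 true selection rates per (true model, MAF).

    Replicates where a homozygote group has fewer than two subjects are
    counted under ``fallback`` and excluded from the three selection
    columns, whose denominators shrink accordingly; the selection
    columns plus fallback then sum to 1.
    """
    cells = [(m, p) for m in models for p in mafs]
    rngs = _cell_rngs(seed, len(cells))
    rule = SelectionRule(xi=xi)
    rows = []
    for (model, maf), rng in zip(cells, rngs):
        spec = SimulationSpec(
            n=n, maf=maf, beta0=beta0, beta1=beta1, model=model,
            error=error, replicates=replicates, seed=seed, xi=xi,
        )
        counts = {"REC": 0, "ADD": 0, "DOM": 0}
        fallback = 0
        for _ in range(replicates):
            y, g = simulate_dataset(spec, rng)
            grouped = group_by_genotype(y, g)
            if min(grouped.counts) < 2:
                fallback += 1
                continue
            z1 = _z1_from_estimates(win_prob_estimates(grouped)).statistic
            counts[select_model(z1, rule)] += 1
        rows.append(
            {
                "true_model": model,
                "maf": maf,
                "select_REC": counts["REC"] / replicates,
                "select_ADD": counts["ADD"] / replicates,
                "select_DOM": counts["DOM"] / replicates,
                "fallback": fallback / replicates,
                "replicates": replicates,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)


def experiment_alpha_star(
    mafs: Sequence[float],
    alpha: float = 0.05,
    n: int = 1500,
    beta0: float = 0.50,
    error: ErrorLaw = ErrorLaw(),
    replicates: int = 2000,
    seed: int = 0,
    xi: float = DEFAULT_XI,
) -> pd.DataFrame:
    """Mean and SD of the adjusted level alpha_star under the null.

    Each replicate estimates the (Z1, Zx) correlations from its own
    null data and solves the size-adjustment equation.
    """
    rngs = _cell_rngs(seed, len(mafs))
    rule = SelectionRule(xi=xi)
    rows = []
    for maf, rng in zip(mafs, rngs):
        spec = SimulationSpec(
            n=n, maf=maf, beta0=beta0, model="NULL", error=error,
            replicates=replicates, seed=seed, xi=xi, alpha=alpha,
        )
        values = []
        fallback = 0
        for _ in range(replicates):
            y, g = simulate_dataset(spec, rng)
            grouped = group_by_genotype(y, g)
            if min(grouped.counts) < 2:
                fallback += 1
                continue
            rho = _rho_from_estimates(grouped, win_prob_estimates(grouped))
            values.append(adjusted_alpha(alpha, rule, rho))
        arr = np.asarray(values)
        rows.append(
            {
                "maf": maf,
                "alpha": alpha,
                "mean_alpha_star": float(arr.mean()),
                "sd_alpha_star": float(arr.std(ddof=1)),
                "fallback": fallback / replicates,
                "replicates": replicates,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)


def _replicate_rejections(
    grouped: GroupedTrait,
    tests: Iterable[str],
    alpha: float,
    rule: SelectionRule,
    rng: np.random.Generator,
) -> dict[str, bool | None]:
    """Rejection indicators for one replicate; None when not computable."""
    out: dict[str, bool | None] = {}
    degenerate = min(grouped.counts) < 2
    est = None if degenerate else win_prob_estimates(grouped)
    for test in tests:
        if test == "TPP":
            out[test] = tpp_from_grouped(grouped, alpha=alpha, rule=rule).reject
        elif test == "KW":
            out[test] = kruskal_wallis(grouped).p_value < alpha
        elif test in ("ZR", "ZA", "ZD"):
            model = {"ZR": "REC", "ZA": "ADD", "ZD": "DOM"}[test]
            out[test] = (
                None
                if degenerate
                else _npt_from_estimates(grouped, est, model).p_value < alpha
            )
        elif test == "MAX3":
            out[test] = (
                None
                if degenerate
                else max3(grouped, "trivariate-normal").p_value < alpha
            )
        else:
            raise InputError(f"unknown test {test!r}; expected subset of {TESTS}")
    return out


def _rejection_grid(
    cells: Sequence[SimulationSpec],
    tests: Sequence[str],
    seed: int,
) -> pd.DataFrame:
    rngs = _cell_rngs(seed, len(cells))
    rows = []
    for spec, rng in zip(cells, rngs):
        tally = {t: 0 for t in tests}
        evaluable = {t: 0 for t in tests}
        for _ in range(spec.replicates):
            y, g = simulate_dataset(spec, rng)
            grouped = group_by_genotype(y, g)
            rej = _replicate_rejections(grouped, tests, spec.alpha, spec.rule, rng)
            for t in tests:
                if rej[t] is not None:
                    evaluable[t] += 1
                    tally[t] += bool(rej[t])
        for t in tests:
            rows.append(
                {
                    "model": spec.model,
                    "maf": spec.maf,
                    "beta1": spec.effective_beta1,
                    "alpha": spec.alpha,
                    "test": t,
                    "rejection_rate": tally[t] / max(evaluable[t], 1),
                    "evaluable": evaluable[t],
                    "replicates": spec.replicates,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


def experiment_type1(
    mafs: Sequence[float],
    tests: Sequence[str] = TESTS,
    alpha: float = 0.05,
    n: int = 1500,
    beta0: float = 0.50,
    error: ErrorLaw = ErrorLaw(),
    replicates: int = 2000,
    seed: int = 0,
    xi: float = DEFAULT_XI,
) -> pd.DataFrame:
    """Empirical type I error of the requested tests under the null."""
    cells = [
        SimulationSpec(
            n=n, maf=maf, beta0=beta0, model="NULL", error=error,
            replicates=replicates, seed=seed, xi=xi, alpha=alpha,
        )
        for maf in mafs
    ]
    return _rejection_grid(cells, tests, seed)


def experiment_power(
    mafs: Sequence[float],
    models: Sequence[str] = ("REC", "ADD", "DOM"),
    tests: Sequence[str] = TESTS,
    alpha: float = 0.05,
    n: int = 1500,
    beta0: float = 0.50,
    beta1: float = 0.50,
    error: ErrorLaw = ErrorLaw(),
    replicates: int = 2000,
    seed: int = 0,
    xi: float = DEFAULT_XI,
) -> pd.DataFrame:
    """Empirical power of the requested tests over a (model, MAF) grid."""
    cells = [
        SimulationSpec(
            n=n, maf=maf, beta0=beta0, beta1=beta1, model=model, error=error,
            replicates=replicates, seed=seed, xi=xi, alpha=alpha,
        )
        for model in models
        for maf in mafs
    ]
    return _rejection_grid(cells, tests, seed)


def min_power_summary(power_table: pd.DataFrame) -> pd.DataFrame:
    """Minimum power over the (model, MAF) grid per test — the robustness
    figure of merit for a procedure facing an unknown genetic model."""
    out = (
        power_table.groupby("test")["rejection_rate"]
        .min()
        .rename("min_power")
        .reset_index()
    )
    return out
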