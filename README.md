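# twophase-npt

Rank-based association testing between a biallelic SNP and a
quantitative trait that is **not** normally distributed — tumor counts,
survival-like times, antibody titers, anything heavy-tailed or
truncated where a linear-model F test is miscalibrated and a
log-transform does not rescue it.

## The problem and the method

Code the genotype as the minor-allele count g ∈ {0, 1, 2} and write
f_ab = Pr(Y_a < Y_b) for the probability that a random trait value from
genotype group *a* falls below one from group *b*.  Under no
association f_01 = f_02 = 1/2.  The mode of inheritance determines
where the signal sits:

* **recessive** — f_01 = 1/2, f_12 = f_02 > 1/2 (only two copies matter),
* **additive**  — f_01 = f_12 > 1/2 (each copy shifts the trait),
* **dominant**  — f_01 = f_02 > 1/2, f_12 = 1/2 (one copy is enough).

For each model there is an optimal nonparametric trend test (NPT):
Z_R, Z_A, Z_D, each of the form (f̂ − 1/2)/σ̂ built from Mann–Whitney
win-probability estimates and their projection variance plug-ins, and
each asymptotically N(0, 1) under the null.  Picking the wrong one
costs real power (the additive test has little power against a
recessive truth).  When the model is unknown, this package runs the
**two-phase procedure (TPP)**:

1. **Select** the model with Z₁ = (f̂_01 − f̂_12)/ŝe: dominant if
   Z₁ > ξ, recessive if Z₁ < −ξ, additive otherwise
   (ξ = Φ⁻¹(0.90) ≈ 1.2816 by default).
2. **Test** with the matching NPT — but at an *adjusted* level α*,
   solved from the bivariate-normal joint law of (Z₁, Z_x) with
   estimated correlation ρ_x, so the overall type I error stays at the
   nominal α.  α* is strictly below α in practice (≈ 0.031 for
   α = 0.05 at MAF 0.25).

Kruskal–Wallis and MAX3 = max(|Z_R|, |Z_A|, |Z_D|) are included as
comparators, and a seeded Monte Carlo suite estimates selection rates,
α*, empirical size and power.  In simulations with heavy-tailed errors
the TPP's minimum power across plausible inheritance models beats KW,
MAX3 and every single-model NPT.

## Worked example

```python
import numpy as np
from twophase_npt import (ErrorLaw, simulate_genotypes, simulate_trait, tpp_test)

rng = np.random.default_rng(42)
genotypes = simulate_genotypes(1500, maf=0.30, seed=rng)
traits = simulate_trait(genotypes, "REC", beta0=0.5, beta1=0.5,
                        error=ErrorLaw(scale=5.0), seed=rng)
result = tpp_test(traits, genotypes, alpha=0.05)
```

Running `python examples/single_snp_test.py` (which is exactly this
cohort) prints:

```
phase 1: Z1 = -2.671  ->  selected model: REC
phase 2: ZR = +2.584  (p = 9.77e-03)
adjusted level alpha* = 0.0300  (nominal 0.05)  ->  reject: True
comparators: KW p = 2.97e-02,  MAX3 p = 2.24e-02
```

Z₁ is well below −ξ, so phase 1 correctly calls the recessive model;
the recessive trend test's p-value (0.0098) is compared against
α* = 0.0300 — not 0.05 — and the association is declared.  The other
`examples/*.py` scripts each demonstrate one capability (selection
rates, size adjustment, power comparison, file-based cohorts), and the
`twophase-npt` command exposes the same paths from the shell
(`test`, `simulate`, `experiment`, `threshold`).

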