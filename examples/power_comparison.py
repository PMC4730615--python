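"""Power of TPP against its comparators under a recessive truth.

Reproduces (at reduced replicates) the headline comparison: when the
trait is heavy-tailed and the minor allele acts recessively, the
two-phase procedure beats Kruskal-Wallis, the misspecified additive
trend test, and MAX3.
"""

from twophase_npt import experiment_power, min_power_summary

table = experiment_power(
    mafs=[0.20],
    models=["REC"],
    tests=["KW", "ZA", "MAX3", "TPP"],
    alpha=0.05,
    replicates=500,
    seed=2,
)
print(table[["test", "rejection_rate"]].to_string(index=False))
print()
print(min_power_summary(table).to_string(index=False))

# Expected ordering at this design (n=1500, beta1=0.5, Gumbel scale 5,
# left-truncated at 0): TPP ~0.47 > MAX3 ~0.42 > KW ~0.34 > ZA ~0.20.
# ZA suffers because it weights the heterozygote contrast that carries
# no recessive signal; TPP recovers most of the oracle recessive test's
# power by usually selecting the right model in phase 1.
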