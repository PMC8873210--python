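"""Combine one vector of p-values with every test in the package.

The vector mixes one strong signal (0.004) with mid-range noise.  CCT and
MinP respond to the smallest p-value; Fisher and Stouffer pool evidence
across all of them and assume independence.  Note that no combined
p-value from CCT/MinP/MCM/CMC can drop below the smallest input.
"""

from pvcomb import combine_all

pvalues = [0.004, 0.12, 0.35, 0.60, 0.83]

print(f"input p-values: {pvalues}\n")
for res in combine_all(pvalues, minp_mode="sidak"):
    stat = f"{res.statistic:8.4f}" if res.statistic is not None else "       -"
    print(f"{res.method:>9s}  statistic={stat}  combined p = {res.pvalue:.5f}")

print(
    "\nMCM = 2*min{p_CCT, p_MinP, 1/2} and CMC = CCT{p_CCT, p_MinP} hedge"
    "\nbetween the Cauchy and minimum-p tests; both remain valid under"
    "\narbitrary dependence at small significance levels."
)
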