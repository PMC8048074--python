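"""Paired tissue validation and clinicopathological association tests.

Matched tumor/normal methylation calls are compared with the exact
McNemar test. When only the marginal frequencies are known (the pairing
is unpublished), the worst-case bound maximizes the McNemar p over every
pairing consistent with those marginals — if even the bound is tiny, the
difference is significant regardless of pairing. Categorical covariates
use Pearson's chi-square, continuous ones a t test.
"""

import numpy as np

from methmark import (
    PairedStatusTable,
    contingency_association,
    group_location_tests,
    mcnemar_exact,
    worst_case_mcnemar_from_marginals,
)

# 34 matched pairs: tumor highly methylated, normal rarely
table = PairedStatusTable(a=1, b=25, c=2, d=6)
print(f"exact McNemar p on discordant pairs (b=25, c=2): {mcnemar_exact(table):.2e}")

# only the marginals known: 26/34 tumors positive, 1/34 normals positive
p_max = worst_case_mcnemar_from_marginals(26, 1, 34)
print(f"worst-case p over all pairings with those marginals: {p_max:.2e}")
print("  -> significant at p < 1e-4 no matter how the pairs line up\n")

# methylation status vs tumor stage (counts per stage II/III/IV)
chi2, p = contingency_association([[6, 8, 4], [1, 16, 6]], mode="pearson_chi2")
print(f"methylation x stage: chi-square = {chi2:.2f}, p = {p:.3f}")

# age in methylated vs unmethylated cases
rng = np.random.default_rng(0)
age = np.concatenate([rng.normal(70, 9, 19), rng.normal(71, 12, 23)])
status = np.array([1] * 19 + [0] * 23)
print(f"age vs methylation status: t-test p = {group_location_tests(age, status):.3f}")
# Large McNemar discordance with tiny p says tumor and normal calls differ
# systematically; the chi-square asks whether positivity tracks stage.
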