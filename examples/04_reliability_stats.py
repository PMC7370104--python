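"""Reliability statistics for repeated volumetric readings.

Simulates two operators reading each condyle twice, then runs the
paired Wilcoxon signed-rank test and the intraclass correlation
coefficients: ICC(3,1) consistency for test-retest of one operator,
ICC(2,1) absolute agreement between operators.
"""

import numpy as np

from condylometry import icc, make_rating_table, wilcoxon_signed_rank

rng = np.random.default_rng(0)
true_volumes = rng.normal(1631.0, 120.0, size=20)  # 20 condyles

table = make_rating_table(
    n_condyles=20,
    true_volumes=true_volumes,
    rater_bias=np.array([0.0, 65.0]),  # second operator reads ~65 mm^3 high
    within_rater_sd=9.0,
    between_rater_sd=0.0,
    occasion_bias=np.array([0.0, -7.0]),  # slight drift at re-reading
    seed=11,
)

first = table[(table.rater == 1) & (table.occasion == 1)].sort_values(
    "condyle")["value"].to_numpy()
retest = table[(table.rater == 1) & (table.occasion == 2)].sort_values(
    "condyle")["value"].to_numpy()
other = table[(table.rater == 2) & (table.occasion == 1)].sort_values(
    "condyle")["value"].to_numpy()

intra = icc(table, "intra")
inter = icc(table, "inter")
w_intra = wilcoxon_signed_rank(first, retest)
w_inter = wilcoxon_signed_rank(first, other)

print(f"median first reading  : {np.median(first):7.1f} mm^3")
print(f"median re-reading     : {np.median(retest):7.1f} mm^3 "
      f"(Wilcoxon p = {w_intra.p_value:.4f})")
print(f"median second operator: {np.median(other):7.1f} mm^3 "
      f"(Wilcoxon p = {w_inter.p_value:.4f})")
print(f"{intra.form} test-retest      : {intra.value:.4f}")
print(f"{inter.form} between-operator : {inter.value:.4f}")
# The fixed 65 mm^3 operator bias barely touches the consistency ICC but
# drags the absolute-agreement ICC down - the signature of a systematic
# between-operator difference.
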