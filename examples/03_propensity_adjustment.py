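"""Propensity-score correction of co-medication confounding.

Simulates a world with NO true drug-ADE effects but heavy co-prescription
confounding: drugs of a prescription cluster are reported together, and one
ADE is elevated in that cluster's reports.  The crude logistic drug effect
on a confounded pair is therefore biased away from its true value 0; the
PS-adjusted estimate should sit much closer to 0.
"""

from icpnm.pipeline import confounding_bias_experiment

print("true log-odds effect of the index drug: 0 (pure confounding)\n")
print("seed   crude beta1   PS-adjusted beta1")
crude_all, adj_all = [], []
for seed in range(3):
    crude, adjusted = confounding_bias_experiment(seed)
    crude_all.append(abs(crude))
    adj_all.append(abs(adjusted))
    print(f"{seed:>4}   {crude:11.3f}   {adjusted:17.3f}")

ratio = sum(adj_all) / sum(crude_all)
print(f"\nmean |bias| ratio (adjusted / crude): {ratio:.2f}")
print("A ratio well below 1 means the propensity score — built from "
      "principal components of the co-medication matrix — absorbed most of "
      "the spurious association induced by cluster co-prescription.")
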