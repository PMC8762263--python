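"""Classical disproportionality statistics on a small report database.

Simulates a small spontaneous-report world with one strong true signal,
builds the 2x2 contingency table for that pair and prints all four classical
statistics with their signalling bounds.
"""

from icpnm import dpa, srs_data
from icpnm.synth import SimulationConfig, make_world, simulate_reports

cfg = SimulationConfig(n_drugs=30, n_ades=6, n_reports=30_000, seed=11,
                       n_true_signals=5, rr_range=(6.0, 8.0),
                       frac_silent_true=0.0, frac_new_drugs=0.0,
                       n_background_ades=6)
world = make_world(cfg)
db = simulate_reports(cfg, world)

pair, rr = sorted(world.truth.true_pairs.items())[0]
t = srs_data.build_contingency(db, *pair)
print(f"pair {pair}, simulated reporting-rate ratio {rr:.2f}")
print(f"counts: c_ij={t.c_ij}, c_i+={t.c_i_plus}, c_+j={t.c_plus_j}, "
      f"c_++={t.c_plus_plus} (expected under independence {t.expected:.1f})")

prior = dpa.fit_ebgm_prior(srs_data.build_all_contingencies(db).values())
for name, score in [
    ("PRR", dpa.prr(t)),
    ("ROR", dpa.ror(t)),
    ("IC", dpa.ic(t)),
    ("EBGM", dpa.ebgm(t, prior)),
]:
    print(f"{name:>5}: point={score.point:7.3f}  lower95={score.lower95:7.3f} "
          f" signal={score.is_signal}")
print("\nEach method compares observed with expected reporting; 'signal' "
      "applies its conventional lower-bound threshold (PRR/ROR > 1, IC > 0, "
      "EB05 >= 2). The frequentist ratios flag this over-reported pair "
      "immediately; the empirical-Bayes shrinker pulls a handful of reports "
      "hard toward the null and demands more evidence — exactly the "
      "robustness/sensitivity trade-off between the method families.")
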