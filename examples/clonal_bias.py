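"""Clonal lineage-bias classification and limiting-dilution estimation.

Simulates single-HSC transplant readouts from the four output archetypes
(Pl, Pl/My, Ba, Ly), applies the 0.1% inclusion filter and the threefold
bias rule at weeks 10 and 16, and estimates repopulation frequency from
recipient counts under the single-hit Poisson model.
"""

import hscbias as hb

clones, truth = hb.simulate_clones(hb.CloneSimulationConfig(seed=0))
included = hb.filter_clones(clones)
calls = [hb.classify_bias(c) for c in included]

counts = hb.subtype_counts(calls)
accuracy = sum(truth[c.clone_id] == c.label for c in calls) / len(calls)
restricted = sum(c.platelet_restricted for c in calls)

print(f"clones: {len(clones)} simulated, {len(included)} pass the 0.1% filter")
print("subtype counts:", {k: counts.get(k, 0) for k in hb.BIAS_LABELS})
print(f"classification accuracy vs planted archetypes: {accuracy:.1%}")
print(f"platelet-restricted clones (no detectable My/B/T output): {restricted}")

# published transplant arms: 11/20 young and 21/27 old recipients
# reconstituted at 5 cells per recipient
young = hb.poisson_lda(n=20, k=11, dose=5)
old = hb.poisson_lda(n=27, k=21, dose=5)
print(f"\nrepopulation frequency, young: {young.percent:.1f}% per cell")
print(f"repopulation frequency, old:   {old.percent:.1f}% per cell")
print("With platelet output included in the readout, aged HSCs repopulate")
print("at least as frequently as young ones (30% vs 16%).")
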