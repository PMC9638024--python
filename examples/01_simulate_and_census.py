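"""Simulate one dual-color field and run the oligomer census on it.

Generates a 7 µm × 7 µm two-channel field with a known species mix
(70% monomers, 15% heterodimers, 10% 2EP2:1OTR heterotrimers, 5%
3EP2:1OTR heterotetramers), runs discounting → grouping → census, and
compares the recovered class fractions with the planted ground truth.
"""

from palmcensus import (
    AnalysisParams,
    SimConfig,
    analyze_field,
    census_field,
    merge_same_channel,
    score_recovery,
    simulate_field,
)

cfg = SimConfig(seed=42, min_separation=150.0)
field, truth = simulate_field(cfg)
print(f"simulated {len(field)} localizations "
      f"({len(set(truth.complex_of.values()))} planted complexes)")

params = AnalysisParams()  # 10 nm discounting, 50 nm search radius
groups = analyze_field(field, params)
fc = census_field(groups, params)

print(f"{fc.n_groups} association groups; "
      f"{fc.pct_molecules_in_heteromers:.1f}% of molecules in heteromers")
print("heteromer composition (% of heteromeric groups):", fc.heteromer_composition)
print("heterotetramer stoichiometry:", fc.tetramer_stoich)

rec = score_recovery(groups, merge_same_channel(field, params), truth)
print(f"recovery: {rec['n_misclassified']}/{rec['n_molecules']} molecules "
      "assigned to the wrong complex")
print("observed class fractions:", {k: round(v, 1) for k, v in
                                    rec["observed_class_fractions"].items()})
print("planted  class fractions:", {k: round(v, 1) for k, v in
                                    rec["planted_class_fractions"].items()})
# With well-separated complexes the census reproduces the planted mix to
# within a few percentage points; residual deviation comes from the
# 10 nm same-channel discounting removing tightly packed protomers.
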