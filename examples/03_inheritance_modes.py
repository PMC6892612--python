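"""Classify hybrid inheritance modes against mid-parent expectations.

Simulates a 12-parent diallel with a strongly dominant trait, classifies
each cross from the parental and hybrid replicate medians and sds, and
summarizes the mode spectrum for the condition.
"""

from diallel import (
    aggregate_replicates,
    classify_cross,
    classify_panel,
    enumerate_half_diallel,
    simulate_colony_data,
    simulate_founders,
    simulate_trait_model,
)
from diallel.inheritance import summarize_condition

call = classify_cross(P1=0.5, P2=1.0, sigmaP1=0.05, sigmaP2=0.05, Hyb=0.75, sigmaHyb=0.05)
print(f"hybrid at the mid-parent value 0.75 -> {call.mode} (separable={call.separable})")
call = classify_cross(P1=0.5, P2=1.0, sigmaP1=0.05, sigmaP2=0.05, Hyb=1.12, sigmaHyb=0.05)
print(f"hybrid above the best parent band  -> {call.mode}")

founders = simulate_founders(12, 300, seed=4)
model = simulate_trait_model(founders, n_causal=15, additive_sd=0.08,
                             dominance_fraction=0.6, overdominant_fraction=0.1,
                             env_sd=0.03, seed=5)
crosses = enumerate_half_diallel(founders.parent_ids)
phenotypes = aggregate_replicates(simulate_colony_data(founders, crosses, model, seed=6))
calls = classify_panel(phenotypes, crosses, "cond1")
summary = summarize_condition(calls)
print(f"\n{summary['n_calls']} crosses classified; "
      f"{summary['fraction_separable']:.1%} had separable parents")
print("mode fractions among separable crosses:")
for mode, frac in summary["mode_fractions"].items():
    if frac > 0:
        print(f"  {mode:22s} {frac:.2f}")
print(f"predominant mode(s): {summary['predominant_modes']}")
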