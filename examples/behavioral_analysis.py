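"""Behavioral performance of the simulated animal: percent correct per
session, response functions, chance level, and above-chance testing.

Run:  python examples/behavioral_analysis.py
"""

from numopop import (PopulationPriors, TaskConfig, chance_level,
                     generate_experiment, percent_correct,
                     response_functions, test_above_chance)

cfg = TaskConfig(n_sessions=4, trials_per_condition=20, rng_seed=3)
ds, truth = generate_experiment(cfg, PopulationPriors(n_neurons=1))

pc = percent_correct(ds.trials)
print("percent correct per session (aborts excluded):")
print(pc.to_string(index=False))

# with responses unconstrained the modal maximum count bounds guessing:
# a mode of 8 gives 100/8 = 12.5% chance of hitting any one target
chance = chance_level([8, 8, 7, 9, 8])
print(f"\nchance level from modal unrestricted count: {chance}%")

rf = response_functions(ds.trials)
peak = rf.loc[rf.groupby(["numerosity", "format"])["probability"].idxmax()]
print("\nmost frequent produced count per instructed numerosity "
      "(Weber-law errors cluster at the target):")
print(peak.to_string(index=False))

above = test_above_chance(ds.trials, chance=chance,
                          strata=["numerosity", "format"])
print(f"\n{int((above.p < 0.001).sum())}/{len(above)} numerosity x format "
      "strata significantly above chance (one-sided t, p < 0.001)")
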