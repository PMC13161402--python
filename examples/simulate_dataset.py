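"""Generate a synthetic number-production experiment with known ground
truth and write it to disk in the package's text format.

Run:  python examples/simulate_dataset.py
"""

from numopop import PopulationPriors, TaskConfig, generate_experiment, \
    write_dataset

config = TaskConfig(n_sessions=1, trials_per_condition=20, rng_seed=7)
priors = PopulationPriors(n_neurons=20)
ds, truth = generate_experiment(config, priors)
write_dataset(ds, "scratch_example_dataset")

print(f"trials: {len(ds.trials)} "
      f"({(ds.trials.outcome == 'correct').sum()} correct, "
      f"{(ds.trials.outcome == 'error').sum()} error, "
      f"{(ds.trials.outcome == 'aborted').sum()} aborted)")
print(f"neurons: {len(ds.neurons)} "
      f"({int(truth.neurons.tuned.sum())} numerosity-tuned, "
      f"{int(truth.neurons.format_coupled.sum())} format-coupled)")
print(f"spikes: {len(ds.spikes)}")
print("\nGround truth of the first tuned neuron:")
print(truth.neurons[truth.neurons.tuned].iloc[0].to_string())
# The tuned neuron fires baseline_hz everywhere, plus gain_hz scaled by a
# log-Gaussian of the trial's numerosity inside its response window.
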