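"""Run the entire pipeline — simulate, behavior, selectivity, decoding,
temporal — from one config and print the markdown report.

Run:  python examples/full_pipeline.py
"""

from numopop import RunConfig, run_pipeline

cfg = RunConfig(
    out_dir="scratch_example_run", seed=11,
    task=dict(n_sessions=1, trials_per_condition=24),
    priors=dict(n_neurons=12),
    decoding=dict(trials_per_class=20, folds=10, resamples=20, n_null=20),
    temporal=dict(n_resamples=5, n_shuffles=4, n_redraws=2, n_bins=20),
)
report = run_pipeline(cfg)
print(open("scratch_example_run/report.md").read())
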