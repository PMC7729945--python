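"""Run a miniature config-driven experiment bundle and show the tables.

The desk preset covers all three studies (discrimination grid, gain-error
study, aliasing curve); this example thins the grids further so it
finishes in about a minute and prints the aggregated discrimination per
condition.
"""

from opmarray import ExperimentConfig, run_experiment

cfg = ExperimentConfig(
    spacings=[30.0, 45.0],
    amplitudes=[10.0, 100.0],
    offsets=[6.5, 20.0],
    n_deep=3,
    n_superficial=3,
    gain_seeds=[0],
    dense_spacing=20.0,
    channel_counts=[100],
    smoothing_fwhms=[0.0],
)
res = run_experiment(cfg)

summary = (
    res["discrimination"]
    .groupby(["offset", "spacing", "amplitude"])
    .discrimination_mm.mean()
    .rename("mean_discrimination_mm")
    .reset_index()
)
print(summary.to_string(index=False))
print()
print(res["aliasing"][["n_channels", "ve_mean", "aliased_pct", "snr_db"]].to_string(index=False))
print()
print(f"rank spectrum: {res['rank']}")
print(f"run id: {res['provenance']['run_id']} ({res['provenance']['elapsed_s']} s)")
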