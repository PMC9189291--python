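"""Simulate duplicate gel lanes for one construct and quantify them back.

A lane is a linear baseline plus two Gaussian bands (arrested and
full-length species); quantification fits both bands and reports
f_FL = I_FL / (I_FL + I_A).
"""

from forceprofile import (
    ConstructSpec,
    SimulationConfig,
    build_construct,
    expected_band_separation,
    simulate_experiment,
)
from forceprofile.densitometry import quantify_lanes

spec = ConstructSpec("L279", domain_length=239, linker_length=23)
config = SimulationConfig(
    seed=42,
    constructs=(spec,),
    overrides={"L279": 0.75},  # injected ground truth
    baseline_only=True,
    replicates=2,
)
profiles, truth = simulate_experiment(config)
print(f"simulated {len(profiles)} lanes; true f_FL = "
      f"{truth['f_true'].iloc[0]:.2f}, band centers "
      f"{truth['fl_center'].iloc[0]:.1f} / {truth['a_center'].iloc[0]:.1f} px")

sep = expected_band_separation(build_construct(spec), config.render)
table = quantify_lanes(profiles, expected_separation=sep)
print(table[["construct", "replicate", "f_fl", "converged"]].to_string(index=False))
print(f"replicate mean f_FL = {table['f_fl'].mean():.3f}")
# At 2% noise the two-Gaussian fit recovers the injected 0.75 to ~0.005.
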