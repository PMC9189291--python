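"""Full pipeline: simulate the reported-peaks fixture, assemble the force
profile, and detect its folding peaks.

The fixture injects the published peak fractions (0.75 / 0.65 / 0.59 at
L = 279 / 224 / 189) over a baseline+drift floor for all other constructs.
"""

from forceprofile import (
    ProfilePoint,
    annotate_peaks,
    assemble_profile,
    build_construct,
    detect_peaks,
    expected_band_separation,
    paper_fixture_config,
    simulate_experiment,
)
from forceprofile.densitometry import FflMeasurement, aggregate_replicates, quantify_lanes

config = paper_fixture_config(seed=42)
profiles, _ = simulate_experiment(config)
print(f"simulated {len(profiles)} lanes "
      f"({len(config.constructs)} constructs x {config.replicates} replicates)")

sep = expected_band_separation(build_construct(config.constructs[0]), config.render)
table = quantify_lanes(profiles, expected_separation=sep)

points = []
for spec in config.constructs:
    if spec.name == "L279-M2":  # mutant lanes are controls, not profile points
        continue
    vals = table.loc[table["construct"] == spec.name, "f_fl"]
    agg = aggregate_replicates([FflMeasurement(v, spec.name) for v in vals])
    points.append(ProfilePoint(L=spec.L, f_fl_mean=agg.mean, se=agg.se, n=agg.n))
profile = assemble_profile(points)

peaks = annotate_peaks(
    detect_peaks(profile, min_prominence=0.05, min_separation=20),
    [s for s in config.constructs if s.name != "L279-M2"],
)
for p in peaks:
    span = p.repeat_annotation
    print(f"peak at L = {p.L}: f_FL = {p.f_fl:.3f} "
          f"(prominence {p.prominence:.2f}), domain spans "
          f"{span.n_full_repeats} repeats + {span.tail_length} aa tail")
# Exactly three peaks: the intact 7-repeat domain and the 5- and 4-repeat
# truncations; the short-L drift region produces no spurious peak.
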