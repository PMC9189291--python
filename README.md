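# forceprofile

Arrest-peptide force-profile analysis (FPA) of cotranslational folding,
built around the Notch ankyrin repeat domain as the model system.

## The problem

When a protein domain folds while still being synthesized, the folding
event pulls on the nascent chain. A translational arrest peptide (AP) such
as *E. coli* SecM (`FSTPVWISQHAPIRGSP`) stalls the ribosome at its final
proline, and that stall is released by exactly this kind of pulling force.
Fusing a domain to the AP through a linker and titrating the tether length
*L* (residues from the domain N-terminus to the last AP residue) turns the
ribosome into a force sensor: for each construct, an in vitro translation
reaction yields an **arrested** chain (A) and, when the stall is released,
a **full-length** chain (FL) carrying a 23-residue C-terminal tail. The
two species are separated by SDS-PAGE and quantified from the gel as

    f_FL = I_FL / (I_FL + I_A),

where *I* are integrated band intensities. Plotting f_FL against *L* gives
a **force profile** whose peaks mark the tether lengths at which the domain
folds — for a repeat protein, one peak per foldable truncation of the
repeat array.

This package implements the full desk side of that assay for an analyst:

- **constructs** — construct geometry and bookkeeping (L, distance to the
  peptidyl-transferase center, truncation/linker libraries, band-identity
  controls, repeat spans, sequence-logo information content);
- **densitometry** — lane cross-sections to f_FL via a joint fit of a
  linear baseline plus two Gaussian bands, with replicate aggregation;
- **profile** — force-profile assembly, prominence-filtered peak detection
  on the irregular L grid, repeat-structure annotation of peaks;
- **stability** — the published equilibrium stabilities of the Nank repeat
  arrays, OLS and logistic f_FL–ΔG° fits, and a nearest-neighbor repeat
  model ΔG(n) = n·ΔG_intrinsic + (n−1)·ΔG_interface;
- **synthsim** — a synthetic gel simulator (stability→f_FL forward model
  with a ~40-residue folding gate at the exit tunnel, plus a lane renderer
  with log-linear migration, baseline and noise) so every stage is testable
  with known ground truth and no external data.

## Worked example

```python
from forceprofile import *
from forceprofile.densitometry import quantify_lanes, FflMeasurement, aggregate_replicates

config = paper_fixture_config(seed=42)          # 56 constructs x 2 lanes
profiles, truth = simulate_experiment(config)
sep = expected_band_separation(build_construct(config.constructs[0]), config.render)
table = quantify_lanes(profiles, expected_separation=sep)
```

Aggregating replicates, assembling the profile and running
`detect_peaks(profile, min_prominence=0.05, min_separation=20)` prints
(see `examples/03_force_profile_peaks.py`):

```
peak at L = 279: f_FL = 0.748 (prominence 0.41), domain spans 7 repeats + 0 aa tail
peak at L = 224: f_FL = 0.646 (prominence 0.34), domain spans 5 repeats + 19 aa tail
peak at L = 189: f_FL = 0.591 (prominence 0.30), domain spans 4 repeats + 17 aa tail
```

The intact 7-repeat domain folds when its C-terminus sits 40 residues from
the PTC (23-residue linker + 17-residue AP); the two truncation peaks are
the 5- and 4-repeat arrays, whose unstructured half-repeat tails act as
extra linker. Correlating the peak fractions with the equilibrium
stabilities (`examples/04_stability_correlation.py`):

```
linear fit: slope = -0.0229 /kcal/mol, intercept = 0.595, r = -0.9976
```

i.e. each kcal/mol of folding stability buys about 0.023 in f_FL over this
range — on-ribosome force tracks solution thermodynamics.

A thin CLI mirrors the pipeline stages
(`fpa library | simulate | quantify | profile | correlate`); each
subcommand wraps the corresponding library call and exchanges plain
TSV/CSV/FASTA/JSON files, with optional 16-bit TIFF gel rendering.

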