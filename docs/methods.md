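# Methods

This note records the models behind `forceprofile`, the defaults and why
they were chosen, and what the synthetic data do and do not establish.

## Construct geometry

A force-sensor construct is, N- to C-terminal: an optional 154-residue
unstructured visualization segment (present when L ≤ 110, so short
constructs remain visible on a gel), a GSGS insulator, the first
`domain_length` residues of the domain, a linker of `linker_length`
residues (this count *includes* the short insulating tetrapeptide next to
the AP), the 17-residue SecM arrest peptide, and — on the full-length
chain only — a 23-residue tail. The assay coordinate is

    L = domain_length + linker_length + ap.length,

and the distance from the domain C-terminus to the peptidyl-transferase
center is `linker_length + ap.length`. Folding the insulator into the
linker count is deliberate: it is the only accounting under which the
published tether lengths (e.g. domain 239 + linker 23 + AP 17 = L 279,
distance 40) come out by plain addition, and lengths — not segment
identities — drive every computation. Placeholder Gly/Ser sequences stand
in for the unpublished LepB-derived segments; callers can supply real
sequences.

Controls: the full-length control mutates the AP's terminal proline to
alanine (no stall, FL band only); the arrest control replaces it with a
stop (A band only, no tail). Neither changes L.

The default repeat boundaries `(0, 48, 81, 114, 147, 180, 213, 239)`
approximate the seven ankyrin repeats: repeat 1 carries a 15-residue
insertion (33 + 15), repeats 2–6 are the canonical 33-residue motif, and
the last repeat is trimmed at the domain's C-terminus. Exact boundaries
are not published; they are a parameter everywhere they are used.

Library generation is two-stage — linker 39 → 8 in 5-residue decrements
(8 always included) at full domain length, then domain truncation in
5-residue steps at linker 8 until L < 30 — yielding 54 constructs at the
defaults. The published library size (47) cannot be reconstructed because
the exact L set was not tabulated; the generator makes no attempt to force
a count. Note that the 23-residue-linker construct (L = 279) is *not* on
the 5-step linker grid; the reported-peaks fixture adds it explicitly.

## Densitometry

A lane cross-section is modelled as a linear baseline plus two Gaussians;
band intensity is the Gaussian area `amplitude · sigma · sqrt(2π)`.
Migration position increases with migration distance, so the larger
full-length chain takes the smaller coordinate; the ordering is enforced
after fitting. Fits are trust-region least squares with bounds (centers
within the profile, σ ∈ [1 px, span/4], amplitudes ≥ 0), initialized from
the two most prominent local maxima at least half the expected band
separation apart, with σ seeded at a quarter of that separation.

Degenerate inputs are handled in two tiers. A second maximum is only
trusted when its prominence clears both the detection threshold (2% of the
intensity range) and six times a robust noise estimate (MAD of first
differences); a candidate farther than three expected separations from the
main band is rejected as a noise spike. When only one maximum survives,
the fitter first attempts a *shared-width* two-band fit seeded one
expected separation to either side of it, with centers confined near their
seeds — overlapping bands cannot constrain independent widths, and the two
species differ by only 23 residues so equal widths are physically
reasonable. If that refit does not resolve a second band (non-convergence,
coincident centers, or a secondary area below 0.5% of the total), the lane
is fitted as a single band, the missing band's area is set to zero and the
result is flagged. An unidentifiable lone band is assigned to the arrested
species (conservative, f_FL = 0) unless the caller supplies expected band
centers, in which case proximity decides — arrest controls are the common
single-band case in practice.

Accuracy, measured against simulator ground truth: noiseless lanes are
recovered to optimizer tolerance (~1e−15 in f_FL); at the default 4σ–5σ
band separation and 2% additive noise the median per-lane |f̂ − f_true| is
about 0.003; at 2σ separation the overlap makes per-lane areas
intrinsically uncertain (~5% median area error, ~0.012 median f_FL error)
— a limit of the data, not the fitter: fixing the width at its true value
still leaves ~3% median area error.

Replicate aggregation reports the mean and the standard error of the mean
(sample SD/√n); a single replicate has *no* SE rather than SE 0.

## Force profiles and peaks

Profiles are points (L, mean f_FL, SE, n) with unique, sorted L. Peaks are
strict local maxima by index-wise neighbor comparison (the L grid is
irregular), filtered by topographic prominence ≥ 0.05 and pairwise L
separation ≥ 20 residues (higher peak wins). Endpoints qualify only when
above their single neighbor by at least the prominence threshold. The
defaults are artifact definitions — the original peak calls were almost
certainly visual — chosen so the reported-peaks fixture yields exactly the
three published peaks while the slight monotone rise at short L yields
none; both are tunable. Exact ties break toward "no peak"; with
continuous-valued data they have measure zero.

## Stability relations

The built-in table carries the published equilibrium folding free
energies: Nank1-7 (−6.65), Nank1-6 (−2.85), Nank1-5 (−2.69), Nank1-4
(+0.37), a calculated single-repeat value (+5.5), and the destabilized M2
double mutant (≈0), all kcal/mol. The linear f_FL–ΔG° fit is ordinary
least squares over the three peak constructs only (M2 and the single
repeat are excluded by a label filter); zero variance in f_FL yields r = 0
with a warning so pipelines stay total. The logistic alternative
`f = f_min + (f_max−f_min)/(1+exp(k(ΔG−ΔG_mid)))` needs four points for
four parameters; with exactly three the plateaus are pinned to caller
bounds and the fit is flagged underdetermined — with three points the
linear/sigmoidal question is genuinely undecidable.

The nearest-neighbor model ΔG(n) = n·R + (n−1)·I is calibrated by least
squares over the four Nank records, giving R = +6.594 and I = −8.716
kcal/mol exactly (the 2×2 normal equations have determinant 20):
individually unfavorable repeats, strongly stabilizing interfaces. It
exists to drive the simulator, not as a thermodynamic claim; a full Ising
treatment of repeat arrays is out of scope.

## The simulator

Forward model: f_FL = f_baseline + drift·L, plus, once the domain
C-terminus clears a gate of D0 residues from the PTC,
(f_max − f_baseline)/(1 + exp(steepness·ΔG)); clamped to [0, 1]. Defaults:
D0 = 40 residues (the distance at which domains of this size fold at the
tunnel exit), f_baseline = 0.2, f_max = 0.8, steepness = 0.5 per kcal/mol,
drift = 5e−4 per residue (the slow rise produced by an unstructured chain
pulling on the tether). The gate is a hard threshold — a deliberate
simplification of what is surely a smooth crossover.

Renderer: band centers follow the standard log-linear SDS-PAGE model
`center = p0 − p1·log10(chain_length)` with p0 = 1600, p1 = 600 over a
400-px profile — chosen so every chain in the standard library lands
inside the profile and the 23-residue size difference separates the two
bands of a lane by ≥ 4 band widths (σ = 4 px), keeping the two-band fit
well-posed. Total lane signal 2000 a.u. splits between the bands as
f_true : 1−f_true. Noise is additive Gaussian at 2% of the lane's maximum
above-baseline amplitude; phosphorimager noise at realistic exposures is
well approximated as Gaussian, so Poisson shot noise is omitted. One
random stream per experiment, consumed lane-by-lane in construct order,
makes per-lane output reproducible from the config seed alone.

The *reported-peaks fixture* injects the published fractions (0.75, 0.65,
0.59 at L = 279/224/189, and 0.37 for M2 at L = 279) as ground truth and
puts every other construct on the baseline+drift floor, rather than
inverting the forward model — so recovery tests check the measurement
pipeline, not the forward-model calibration. M2 lanes are excluded from
profile assembly (they duplicate L = 279) and serve as the
destabilized-control measurement.

What the simulator does **not** emulate: band skew and smearing, lane
warping, saturation, inter-lane background structure, loading variation,
and any kinetics of translation or arrest release. Passing recovery tests
therefore demonstrate correctness of the quantification and profile logic
under the stated noise model, not performance on real gel images.

Gate recovery: `estimate_gate_threshold` fits a two-level step model over
a dense linker series and returns the split minimizing squared error; on
simulated scans it recovers D0 = 40 within the grid resolution (±5
residues is the tested bound).

## Problem sizes and determinism

The test suite simulates at the experiment's own scale — 56 constructs ×
2 replicates (112 lanes) for the fixture, 100 lanes for the recovery
curve, 46 lanes for the gate scan — and runs in a few seconds. All
randomness flows from explicit integer seeds; identical configs produce
byte-identical ground-truth tables. Hypothesis-based property tests run
derandomized.
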