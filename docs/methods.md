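# Methods

`nucleomech` quantifies how confined migration remodels the cell nucleus,
combining five readout families: nuclear morphometry from fluorescence
microscopy, lamin B1 distribution profiling, γH2AX focus counting, comet-assay
DNA-damage metrics, DNAse-digestion densitometry, and two single-nucleus
mechanics pipelines (optical-tweezers poroelastic indentation and AFM Hertz
fits). Every analysis stage is paired with a seeded synthetic-data generator
that renders the corresponding input modality with known ground truth, so the
whole pipeline is testable end to end without any raw data.

## Poroelastic optical-tweezers inference

**Model.** An indenter bead of radius R pressed a depth δ into the nuclear
surface makes Hertzian contact with radius a = √(Rδ). The instantaneous
response is that of an incompressible elastic half-space,

    F0(δ) = (4/3) · E/(1 − ν²) · √R · δ^{3/2},   ν = 0.5,

and during a constant-depth hold the force relaxes as interstitial fluid
drains through the porous chromatin:

    F(t) = F∞ + (F0 − F∞) · g(τ),   τ = Dp · t / a²,

with Dp the poroelastic diffusion coefficient (µm²/s). For g we use the
two-term exponential approximation for spherical poroelastic indentation,

    g(τ) = 0.491 · exp(−0.908 √τ) + 0.509 · exp(−1.679 τ),

which satisfies g(0) = 1, strict monotone decay, and g(∞) = 0. Any function
meeting that contract can be substituted (`ot.g_master` isolates the choice);
generator and fitter share the same g, so recovery results hold for any
compliant choice.

**Protocol.** The default indentation schedule is a square-wave oscillation at
0.5 Hz with 100 % offset (the bead pushes for half of each 2 s period and
fully retracts for the other half), amplitudes swept from 0.6 to 1.6 µm in
0.05 or 0.10 µm steps, 45 s of data per amplitude, and a 3 µm nominal bead.
0.5 Hz leaves enough time for essentially complete relaxation between pushes.
A per-bead measured diameter can override the nominal one.

**Pipeline.**

1. *Cycle segmentation.* Push onsets are placed from the protocol clock and
   refined per amplitude block by summing the force increments around the
   expected onsets of several cycles — the aligned rising edge gives the
   residual clock lag to one sample. The first cycle of each block is
   discarded (bead settling). Each kept segment stores the empirical peak
   estimate F0 (mean of the first 3 samples) and plateau estimate F∞ (mean of
   the last 10 % of the hold).
2. *Relaxation fit.* Per segment we fit F(t) = F∞ + (F0 − F∞) g(Dp t/a²) with
   F0, F∞ **and** Dp free (the empirical estimates only seed the fit). Freeing
   the amplitudes matters: at high Dp the first samples have already relaxed,
   and at low Dp the hold ends before the plateau, so the seeded estimates are
   biased in opposite directions. The model is linear in (F0, F∞) for fixed
   Dp, so the fit is a variable projection: the linear pair is profiled out in
   closed form and a bounded Brent search runs over log Dp. The profiled RSS
   can be bimodal — a spurious slow branch at Dp → 0 mimics a partial decay by
   extrapolating an enormous relaxation amplitude — so the search first scans
   a coarse log grid and rejects candidates whose fitted amplitude exceeds
   three times the observed force range; segments with no admissible candidate
   or no measurable relaxation (F0 ≈ F∞) are flagged unidentifiable and
   skipped.
3. *Aggregation.* E comes from the closed-form least-squares projection of the
   refined peak forces onto the δ^{3/2} Hertz basis across the sweep
   (instantaneous stiffness; an equilibrium modulus from the plateau forces is
   emitted as a secondary column). Dp is the median over identifiable
   segments — robust to the occasional survivor of the admissibility filter.
   Optional shallow/deep depth bins report both quantities per commanded-depth
   class.

**Synthetic traces.** The generator renders the same model: Hertzian jump,
poroelastic decay with drained-limit plateau F∞ = F0 / (2(1 − ν_d)) at a
drained Poisson ratio ν_d = 0.3, zero force on retract, additive Gaussian
noise, 500 Hz sampling. "5 % noise" in the recovery studies means a noise SD
of 5 % of the largest-amplitude peak force, which makes the smallest-amplitude
blocks genuinely low-SNR.

**Measured recovery** (recomputed by `scripts/acceptance.py`): zero-noise
round trips are exact to ~10⁻⁶ relative on the grid E ∈ {0.5, 1, 2} kPa ×
Dp ∈ {1, 10, 100} µm²/s; at 5 % noise with 50 traces per grid point the median
relative errors are ≲0.4 % for E and ≈2 % for Dp. The hardest corner is
Dp = 1 µm²/s, where relaxation does not complete within the 1 s hold and
per-segment identifiability is marginal; the admissibility filter plus the
median keep its error well inside 15 %.

## AFM Hertz analysis

Approach curves are modelled as a flat baseline followed by a Hertzian rise
F = (4/3) E/(1 − ν²) √R_tip δ^{3/2} past the contact point z_c (paraboloidal
tip, ν = 0.5). The contact point is co-estimated by scanning every candidate
index and minimising the joint residual of (flat before, Hertz after) — the
Hertz prefactor is linear, so each candidate costs O(n). This absorbs any
uniform z-offset. The modulus is then fitted over the 10–90 % window of the
post-contact force, avoiding baseline noise and deep-substrate effects;
per-curve fits with relative residual above 20 % are rejected before
aggregation. Per-nucleus results are the mean ± SD over curves (PeakForce-
style maps supply thousands; nuclei below the configured minimum of 4000
curves are flagged `below_minimum`, not dropped), and per-condition summaries
report mean, SD, and CV — the CV being the heterogeneity statistic that
separates a mechanically uniform population from a dispersed one. Tip radius
is a required input: cantilever geometry is instrument metadata the data
cannot supply. Measured recovery: E median error ≈0.6 % at 2 % force noise,
contact point within ~1 nm median (1 nm z-sampling).

## Nuclear morphometry

*Segmentation* is Gaussian smoothing (σ = 1 px) → Otsu threshold → hole
filling → minimum-area filter, with optional watershed on the distance
transform to split touching nuclei. The recipe is a package choice; it
recovers synthetic masks with IoU > 0.99.

*Area* is pixel count × pixel size², so it scales exactly with the
calibration. *Circularity* 4πA/P² is measured on a sub-pixel contour of the
Gaussian-smoothed mask (σ = 1 px, 0.5 level), with area and perimeter taken
from the same polygon. The light smoothing removes the pixelation staircase
that would otherwise inflate P by several percent; σ = 1 px keeps genuine
corners nearly intact (a 100 px square measures 0.799 against the analytic
π/4 ≈ 0.785; a rasterised disk measures 0.99; a 2:1 ellipse matches the
elliptic-integral value to 0.01). Larger σ flatters circles but rounds
corners; the default is the compromise.

*Osmotic and confinement responses* are pure arithmetic on paired areas:
fold change post/pre, and a shrunk/swollen/unchanged call at ±10 % relative
change.

*Lamin B1 transversal profiles* are sampled along the major axis of the
best-fit ellipse through the centroid (the axis choice is configurable; the
line placement is not dictated by the data), length-normalised to [0, 1] with
101 samples and scaled to the profile maximum. Classification: peaks are
local maxima with prominence ≥ 0.2 of the range after a 5-sample moving
average; a profile is *peripheral* iff it has exactly two peaks and both lie
in the outer 25 % of the abscissa — the two-peak signature of a lamina
confined to the nuclear periphery — otherwise *aberrant*. A peripheral
enrichment score (mean of outer 20 % bins over mean of central 50 % bins)
accompanies every call. On synthetic nuclei the classifier is correct 100/100
at zero noise and ≥ 95/100 at 10 % noise.

*γH2AX foci* are counted by Laplacian-of-Gaussian blob detection over a
physical diameter range (default 0.4–1.6 µm) restricted to the nucleus mask,
keeping blobs whose peak is at least 1.5× the within-mask background median.
The high-damage call is foci_count > 2. "Visible focus" has no universal
definition; this rule is the package's operationalisation and is exact on
noiseless fixtures for counts 0–6.

Images are single-plane 2-D; confocal stacks are reduced upstream
(max-projection for foci, mid-plane section for profiles).

## Comet assay

The comet migrates toward +x (a flip flag handles mirrored inputs). Head
geometry comes from marginal profiles: the row-sum argmax fixes the comet
axis, the column-sum rises at the head's leading edge and reaches its first
prominent local maximum at the head centre (the tail only contributes beyond
the trailing edge); the head radius is half the row span of the comet
component left of centre, which is tail-free by construction. DNA sums
integrate the *signed* background-subtracted intensity on the two sides of
the trailing edge inside a rectangle derived from the detected geometry —
signed sums let noise cancel instead of accumulating through clipping, and a
mask-independent rectangle avoids the selection bias of summing noise over
noise-thresholded pixels. Background is re-estimated as the median outside
that rectangle. Under noise the tail support is found on a σ = 2 px smoothed
copy (noise floor ~7× lower), keeping only the component connected to the
head so that smoothed noise blobs cannot masquerade as far tail.

Reported statistics: tail DNA fraction, tail length (trailing edge to the
farthest tail pixel), extent tail moment = length × fraction (an identity in
the code), and Olive tail moment = |intensity-centroid(tail) −
intensity-centroid(head)| × fraction. Both moment conventions are computed
because the field uses either without always saying which; the Olive variant
is the default reported metric and outputs carry the definition name.
Measured recovery on 50 fixtures: fraction exact at zero noise, within ±0.03
at 10 % noise (tolerance ±0.05).

## DNAse digestion

Gel-lane densitometry profiles run along the migration axis with increasing
index = smaller fragments; more compact, digestion-resistant chromatin
releases larger fragments and peaks at a *smaller* position. Lane profiles
are across-lane column means with an inter-lane strip median subtracted. The
maximum-DNA-peak position is the argmax of a 5-sample moving mean, refined by
the intensity centroid of the half-maximum region around it (region edges are
taken from a heavier smoothing so their jitter stays out of the centroid) —
a bare argmax wanders across a broad band under noise, the centroid is stable
to a fraction of a sample. Ties break toward smaller positions. Condition
comparison calls "more resistant" only when the peak shift exceeds the
smoothing window; the area between unit-normalised profiles is emitted as a
secondary divergence diagnostic. In-situ digestion summarises per-nucleus
relative area change between first and last timepoints per condition.

## Statistics

Two groups: Student's t test (Welch by default; a pooled-variance switch
exists, under which t² equals the one-way ANOVA F on the same two groups).
Three or more groups: one-way ANOVA. Asterisks follow the usual convention
(* p < 0.05, ** p < 0.01, *** p < 0.001, ns otherwise). No multiple-testing
correction is applied by default, matching common practice for these
readouts; Benjamini–Hochberg is available behind a flag. Each row of the
long-format group table is treated as one independent unit — whether cells or
replicates are the unit is the caller's modelling decision.

## Synthetic data: what it does and does not emulate

The generators reproduce the *geometry and signal structure* each analysis
relies on: filled elliptical or multilobed nuclei; a thin peripheral lamin
shell, with 2–4 internal fold lines plus a low-order Fourier boundary
perturbation in the aberrant mode; well-separated Gaussian foci; a uniform
comet head disk with an exponential tail (decay length = tail length / 3,
Gaussian across the axis, head:tail intensity split exact); square-wave
force traces as above; AFM baselines plus Hertzian rises truncated at the
0.3 nN setpoint; one- or two-Gaussian lane profiles. Noise is additive
Gaussian everywhere (a Poisson flag exists for images), with a positive
background offset of 3× the noise SD so clipping at zero is negligible.
A single seed fans out into independent named streams; identical seeds give
bit-identical artifacts.

Not emulated: optical PSFs, uneven illumination, autofluorescence,
out-of-focus light, chromatin texture inside nuclei, overlapping comets,
gel smearing beyond Gaussian bands, instrument drift. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated noise
model, not robustness to every real-microscopy artefact; default noise SDs
are package choices, not measured SNRs.

## Numerical choices and problem sizes

Traces are sampled at 500 Hz (so a default 11-amplitude experiment is ~248 k
samples); relaxation fits use all samples of a hold. The recovery studies run
50 traces per (E, Dp) grid point, 100 AFM curves per modulus level, 100
nuclei per classification condition, and 50 comet/digestion fixtures —
sizes at which medians are stable while the full suite stays in a few
minutes. Degenerate inputs are first-class: blank images give empty masks,
flat profiles and traces raise informative errors, constant relaxation
segments are flagged rather than fitted, and truncated traces yield partial,
flagged results.

## Known limitations

* The poroelastic master curve is an approximation for sphere-on-half-space;
  real nuclei are finite, layered bodies, so E and Dp are effective
  parameters of the probed depth window.
* Whether the instantaneous or the equilibrium modulus corresponds to a
  published stiffness value is often ambiguous; both are reported and the
  instantaneous one is the default.
* Circularity at σ = 1 px smoothing carries a ~+0.014 bias on sharp-cornered
  shapes and ~−0.01 on rasterised smooth shapes — within the stated ±0.02
  but not below it.
* The comet analyzer assumes one comet per image with the head leading on
  −x; multi-comet scenes must be cropped upstream.
* Gel positions are reported in profile-sample units; mapping to fragment
  sizes requires a ladder calibration the package does not perform.
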