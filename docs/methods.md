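# Methods

This note documents the models, conventions and defaults behind `synquant`,
the reasoning where a design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Image preprocessing and puncta detection

Channels pass through a fixed four-step chain mirroring common FIJI macro
practice: background subtraction → Gaussian blur → 3×3 mean smoothing →
percentile contrast stretch.  Background subtraction is a morphological
(grey-opening) estimate with a disk whose radius is given in μm (default
5 μm); for large radii the background is computed on a downscaled copy, the
same strategy ImageJ's rolling-ball uses.  The Gaussian sigma default is
0.05 μm and the contrast stretch saturates 0.35% of pixels per tail.
Contrast enhancement exists only to stabilize detection; intensity metrics
are always taken from a caller-designated raw measurement plane, because a
contrast stretch would corrupt integrated densities.  We make no claim of
bit-exact equivalence with ImageJ's filters.

Detection thresholds are fixed per experiment in configuration and applied
identically to every image of a batch; `suggest_threshold` (Otsu on pooled
training images) is advisory only.  The binary mask is `pixels ≥ threshold`.
Touching spots are split by a distance-transform watershed whose markers are
the h-maxima of the distance map deeper than a merge tolerance (default
0.5 px) — a reconstruction-based equivalent of the "adjustable watershed"
idea, not a bit-exact reproduction of any plugin.  Components smaller than
the minimum particle area are then removed.  The 0.05 minimum particle size
is interpreted as μm² (its units are conventionally left implicit in macro
descriptions); all connectivity is 8-connected in 2D, labels are ordered by
raster scan so outputs are bit-reproducible, and areas are always reported
in μm².

## ROIs, perimeter bands and 3D volumes

A cell ROI is either the largest connected component above a marker-channel
threshold (holes filled) or a rasterized polygon; polygons use half-open
pixel-center semantics so a w×h μm rectangle rasterizes to exactly
(w·h)/px² pixels.  Perimeter length is the length of the lightly smoothed
marching-squares contour (circular moving average, window 7); raw
marching-squares staircases overestimate curved boundaries by 5–8%, while
the smoothed estimate is within ~1% on circles and ellipses and ~1.5% on
squares.  The perimeter *band* — the region against which puncta band
overlaps are measured — is dilation minus erosion by a Euclidean disk of
radius width/2.  The band width is an explicit free parameter (default
0.5 μm): the original macros quantify overlap "with the perimeter" without
stating the boundary's effective thickness, so it must be declared rather
than inferred.  Dendrite ROIs are handled like somas except that per-μm
densities divide by the skeleton length of the mask.

The 3D soma reconstruction replaces proprietary isosurface tools with
voxel-threshold segmentation: the largest 26-connected component above
threshold, volume = voxel count × pixel-area × z-step.  Accuracy is
established on analytic spheres (within 10%), not against any commercial
renderer.

## Synapse calling

Classification thresholds are inclusive: bouton ⇔ outside the cell
(inside-area fraction ≤ 0.5, configurable) with ≥ 0.1 μm² band overlap;
cluster ⇔ inside (fraction > 0.5) with ≥ 0.2 μm² band overlap; synapse or
synaptosome ⇔ mask intersection ≥ 0.03 μm².  Straddling puncta are not
defined by the original rules, hence the explicit inside-fraction cutoff.
Every overlap equals an exact pixel-intersection count times the pixel
area.

Pairing multiplicity is also under-specified in common practice; the
default is best-match per presynaptic particle (maximum overlap, ties to
the lower cluster id) so one bouton is never counted as several synapses
and n_synapses ≤ n_boutons; an all-pairs mode is available.  Distinct
boutons may share a cluster — important because two nearby clusters can
merge into one detected particle without costing a synapse call.
Per-synaptosome intensity defaults to the union of the paired masks
(intersection and post-only modes are exposed); the union is the natural
region when the measurement channel localizes to the whole bipartite
structure.

## Electrophysiology

RMP is operationalized as the mean of a pre-stimulus baseline window (the
moment of break-in is not recoverable from sweep files).  TC is a
nonlinear least-squares fit of V(t) = V_ss + A·e^(−t/τ) from step onset to
90% of the step duration, initialized by log-linear regression.  IR
averages ΔV_ss/ΔI over five 10 pA steps, using each sweep's own baseline,
which makes it exactly invariant to voltage offsets.  Sag is reported as a
signed difference — mean over the final 100 ms of the 1 s pulse minus the
pulse minimum — with the minimum taken on a 1 ms boxcar-smoothed copy,
because the raw minimum over tens of thousands of samples is an
extreme-value statistic that reports spurious sag on any noisy trace.
Capacitance is TC/IR (ms/MΩ → nF, reported in pF) as an exact identity.

AP detection triggers on upward dV/dt crossings of 20 mV/ms after 0.1 ms
boxcar smoothing (at 50 kHz the raw sample derivative of sub-mV noise
alone exceeds any physiological criterion), with a 2 ms refractory and a
20 mV minimum rise from threshold to peak; the AHP minimum is searched
5 ms after the peak.  These are declared detector defaults, not values
carried over from any acquisition software.  fAHP uses the first AP of the
lowest suprathreshold step (rheobase-adjacent), as threshold voltage minus
AHP minimum.

PPR measures, per stimulus and sweep, the absolute extremal deviation
within 20 ms after the stimulus from a 5 ms local pre-stimulus baseline;
amplitudes are averaged across sweeps before taking amp₂/amp₁ (averaging
ratios per sweep is exposed but non-default, as small first amplitudes
make per-sweep ratios unstable).  Results with averaged amp₁ < 50 pA are
flagged excluded but still reported.

## Gene-program statistics

The expressed-gene rule "RPKM > 99% of the intergenic background" admits
two readings; the default keeps genes above the 99th percentile
(linear-interpolation) of the background distribution, and a literal
`> 0.99 × background value` mode is available, with the mode recorded in
the output metadata.  DEG calls are inclusive at p ≤ 0.05 and fold change
≥ 1.5.  Candidate scoring assigns one point per met criterion (binary
equal weights — consistent with integer score sums over four criteria),
after removing genes below an FPKM-5 expression floor, and ranks by score
with alphabetical tie-breaks.  Database annotations (disease gene lists,
synaptic ontologies, homolog maps) are consumed as pre-built tables, never
queried.  Fold enrichment is (k/|query|)/(|reference|/universe); the
two-sided Fisher p sums all hypergeometric table probabilities not
exceeding the observed one, and is verified against exhaustive enumeration
for every table with universe ≤ 30.

## Synthetic data

Generators are pure functions of (parameters, seed).

*Decorated cells* (default field 40 μm at 0.1 μm/px) render an elliptical
soma (semi-axes 8×5 μm, perimeter ≈ 41.4 μm) in a marker channel.  The
bouton count is Poisson with mean density × perimeter (default 0.15/μm);
centers are placed uniformly by arc length with a 0.9 μm hard-core
exclusion, sit 0.15 μm outside the boundary, and a pairing fraction
(default 0.8) receives a cluster 0.15 μm inside at sub-resolution
tangential jitter.  The hard core reflects that boutons are ~0.6–0.8 μm
physical objects: centers closer than the optical resolution would render
as one punctum, making the planted count unobservable for any
threshold-based detector.  Spots are pixel-integrated Gaussians (sub-pixel
placement does not bias areas), blurred by a 0.1 μm PSF and corrupted with
Poisson plus Gaussian (σ = 2) noise; peak ≈ 160 over background 8, with a
suggested detection threshold of 60, gives ≥ 95% single-punctum recall.
The geometry guarantees planted structures satisfy the 0.1/0.2/0.03 μm²
rules with ≥ 50% margin.  What these images do *not* emulate: tissue
autofluorescence, off-target puncta and clusters without boutons, soma
shape irregularity, and z-projection artifacts — so recovery on them
bounds algorithmic error, not biological measurement error.

*Synaptosome fields* place 120 presynaptic puncta with ≥ 1.8 μm separation,
pair a fraction (default 0.7) with a postsynaptic punctum offset 0.2 μm,
and draw per-pair measurement flux from a lognormal whose log-mean drops by
log(0.6) in the "mutant" condition, emulating reduced phosphorylation.

*Membrane protocols* are closed-form RC responses (defaults R = 150 MΩ,
C = 80 pF, τ = 12 ms, RMP = −65 mV, 50 kHz sampling, 0.2 mV noise) for the
TC/IR/sag sweeps, an optional slow depolarizing relaxation emulating Ih on
the −100 mV pulse, and leaky-integrate-and-fire spiking on 100 pA steps
(threshold −40 mV, reset −55 mV = AHP minimum, 2 ms refractory) with
stereotyped 1 ms AP waveforms, so spike counts, AP peak (+30 mV) and fAHP
(15 mV) are known in closed form.  *PPR sweeps* are double-exponential
EPSCs (rise 0.5 ms, decay 4 ms — fast AMPA kinetics typical of inputs onto
interneurons, which also leaves < 0.01% residual at the 50 ms
inter-stimulus interval), amplitude 150 pA and a planted ratio.

*Gene tables* plant a DEG fraction (default 4%) with fold changes
1.5 + Exp(0.8) and p ∈ [1e−8, 1e−2], 70% down-regulated; null genes have
fold changes near 1 and uniform p, so joint-threshold false positives are
~0.05 × P(FC ≥ 1.5 | null) ≈ 5 × 10⁻⁵ per gene.  A reference list overlaps
the down-regulated set by a planted count for enrichment checks.

## Problem sizes and numerical choices

The acceptance script uses 20 simulated cells (400×400 px each, ~0.25 s
per cell through the full pipeline), one 120-punctum synaptosome field,
one membrane protocol set, ten PPR sweeps, a 5000-gene table with 200
planted DEGs, and the exhaustive Fisher scan over all tables with universe
≤ 30 (23 655 tables); the whole script runs in well under a minute.
Because the realized Poisson density of 20 cells fluctuates ~10% around
the nominal rate, density recovery is assessed against the generator's
per-run ground truth rather than the nominal parameter — the quantity that
actually measures pipeline fidelity.  Ties in best-match pairing go to the
lower cluster id; label maps are raster-ordered; all thresholds are
inclusive; empty detections are results, not errors (an empty ROI mask is
an error, since every downstream quantity divides by its geometry).

## Known limitations

Watershed splitting cannot separate spots closer than the optical
resolution, and the simulator deliberately avoids planting such pairs;
real images will under-count at high local densities.  The perimeter-band
width is a free parameter with no experimental ground truth.  Vendor sweep
formats (ABF/NWB) are not read — sweeps arrive as CSV plus a JSON protocol
descriptor.  Group statistics stop at mean ± s.e.m.; inferential tests are
left to downstream tools.
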