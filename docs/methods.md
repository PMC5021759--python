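# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Spatial frame

All morphometry is binned into concentric shells ("annuli") of width
6.25 µm around the soma center; nine annuli are carried everywhere
(annulus 0 contains the soma). Annulus assignment is by floor of
distance / 6.25 with half-open intervals [k·6.25, (k+1)·6.25), so a
punctum at 10.5 µm belongs to annulus 1 and a boundary value falls
outward. Distances are 3D physical Euclidean distances from a single
reference point (the soma center), not geodesics along the dendrites.
The acquisition geometry assumed throughout is 0.25 µm xy pixels and a
1 µm z step, 16-bit; at this geometry the puncta local-maximum
neighborhood (xy radius 2 px, z radius 1 voxel) is 500 nm × 500 nm ×
1 µm.

## Imaging streams

**Neuron fill.** The fill channel is convolved with a
Laplacian-of-Gaussian ("radius 1 voxel" read as Gaussian σ = 1 voxel
per axis followed by the Laplacian, sign-flipped so bright structures
are positive). The binarization threshold is the mode plus 1/10 of the
standard deviation of the transform's maximum-Z projection; the mode of
the continuous-valued transform is taken from a 1024-bin histogram.
The threshold is applied to the full 3D transform, an optional
exclusion mask (the reproducible substitute for interactively clearing
neighboring neurons) is subtracted, and the largest 26-connected
component is retained. Because the LoG of a large uniform blob is
nearly zero in its interior, the soma comes out hollow; enclosed
cavities are filled before any downstream measurement. This chain is
invariant to global intensity offsets (the mode shifts with the offset)
and to gain up to quantization.

**Soma center.** The fill stack is contrast-saturated (0.4 % of the
range, split between tails), rescaled to 8-bit, convolved with a heavy
LoG (xy radius 10 px, z radius 1 voxel), max-Z projected, and
thresholded by an exhaustive-search Rényi-entropy criterion (order
α = 2 by default; the criterion maximizes the summed renormalized
background and foreground Rényi entropies over all 8-bit thresholds).
Among the thresholded objects the *most massive* one is kept, with mass
the z-summed saturated intensity over the footprint — the soma spans
many z planes while dendrites occupy one or two, so mass concentrates
at the soma. Its center of mass (same weights) gives x/y; z is the
intensity-weighted mean over the footprint columns, a choice a
projection cannot dictate. When the fill mask is available the
projection estimate additionally seeds an iterated local 3D center of
mass over mask voxels within 8 µm, which sharpens the reference point
to sub-voxel accuracy; the distance map is then the physical Euclidean
distance of every voxel from this point.

**Skeleton, length and crossings.** The mask is thinned by 3D
medial-axis skeletonization. Skeleton steps are the edges of the
minimum spanning tree of the 26-adjacent skeleton voxels with physical
step lengths (the spanning tree removes the redundant
diagonal-plus-orthogonal duplicate steps a raw 26-neighborhood
contains). Per-annulus dendrite length sums step lengths by the
annulus of each step's midpoint; annulus 0 (the soma shell, which also
collects the skeleton of the soma body) is excluded from "total
dendrite length". A Sholl crossing at radius k·6.25 is a spanning-tree
step straddling that sphere; counting straddling steps rather than
clustered voxel groups keeps two touching branches separable as two
crossings.

**Punctae.** Puncta channels receive the same LoG; local maxima within
the ellipsoidal neighborhood seed a watershed over the (negated) LoG
landscape restricted to LoG above a robust noise floor (5 MAD-estimated
SDs of the transform, so a noise-only stack yields no punctae, while
the floor scales with gain and vanishes against the signal).  Plateau
maxima collapse deterministically to their first voxel in scan order.
Growth is 26-connected and intensity-ordered (the watershed priority),
and the watershed lines prevent nearby punctae from merging. There is
no size filter by default (configurable minimum, 1 voxel). A punctum
belongs to the neuron iff its mask shares at least one voxel with the
fill mask. Intensity is measured on the raw image (mean over the
mask); soma distance is the mean of the distance map over the mask;
normalized intensity (AFU) divides by the mean raw intensity of
control-neuron punctae of the same channel and imaging session, making
the control session mean 1 AFU by construction.

**Statistics.** Two-sample comparisons are screened for normality with
Shapiro–Wilk on each sample at p < 0.05; both passing selects Student's
t (paired or unpaired), otherwise a rank test — Wilcoxon signed-rank
when paired, Mann–Whitney U when unpaired (a signed-rank test requires
pairing, so the unpaired non-normal branch necessarily deviates from a
signed-rank). Significance is p < 0.05 and no multiple-testing
correction is applied across sweep combinations.

## Compartmental models

Each Sholl crossing in annulus k becomes one dendritic compartment of
length 6.25 µm, attached round-robin to the compartments of annulus
k−1 (any assignment preserving counts is admissible; round-robin is
deterministic). Compartment diameter inverts the cylinder volume
relation d = 2·√(V′/(π·6.25)) with V′ the annulus fill volume divided
by that annulus's compartment count, so modeled dendritic volume per
annulus equals measured volume exactly; a switch restores the
total-volume reading. The annulus-0 compartment is the soma (same
inversion); every model receives an identical 100 µm × 1 µm axon and an
apical dendrite (250 µm default, diameter 2 µm, no synapses — it is the
passive load standing in for unimaged apical material and is swept).
Segments per compartment follow the d-lambda rule with d-lambda 0.1:
nseg is the smallest odd integer ≥ L/(0.1·λ₁₀₀), λ₁₀₀ the 100 Hz AC
length constant.

Synapse tables store integer counts at 16 discrete conductance levels
(0.25 … 4.00 nS in 0.25 steps): 1 AFU equals 1 nS, values round to the
nearest level and clip at the 0.25/4 nS floor and cap (≈99 % of
normalized intensities fall inside). Discrete levels rather than
binned ranges keep allocation statements exact (e.g. "4 of the 18
active excitatory synapses at 1.5 nS").

## Stimulation and integration

A protocol of strength s ∈ (0, 1] activates round(s·N) synapses, each
firing once at a uniformly random time inside the integration window
T. Actives are allocated over the (annulus, type, level) table by a
multinomial draw proportional to counts, placed uniformly over that
annulus's compartments and uniformly along the compartment. All
stimulus draws are deterministic per seed; sweeps and substitution
experiments share stimulus seeds across groups/conditions so
comparisons are paired.

The cable is integrated with a staggered scheme: exponential-Euler
gate updates at the current voltage, then a backward-Euler voltage
solve over the compartment tree by Hines elimination (O(N) per step).
Membrane: Hodgkin–Huxley Na/K on soma and axon, passive dendrites and
apical; the dendrite-excitability knob divides the dendritic leak
density. The HH leak reversal is calibrated at build time so the
resting state (−65 mV) is an exact fixed point — zero input drifts by
< 0.01 mV over 500 ms. Synapses are double-exponential conductances
(default rise 0.5 ms E / 1 ms I; decays 3 ms / 8 ms, swept), reversals
0 / −70 mV, peak-normalized, and aggregated per segment and receptor
class into two decaying states so cost is independent of the number of
events. Default dt = 0.025 ms; halving dt leaves AP counts unchanged
and changes subthreshold traces by < 0.5 mV (during a spike upstroke a
sub-step timing shift is necessarily several mV for any first-order
scheme, so trace convergence is assessed subthreshold). An AP is a
strict upward crossing of −35 mV at the distal axon segment within the
window; rate = count/T. Events are inserted at the step containing
their onset; divergence beyond |V| > 200 mV aborts with an instability
error naming dt.

Biophysical defaults (axial resistivity 150 Ω·cm, capacitance
1 µF/cm², dendritic leak 1e−3 S/cm², gNa 0.2 and gK 0.036 S/cm² on
soma+axon) are package defaults chosen so the default synthetic
populations span a graded ~1–70 Hz range with a monotone
strength–rate relation — the operating regime in which morphological
comparisons are meaningful. They are deliberately conservative about
channel detail: the scientific claims concern morphology, not
kinetics, and dendritic excitability is swept as a free parameter.

## Sweep and substitution

The default scheme varies each of the five unconstrained parameters
over five values sharing a middle baseline, one at a time
(1 + 5·4 = 21 combinations), crossed with five stimulation strengths
(0.2–1.0): 105 combinations, 6615 simulations for a 63-model group. A
full-grid scheme is available. Percent difference per combination is
100·(mean₊ − mean₋)/mean₋; combinations where fewer than half of all
models fire at least one AP are flagged not-compared, and rank-matched
model-pair differences are reported alongside. Models are ranked by
mean rate over all combinations, ties by id.

Substitution replaces exactly one parameter of every recipient model
with the donor group's per-annulus average: dendrite counts (rounded,
orphaned outer annuli repaired by truncation with a warning), total
synapses (largest-remainder reallocation to the donor per-annulus
totals, preserving the recipient's composition), E/I ratio (donor E
fraction at fixed totals), E or I intensity spectra (donor level
distribution at fixed counts), or fill volume. All other marginals are
preserved exactly. Hybrids run at middle parameter values and
strengths {1.0, 0.6, 0.2}, compared to their originals with the paired
screened test.

## Synthetic data: what it emulates, what it does not

**Phantoms.** A neuron is a spherical soma (4 µm radius by default)
plus constant-radius (0.5 µm) tubes along synthesized polylines,
blurred by a Gaussian PSF (σ 1 px xy, 0.5 voxel z), on a constant
16-bit offset with additive Gaussian noise — the simplest model under
which mode+SD thresholding is well defined. Branch trees hit a target
per-annulus crossing profile exactly: branches march outward with
azimuthal jitter, bifurcate 2 µm before a sphere with 40–65° divergence
(so sibling tubes separate beyond the PSF before crossing), and
terminate just inside a boundary. Short tangential twigs add dendrite
length inside an annulus without crossing its boundaries, decoupling
length from crossings. Ground truth (per-annulus polyline length,
sphere crossings, puncta records, the rendered tube voxel set) comes
from the geometry, not the rendering. Punctae are 3D Gaussians (σ 1 px
xy) whose integrated intensity is proportional to the specified
normalized intensity.

**Populations.** Direct (non-rendered) profile populations draw
per-neuron size factors (CV 0.25), Poisson puncta counts at densities
0.45 E / 0.15 I per µm (so inhibitory totals scale linearly with
excitatory totals at slope ≈ 1/3), log-normal intensity spectra, and a
baseline arbor of ~0.8 mm dendrite / ~500 punctae scaled to a cultured
cortical neuron. Group contrasts default to the effect sizes the
pipeline is built to resolve: ×1.24 length, ×1.30 complexity, balanced
×1.30 E and I addition, ×1.30 inhibitory intensity. The rendered
imaging population uses a tight 3 % CV and six occupied annuli by
default: the phantom benchmark isolates pipeline *measurement* error
from biological variability, and the smaller field renders and
segments in minutes (the benchmark uses ≥20 neurons per group; the
acceptance script uses 24). Largest-remainder rounding of crossings
keeps the realized group contrast at the configured multiplier.
Substitution-direction experiments construct populations with CV 0.1:
with large dispersion, Jensen-type curvature of the saturating
rate-vs-synapse-count relation across heterogeneous cells can mask the
mean effect of substituting a group-average parameter.

**MEA traces.** 64 electrodes at 12.5 kHz carry Poisson-timed biphasic
spikes (~1.6 ms, 8× noise SD, negative-going) in Gaussian noise, per
epoch (baseline, 2 h, 12 h at configurable rates, e.g. ×2.02 and ×6.34
for the treated condition, ×1.32 at 12 h for controls). Traces render
lazily per (epoch, electrode) from spawned seeds so a full recording
never resides in memory. The generator omits burst synchrony,
electrode cross-talk and drift; detection is a 5-robust-SD (MAD/0.6745)
threshold with a 1 ms lockout, so at high rates ~1 % of spikes merge —
the recovered 12 h increase runs ~2 % low, well inside the benchmark
tolerance.

Passing the phantom benchmarks shows the pipeline recovers known
geometry and known contrasts under this noise model; it does not
establish performance on real stacks with uneven background,
depth-dependent PSFs, overlapping neurons, or antibody artifacts —
the exclusion-mask mechanism and per-session normalization address
those only partially.

## Reproducibility

Every stochastic stage consumes an explicit seed; the pipeline driver
fans a single global seed out per stage via
`SeedSequence((global_seed, stage_index))`, outputs carry a provenance
header (config hash + seed), and the run manifest records content
hashes. Fixed seed implies bit-identical outputs everywhere, including
the lazily rendered generators.

## Known limitations

* Skeleton-based length slightly overestimates near junctions and
  erodes terminal tips (~0.5 µm); total length is recovered within
  ~3 % per neuron and group contrasts within ~2 percentage points.
* The soma-shell annulus mixes soma-body skeleton with proximal
  dendrite; it is excluded from totals rather than resolved.
* The HH-on-soma/axon membrane saturates near ~70–100 Hz and can
  depolarization-block under extreme drive; comparisons are designed
  for the graded regime.
* AFU recovery from rendered phantoms carries the imaging offset into
  the raw mean (no background subtraction, matching the measurement
  convention), so absolute intensity recovery is approximate even
  though session-relative ratios are preserved.
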