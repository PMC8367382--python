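# Methods

This note documents the models, defaults and design choices behind the
package. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Analysis pipeline

**Registration.** Each imaging round carries a DAPI counterstain that
anchors alignment; probe channels are never registered on their own
signal. Stage one estimates a translation by phase cross-correlation
with 20× upsampled refinement (sub-pixel). Stage two estimates a
residual elastic field by normalized block matching: the image is tiled
on a regular grid (default 64 px spacing with a 32 px search margin),
each block is matched to the reference by upsampled phase correlation,
low-contrast blocks (std below 5 % of the image std) and implausible
matches (> 10 px, the configured displacement cap) are discarded and
refilled from their nearest accepted neighbour, and the node field is
bicubically upsampled and Gaussian-smoothed (σ = spacing/4) into a dense
per-pixel field. This is a deliberately simple smooth estimator whose
contract is accuracy on synthetic warps, not fidelity to any particular
B-spline energy-minimization tool. Displacement convention:
`moving(x) ≈ reference(x + d(x))`; applying a transform resamples the
moving image bilinearly at `x − d(x)` (exact inversion for pure
translations, first-order for smooth fields), with out-of-field pixels
set to 0. All channels of a round are resampled in a single
interpolation pass.

**Segmentation.** Gaussian smoothing (σ = 2 px) → Otsu foreground →
Euclidean distance transform → peak markers with a minimum separation
of one nucleus radius → watershed → removal of objects below
20 µm². Otsu always produces a split, even on pure noise, so a contrast
guard rejects the segmentation outright unless the foreground exceeds
the background by at least 10 robust (MAD-based) standard deviations of
the smoothed image. Somatic ROIs are the nuclei expanded isotropically
by 5 µm with contested pixels assigned to the nearest nucleus
(`skimage.segmentation.expand_labels`), so ROIs are disjoint by
construction and probe signal is never double-counted; the alternative
reading (overlapping dilated ROIs) was rejected for exactly that
double-counting reason.

**Quantification.** Thresholds are quantiles of the full registered
image histogram, one per gene per section: the smallest intensity whose
strictly-above fraction does not exceed the tail fraction. The allowed
range is 0.002–0.01 with 0.005 (the midpoint) as default. Slc17a7
defaults to the upper end (0.01) because it is expressed in every
excitatory cell and is by far the densest channel; all other genes use
0.005. Being quantile-based, the binarization is invariant to monotone
intensity rescaling. The excitatory gate keeps cells with
PAC(Slc17a7) ≥ 1 (boundary inclusive) and drops the gate gene from the
matrix. Within-cell normalization divides each row by its sum (L1);
all-zero rows are left at zero and flagged. L1 was chosen over max- or
z-scaling because the downstream clustering compares composition
profiles; the alternative normalizations remain one-line changes at the
call site.

**Cell typing.** The kNN graph (Euclidean on normalized PAC, k = 15,
symmetrized, unweighted) feeds Leiden community detection
(RBConfiguration partition). The resolution grid 0.1–2.0 in steps of
0.05 is scanned in ascending order and the first resolution giving
exactly five clusters is taken; if none does, the closest-к resolution
wins (ties toward lower resolution) with a warning recorded. UMAP
(k = 15, fixed random state) runs on the same features but
independently of the clustering graph. Phenotypes are assigned by mean
raw marker PAC in the fixed order Synpr → core, Nnat → shell, Ctgf →
deep_L6, each marker taking the highest-mean unassigned cluster (ties
to the lower cluster id, with a warning); remaining clusters are ranked
cortex_a/cortex_b by descending Pcp4. Clustering is per section/animal
by default.

**Projections.** Tracer channels are areal fills, not punctate spots,
so they are binarized with Otsu's threshold floored at median + 5
robust SD of the channel — an empty channel yields no calls, and the
threshold does not depend on how many cells happen to be labeled (a
histogram-tail quantile does, and collapses into the noise floor when
the fill area is below the tail fraction). A cell is called labeled
when its label PAC ≥ 1, symmetric with the excitatory gate. This
automated rule replaces the original manual, blinded scoring, whose
criterion is unrecoverable; its contract on synthetic data is recall
≥ 0.95 and false-positive rate ≤ 0.02. Dual-labeled cells are excluded
from all RSC-vs-LEC comparisons; the dual fraction is reported as a
percentage of labeled cells to one decimal. Contingency percentages
are the modal-phenotype share of each projection column among
single-projection core/shell cells, rounded to the nearest integer, and
are re-derived from their own counts on every construction (an
assertion, not a convention).

**Statistics.** Two-sided Mann–Whitney U per gene (scipy; exact null
for small tie-free samples, normal approximation otherwise), Bonferroni
correction over the genes tested in the call
(`p_adj = min(1, p·m)`), stars on adjusted p: ns ≥ 0.05, * < 0.05,
** < 0.01, *** < 0.001. Box summaries report quartile hinges and
whiskers at the most extreme points within 1.5 IQR; values beyond the
whiskers are omitted.

**scRNA-seq QC.** CPM(g, c) = 1e6 · count(g, c) / library size of c,
over all genes including spike-ins if present (spike-in handling in the
original is unstated; exclusion is a config flag, default include).
Filters run sequentially — Snap25 CPM < 0.001 first, then Slc17a7
CPM < 1e-10 — and a cell failing rule *i* is attributed to rule *i*
and not re-tested, which matches the "additional cells" phrasing of
the source ledger; swapping the order can move attribution but never
changes the retained count (a tested property). Transcriptomic classes
for the contingency table come either from planted truth or from a
marker-max rule (highest CPM among Synpr/Nnat/Pcp4); replicating a full
Seurat-style clustering is explicitly out of scope.

## Synthetic data: what it emulates, and what it does not

The generator plants a concentric geometry in a 512 × 512 µm field
(1 µm/px): core disc of radius 90 µm, shell annulus to 150 µm, deep-L6
ring to 190 µm, cortex beyond, holding 150 cells by default at
proportions core 0.25 / shell 0.30 / deep_L6 0.15 / cortex_a 0.15 /
cortex_b 0.15. Absolute claustrum dimensions are not standardized
anywhere we could anchor them, so the radii are exposed configuration,
and the per-section density is a package choice. Cells are placed by
rejection sampling with a hard minimum centre distance of two nucleus
radii (default nucleus radius 4 µm; somatic footprint = nucleus + 5 µm,
matching the analysis dilation). Placement failures raise an error
naming the achievable density.

Expression is a per-phenotype table of spot densities (spots per
100 µm² of soma): each class carries its defining marker at 20 (Synpr
in core, Nnat in shell, Ctgf in deep L6), secondary markers at 3–16
(e.g. Gnb4 in both claustral classes, Pcp4 graded 16/10/8 across
cortex_a/cortex_b/deep_L6), Slc17a7 at 12 everywhere (all simulated
cells are excitatory), and an off-target baseline of 0.3. Spots are
Poisson in number, uniform within the soma, lognormal in brightness
(σ = 0.5, emulating hybridization-efficiency and axial-position
variation — and important: with identical spot amplitudes the
top-quantile threshold selects only chance spot coincidences, which is
neither realistic nor stable), splatted bilinearly at sub-pixel
positions, blurred by a Gaussian PSF (σ = 0.6 px), offset by a
background of 100 counts and corrupted by Poisson noise plus Gaussian
read noise (σ = 2), written as 16-bit.

Rounds 2 and 3 are resampled through a planted rigid shift (defaults
(3, −2) and (−4, 3) px) plus a smooth elastic field from a 4 × 4 grid
of uniform control displacements capped at 3 px, bicubically upsampled
and centered so the dense field has zero mean — any net translation
belongs, by convention, to the rigid component, which keeps the planted
decomposition identifiable by a registration estimator. The
retrograde-label round is rendered in the reference frame (the spec of
the registration stage covers probe rounds; a planted label-round
transform is configurable but defaults to identity). Label fills are
perinuclear discs (nucleus radius + 0 µm by default): with full-soma
fills, neighbouring somata overlap each other's ROIs whenever centres
fall within twice the soma radius, producing false dual calls at rates
far above the label-call contract; perinuclear fills cannot cross the
ROI midline at the minimum placement distance.

Projection flags are independent per-channel Bernoulli draws from
per-phenotype affinities. The defaults —
core {RSC 0.15, LEC 0.039}, shell {RSC 0.025, LEC 0.15}, cortex/deep-L6
{RSC 0.006, LEC 0.011} — were calibrated once, by exact mixture
enumeration (`expected_label_composition`), so that the *reported*
statistic (modal share among single-projection core/shell cells after
dual exclusion) is ~85 % core for RSC and ~84 % shell for LEC with a
dual fraction near 2 % of labeled cells. Own-affinities much larger
than ~0.2 cannot coexist with a ~2 % dual fraction under independent
draws — the cross-affinities required for 15 % impurity then force the
dual rate an order of magnitude higher — which is why the defaults sit
at 0.15 rather than near 1.

The count-matrix generator plants five classes (Synpr-high, Nnat-high,
cortical, Snap25-low, Slc17a7-low) with sizes fixed by
largest-remainder rounding of the proportions (27/1112 and 74/1112 for
the contaminants) and negative-binomial counts (dispersion r = 5).
Contaminants carry structural zeros in their defining gene because the
CPM cutoffs are below one read at any realistic library size — they
are zero-count filters in practice — so the ledger reproduces exactly
up to NB zero-leakage in neurons, which at the default means
(Snap25 = 100, Slc17a7 = 150) has probability < 1e-6 per cell.

What the generator does *not* emulate: optical sectioning and 3-D PSFs,
spectral bleed-through, autofluorescence, segmentation-hostile nuclear
morphologies, cell-type-specific soma sizes, spatial expression
gradients within a phenotype, and doublets. Passing tests therefore
demonstrate that the pipeline recovers planted structure under
idealized-but-noisy imaging, not that it is robust to every failure
mode of real tissue; the registration, threshold and label-call
contracts are the parts most likely to need retuning on real data.

## Problem sizes

Defaults were chosen so the full test suite runs in a few minutes on
one CPU: single sections are 512 × 512 µm with 150 cells;
registration/segmentation checks use 512 × 512 px fields (300 cells for
the segmentation oracle); the projection-recovery checks pool ten
1024 × 1024 µm sections of 600 cells (same density and affinities as
the defaults), because per-section label counts (~15 at 150 cells) are
too small to test percentages against a ±5-point band; the QC
calibration averages 200 generator draws. The acceptance script runs
one registration pair, one 300-cell segmentation field and three large
sections.

## Known limitations

- The elastic estimator recovers only fields smooth at the block scale
  (≥ ~64 px); sharper tears or folds alias into local errors.
- The excitatory gate interacts with the quantile threshold: the
  per-cell positive-pixel budget is tail_fraction × image area /
  n_cells, so very dense fields starve the gate. At the default
  density the budget is ~17 px per cell against a gate of ~2.5 px.
- Exactly five clusters is an outcome-defined stopping rule; on data
  without five real populations the warning path reports the closest
  achievable partition instead.
- Automated label calling is a substitution for manual blinded scoring
  and its thresholds (Otsu + 5 MAD floor, PAC ≥ 1) are validated only
  against the synthetic fill model.
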