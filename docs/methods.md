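# Methods

This note documents the models and procedures implemented in `guvmem`, the
assumptions behind them, the parameters that matter, and the design choices
made where the underlying analyses left the design open.

## GUV scene model (synthetic data)

A GUV images as a thin bright ring in the lipid channel (the equatorial
cross-section of the vesicle), with membrane-bound protein appearing as
discrete bright puncta *on* that ring in the protein channels. The generator
renders:

* lipid channel: `background + Σ_g A_g · exp(−(d − R_g)² / 2τ_g²)` where `d`
  is distance to the vesicle center, `R_g` the ring radius (default 10–14 px)
  and `τ_g` the ring thickness (default 1.5 px);
* protein channels: `background + Σ_p A_p · exp(−r² / 2σ_p²)` with each spot
  centered on a ring at a specified angle (σ default 1.5 px, amplitude
  default 200 intensity units);
* additive Gaussian noise (default σ = 20, i.e. spot SNR 10), clipped to
  `[0, 2^bit_depth − 1]`.

Defaults: 256×256 frames, 10 vesicles per scene on a jittered grid with
center separations above twice the maximum radius, 70% of vesicles carrying
1–2 puncta, background offset 100, 16-bit range. These are the conditions
under which the recovery properties below are stated.

What the generator deliberately does **not** emulate: optical PSF convolution
beyond the Gaussian spot profile, Poisson (shot) statistics, photobleaching,
vesicle deformation or adhesion, and out-of-focus light. Passing recovery
tests therefore demonstrate the correctness of the pipeline's logic under a
clean, additive-Gaussian imaging model — not robustness to every artifact of
real confocal data. The import path for externally produced detections
(`import_detections`) exists precisely so that real-data detectors can be
swapped in.

## GUV recognition

The production analyses this package descends from used a trained neural
detector; a trained network is not reproducible from a text description, so
the default detector is deterministic: Canny edges feed a circular Hough
transform over the configured radius range `[r_min, r_max]`, peaks above
`min_score` (fraction of perimeter supported, default 0.35) become
candidates, and each candidate is refined against the ring's radial
intensity profile — a coarse intensity-weighted centroid over the local
window (the Hough center can sit a few pixels off on noisy rings), then the
argmax of the per-integer-radius mean intensity, then weighted-moment
polishing of center and radius. The Hough radius alone lands on a Canny edge
of the annulus, roughly one ring-thickness away from the intensity crest;
the refinement recovers the crest to sub-pixel accuracy on clean scenes.

Duplicates (center distance < 0.5·(r₁+r₂)) are suppressed keeping the higher
score — non-concentric vesicles never sit that close. Under
`edge_policy="exclude"`, candidate circles that exit the frame are dropped
*before* refinement: a partial rim at the frame edge must not be refined into
a spurious interior circle.

## Per-vesicle puncta pipeline

For each vesicle, the protein-channel crop (region bbox padded by `crop_pad`,
default 5 px) passes through a fixed stage order:

1. **Background subtraction** at the Li minimum-cross-entropy threshold
   computed on that crop, clipping at zero. The threshold is the level `t`
   minimizing `−[A₀ log(A₀/n₀) + A₁ log(A₁/n₁)]` over the classes `< t` /
   `≥ t` (A = intensity sum, n = count per class), found by exhaustive search
   over all integer levels via cumulative histogram moments; ties take the
   smallest level. A constant crop returns that constant.
2. **Non-local-means denoising** (`skimage.restoration.denoise_nl_means`,
   fast mode) with strength `nl_h` (default 10), patch size `nl_patch`
   (default 7) and search window `nl_search` (default 21, mapped to a patch
   distance of `(nl_search−1)/2`).
3. **Gaussian blur** with `blur_sigma` (default 1.0 px) to regularize spot
   shape.
4. **8-bit conversion and global histogram equalization** using the standard
   CDF lookup table (`round((cdf − cdf_min)/(N − cdf_min) · 255)`); a
   constant image maps to all zeros.
5. **Otsu masking**: the threshold minimizes within-class variance over all
   levels (exhaustive, smallest level on ties); the mask is `pixels > t`. A
   constant crop signals "no foreground", which propagates as zero puncta.
6. **Component labelling**: connected components (8-connectivity by default,
   4 available) with area strictly greater than `min_component_px = 5` are
   puncta — "larger than 5 pixels" is read literally as area ≥ 6.

Two numerical guards in stage 2–4 keep the chain meaningful on noisy crops.
Both are anchored to the crop's raw noise SD, wavelet-estimated
(`skimage.restoration.estimate_sigma`) before any smoothing, so they do not
drift with the denoiser settings:

* **Detection limit** — after denoising, the crop must rise at least
  `detection_limit_k` (default 3) raw-noise SDs above its median; otherwise
  it contains only residual noise from the unbound protein pool and is
  zeroed. Without this, rank-based equalization amplifies arbitrarily small
  residual ripple to full 8-bit range and every empty vesicle sprouts false
  puncta.
* **Noise floor** — the flat unbound-protein level that per-crop background
  subtraction leaves behind (the denoised median plus `noise_floor_k`
  (default 1) raw-noise SDs) is floored to zero before quantization, so that
  equalization assigns rank ~0 to background rather than promoting it.

With these defaults the planted-truth recovery (proportion of GUVs with
puncta, colocalization proportion) is stable across a ±50% sweep of `nl_h`,
`nl_patch`, `nl_search` and `blur_sigma` — robustness substitutes for filter
settings the underlying procedure did not pin down.

The `subtract_local_background` helper (mean of a ~10-px square sampled
outside the vesicle, subtracted from the whole channel) reproduces the
display-style background subtraction used for representative images; it is
not part of quantification.

### Readouts

* `proportion_guvs_with_puncta` = vesicles with ≥ 1 punctum / all vesicles.
* `colocalize`: a punctum is colocalized iff its (half-open, tight) bbox
  intersects at least one partner-channel bbox. The colocalized count is
  taken in the channel with more puncta and divided by that channel's total;
  when the counts tie, the larger of the two colocalized counts is used,
  which makes the proportion symmetric under channel swap. A punctum
  overlapping several partners counts once. Two empty channels give 0.
* `particle_area_above_threshold` reproduces the per-cell "above-threshold
  particle area" measure used for live-cell recruitment kinetics: binarize
  at an empirically chosen per-cell threshold, keep components of at least
  `min_area` pixels (default 1), sum their areas.

## Trajectory contact model

The in-memory trajectory is a labelled atom list (protein residue numbers;
lipid class PS/PC with headgroup/acyl region per atom; Ca²⁺ ions) plus
per-frame coordinates in nm in a periodic orthorhombic box. Multi-model PDB
is the interchange format (via MDAnalysis; GRO/XTC are accepted
transparently); PDB carries ångströms and no time axis, so coordinates are
converted on read and frame times are synthesised from a `dt_ps` argument
(default 2000 ps, the 2-ns analysis grid). A global CRYST1 record outside
the MODEL blocks is honoured by falling back to the topology's box.

Definitions:

* **Contact**: residue *i* is in contact in a frame iff any of its heavy
  atoms is within `contact_cutoff` of any lipid atom under the per-axis
  minimum-image convention. The cutoff defaults to 0.40 nm, a common
  heavy-atom convention; the underlying analyses did not state one, so it is
  config-exposed, and all synthetic tests are cutoff-agnostic by
  construction (scheduled distances sit in [0.7, 0.95]·cutoff, unscheduled
  in [1.5, 3]·cutoff). Hydrogens are excluded by default.
* **Class/region frequencies** use the corresponding lipid-atom subsets; a
  frame may contribute to both PS and PC frequencies, so `frequency_any` is
  not the sum.
* **Analysis window**: frequencies are computed over the trailing
  `analysis_window_ns` (default 1000 ns) subsampled at `sample_interval_ns`
  (default 2 ns) by nearest-time selection; the residues-in-contact series
  covers the full trajectory at the same sampling.
* **Replicate aggregation** requires identical time grids (no
  interpolation): pointwise mean and SE = SD/√n, plus each replicate's
  time-averaged count over the final window with across-replicate mean and
  sample SD. `compare_conditions` is a one-tailed pooled t-test for reduced
  binding (alternative: condition B < condition A); with zero variance in
  both groups and equal means the test is uninformative and returns p = 0.5
  by convention.
* **Coordination events** are maximal runs of consecutive sampled frames
  with the ion–lipid distance (minimum over that lipid's configured
  phosphate-oxygen names, default O11–O14) below 0.35 nm; duration = run
  length × frame spacing, so a 3-frame run on the 2-ns grid is 6 ns. Events
  are per ion–lipid pair: one ion bridging two lipids simultaneously yields
  two events. The per-ion distance to the nearest lipid atom of any type is
  returned alongside, supporting "held at > 0.5 nm" summaries.

### Synthetic trajectories

The generator scripts *when* each pseudo-residue or ion is in contact, not
how lipids move: lipids form a static planar lattice (2-nm spacing, ~30% PS
by a deterministic pattern) in a 14×14×10 nm box, with a laterally offset
acyl pseudo-atom per lipid so headgroup and acyl contacts are independently
addressable. In scheduled frames the actor sits directly above its dedicated
target atom at a distance drawn uniformly in [0.7, 0.95]·cutoff; otherwise
in [1.5, 3]·cutoff. The lattice geometry guarantees every other membrane
atom is at least half a lattice spacing away laterally, far outside both
bands, so the planted truth (per-residue contact frame sets by class/region,
per-ion event intervals) holds exactly for any analysis at the spec'd
cutoffs. Ion schedules place the ion above a dedicated PS phosphate oxygen
(O13) analogously around the 0.35-nm cutoff; unscheduled ion distances start
at 1.5 × 0.35 = 0.525 nm, which also realizes the "> 0.5 nm from the nearest
lipid atom" regime.

## Superposition

`kabsch_superpose` centers both point sets, takes the SVD of the covariance
`H = B₀ᵀ A₀`, and corrects the sign of the smallest singular direction so the
returned rotation is always proper (det = +1); reflections are never
returned, and a mirrored input therefore keeps a strictly positive RMSD.
Collinear point sets (second singular value ≈ 0) are rejected as degenerate.
`backbone_rmsd` pairs N/CA/C/O atoms (or a configured subset, e.g. CA-only)
by residue number across an inclusive range and reports the Kabsch-minimal
RMSD in Å; any missing residue or atom in the range is an error listing the
gaps. Matching is by author residue number — the intended comparisons are
same-protein model pairs, so no sequence alignment is attempted.

## Statistics

`unpaired_t_test` is the pooled-variance Student test (df = n₁+n₂−2) because
that is the test named by the assays this package supports; Welch's
correction is available behind a flag. `one_way_anova` is the standard
fixed-effects F = MS_between/MS_within. Degenerate conventions: identical
groups give t = 0 with p = 1 (two-tailed) or 0.5 (one-tailed); an
all-identical ANOVA gives F = 0, p = 1; zero within-group variance with
different means gives F = ∞, p = 0. `mean_sd_sem` uses the n−1 sample SD and
SEM = SD/√n. p-values come from scipy's t and F distributions; the tests
check them against closed-form hand computations and numerical integration
of the t density.

## Numerical choices and conventions

* Pixel coordinates are 0-based (row, col); all bounding boxes are half-open
  `[r0, r1) × [c0, c1)`.
* Thresholds operate on integer-quantized intensities (`rint`); both Li and
  Otsu break ties toward the smallest level, with the Li classes split as
  `< t` / `≥ t` (so a two-level crop thresholds strictly above the
  background level) and the Otsu mask strictly above the threshold.
* Internally coordinates are nm; PDB I/O converts to/from Å (1 = 10), and
  round trips are lossless to the 10⁻³ Å PDB precision.
* Histogram equalization maps a constant image to zero rather than to full
  scale — the convention that keeps "no structure" crops empty.
* CSV outputs are deterministically ordered (image id, region index) with
  ≥ 8 significant digits; repeated runs on fixed input are byte-identical.

## Problem sizes used in tests

The test suite and the acceptance script run on 256×256 scenes with 10
vesicles (50 scenes for recovery statistics, with the denoise-parameter
sweep on a 10-scene subset) and trajectories of 30–100 frames at 2-ns
spacing with ~135 atoms — small enough for exact brute-force oracles
(256-level threshold search, flood fill, run-length scans, rotation-space
minimization) to verify every operation, while exercising the identical code
paths used at production scale.

## Known limitations

* The circle detector assumes approximately circular, non-adherent vesicles
  well separated from their neighbours; clusters and strongly deformed
  vesicles are out of scope (use `import_detections` with an external
  detector).
* Colocalization is geometric (bounding boxes), not intensity-correlative;
  Pearson/Manders-style measures are deliberately out of scope.
* Only orthorhombic simulation boxes are supported, and the contact cutoff
  convention (heavy-atom, 0.40 nm) is a documented default rather than a
  community-universal constant.
* The equalization/Otsu stage quantizes to 8 bits regardless of the input
  bit depth; extremely low-contrast 16-bit puncta (below ~1/255 of the crop
  maximum after denoising) would be lost.
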