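# guvmem

Quantitative analysis of Ca²⁺-dependent protein recruitment to membranes, as
measured in giant unilamellar vesicle (GUV) reconstitution assays and in
molecular-dynamics simulations of a peripheral membrane-binding protein on
mixed PS/PC bilayers.

The package is aimed at researchers who image fluorescently labelled proteins
binding to GUVs (or simulate the same binding event) and need reproducible,
testable numbers out of those experiments:

* **GUV image analysis** — recognize individual vesicles in the lipid
  channel, call discrete protein puncta on each vesicle with a fixed
  thresholding/denoising chain, and compute the two standard readouts:
  the proportion of GUVs carrying at least one punctum, and the
  bounding-box colocalization proportion between two protein channels.
* **Trajectory contact analytics** — per-residue membrane contact
  frequencies split by lipid class (PS/PC) and region (headgroup/acyl
  tail), residues-in-contact time series with replicate mean ± SE, and
  detection of transient Ca²⁺–lipid coordination events.
* **Structure comparison** — Kabsch least-squares superposition and
  backbone RMSD over a residue range.
* **Statistics** — Student's unpaired t-test (one- or two-tailed),
  one-way ANOVA, and mean/SD/SEM summaries.

A first-class synthetic-data module generates confocal-style GUV scenes and
membrane trajectories with exact planted ground truth, so the entire pipeline
is testable end to end without any external data.

## The quantities computed

For an image with vesicles \(g = 1..N\) and per-vesicle punctum counts
\(k_g\), the recruitment readout is

    P(puncta) = |{g : k_g >= 1}| / N .

A punctum is a connected foreground component of more than 5 pixels in the
Otsu mask of the preprocessed per-vesicle crop (background subtraction at the
Li minimum-cross-entropy threshold → non-local-means denoising → Gaussian
blur → 8-bit histogram equalization). Two puncta from different channels are
colocalized when their bounding boxes intersect; the colocalization
proportion divides the colocalized count in the channel with more puncta by
that channel's total.

For a trajectory, residue *i* contacts the membrane in a frame when any of
its heavy atoms lies within the contact cutoff (default 0.40 nm) of any lipid
atom under the minimum-image convention; frequencies are percentages of the
analyzed frames (by default the final 1 μs sampled at 2-ns intervals). A
Ca²⁺–lipid coordination event is a maximal run of consecutive sampled frames
with the ion within 0.35 nm of a lipid's phosphate oxygens; its duration is
the run length times the frame spacing.

The Kabsch superposition returns the proper rotation R (det R = +1) and
translation minimizing RMSD = sqrt(mean ||R b_i + t − a_i||²) over paired
backbone atoms (N, CA, C, O by default), matched by residue number.

## Worked example

```bash
python examples/quantify_guv_scene.py
```

```
GUVs: planted 10, detected 10
proteinA: 7/10 GUVs with puncta -> proportion 0.70 (planted 0.70)
colocalization: 6/10 puncta in the majority channel overlap the partner channel -> proportion 0.60 (planted 0.70)
```

The scene plants puncta on 7 of 10 vesicles; the detector finds all ten
rings, and the puncta pipeline reproduces the planted proportion. The
colocalization estimate fluctuates around the planted value on a single
10-GUV scene and converges when scenes are pooled (see the acceptance
script). The other examples cover the trajectory analytics
(`membrane_contact_profile.py`, `calcium_coordination_events.py`) and
structure superposition (`backbone_superposition.py`); each prints the
numbers it computes and a line on how to read them.

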