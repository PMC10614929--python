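"""Quantify protein recruitment to GUV membranes in a synthetic scene.

Builds a two-protein-channel scene with known planted truth (7 of 10 vesicles
carry puncta; 60% of channel-B spots are planted on top of channel-A spots),
recognizes the vesicles in the lipid channel, runs the per-GUV puncta
pipeline, and prints the two headline readouts: the proportion of GUVs with
at least one punctum, and the bounding-box colocalization proportion.
"""

from guvmem import (
    DetectParams,
    detect_guvs,
    generate_guv_scene,
    quantify_guvs,
    random_scene_spec,
)

spec = random_scene_spec(
    seed=7, channel_roles=("lipid", "proteinA", "proteinB"), coloc_fraction=0.6
)
image, truth = generate_guv_scene(spec)

regions = detect_guvs(image.channel("lipid"), DetectParams(r_min=8, r_max=16))
print(f"GUVs: planted {len(truth.regions)}, detected {len(regions)}")

result = quantify_guvs(image, regions, ["proteinA", "proteinB"])
summary = result["summary"]["proteinA"]
print(
    f"proteinA: {summary.n_with_puncta}/{summary.n_guvs} GUVs with puncta "
    f"-> proportion {summary.proportion:.2f} "
    f"(planted {truth.proportion_with_puncta('proteinA'):.2f})"
)

num = den = 0
for coloc in result["coloc"][("proteinA", "proteinB")]:
    num += coloc.n_colocalized
    den += max(coloc.n_puncta.values())
print(
    f"colocalization: {num}/{den} puncta in the majority channel overlap the "
    f"partner channel -> proportion {num / den:.2f} "
    f"(planted {truth.coloc_proportion('proteinA', 'proteinB'):.2f})"
)
print(
    "A proportion near the planted value means the pipeline recovers membrane "
    "recruitment without counting noise as puncta."
)
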