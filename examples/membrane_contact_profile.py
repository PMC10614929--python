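"""Per-residue membrane contact frequencies and replicate statistics.

Generates two 'wild-type-like' replicate trajectories whose basic-patch
pseudo-residues (34, 37, 39) are scripted to touch PS lipids often, plus two
'mutant-like' replicates with sparse contacts, then reports contact
frequencies by lipid class, the residues-in-contact time series aggregated
across replicates, and a one-tailed t-test for reduced membrane binding.
"""

import numpy as np

from guvmem import (
    ContactParams,
    aggregate_replicates,
    compare_conditions,
    generate_trajectory,
    residue_lipid_contact_frequency,
    residues_in_contact_timeseries,
)
from guvmem.synthetic_data import TrajSpec

N_FRAMES = 100
RESIDUES = [30, 34, 37, 39, 54, 57]


def replicate(seed, contact_prob):
    rng = np.random.default_rng(seed)
    schedule = {}
    for resid in (34, 37, 39):  # the basic patch prefers PS headgroups
        frames = {f for f in range(N_FRAMES) if rng.uniform() < contact_prob}
        schedule[resid] = {"PS_headgroup": frames}
    trp = {f for f in range(N_FRAMES) if rng.uniform() < contact_prob * 0.6}
    schedule[57] = {"PS_acyl": trp}  # the aromatic anchor reaches the acyl core
    spec = TrajSpec(n_frames=N_FRAMES, residue_ids=RESIDUES,
                    contact_schedule=schedule, seed=seed)
    return generate_trajectory(spec)[0]


params = ContactParams(analysis_window_ns=100.0, sample_interval_ns=2.0)
wt = [replicate(seed, 0.8) for seed in (1, 2)]
mut = [replicate(seed, 0.1) for seed in (3, 4)]

profile = residue_lipid_contact_frequency(wt[0], params)
print("residue  any%   PS%    PC%    acyl%   (replicate 1, final 100 ns)")
for i, resid in enumerate(profile.residue_ids):
    print(
        f"  {resid:3d}   {profile.frequency_any[i]:5.1f}  "
        f"{profile.frequency_PS[i]:5.1f}  {profile.frequency_PC[i]:5.1f}  "
        f"{profile.frequency_acyl[i]:5.1f}"
    )

wt_series = [residues_in_contact_timeseries(t, params, f"wt{i}") for i, t in enumerate(wt)]
mut_series = [residues_in_contact_timeseries(t, params, f"mut{i}") for i, t in enumerate(mut)]
wt_agg = aggregate_replicates(wt_series, window_ns=100.0)
mut_agg = aggregate_replicates(mut_series, window_ns=100.0)
print(
    f"\nresidues in contact (time-averaged, final window): "
    f"wild-type {wt_agg.grand_mean:.2f} +/- {wt_agg.sd:.2f}, "
    f"mutant {mut_agg.grand_mean:.2f} +/- {mut_agg.sd:.2f}"
)

test = compare_conditions(wt_agg.replicate_means, mut_agg.replicate_means)
print(
    f"one-tailed t-test (mutant < wild-type): t = {test.statistic:.2f}, "
    f"df = {test.df:.0f}, p = {test.p_value:.4f}"
)
print(
    "High PS and zero PC frequencies for residues 34/37/39 reflect the scripted "
    "electrostatic preference; a small p supports reduced mutant binding."
)
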