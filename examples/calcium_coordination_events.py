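"""Detect Ca2+-lipid coordination events in a scripted trajectory.

Plants two ions: one with three short coordination episodes with a PS
phosphate oxygen (below the 0.35 nm cutoff) and one that never coordinates,
staying beyond 0.5 nm from any lipid atom.  Prints each detected event with
its duration, and the fraction of frames each ion spends within 0.5 nm of the
nearest lipid atom.
"""

from guvmem import ContactParams, detect_coordination_events, generate_trajectory
from guvmem.synthetic_data import TrajSpec

spec = TrajSpec(
    n_frames=60,
    residue_ids=[30],
    dt_ps=2000.0,
    ion_schedule={
        0: [(5, 5), (20, 22), (40, 44)],  # short-lived episodes
        1: [],                            # encaged ion, never coordinates
    },
    seed=12,
)
traj, truth = generate_trajectory(spec)

events, nearest = detect_coordination_events(traj, ContactParams())
print(f"detected {len(events)} coordination events "
      f"(planted {len(truth.events)}):")
for ev in events:
    print(
        f"  ion atom {ev.ion_index} with lipid residue {ev.lipid_residue}: "
        f"{ev.t_start_ns:.0f}-{ev.t_end_ns:.0f} ns, duration {ev.duration_ns:.0f} ns"
    )

for ion, (times, dists) in nearest.items():
    frac_far = (dists > 0.5).mean()
    print(
        f"ion atom {ion}: nearest-lipid distance > 0.5 nm in "
        f"{100 * frac_far:.0f}% of frames (min {dists.min():.2f} nm)"
    )
print(
    "Durations are multiples of the 2-ns sampling interval; the non-"
    "coordinating ion stays beyond 0.5 nm throughout, as scripted."
)
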