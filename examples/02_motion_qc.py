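"""Framewise displacement and the motion exclusion rules.

FD follows the Power convention (sum of absolute backward differences,
rotations scaled by a 50 mm head radius). Frames with FD > 0.5 mm are
flagged together with their immediate neighbors; a run with more than
40% flagged frames is excluded, and a participant must have four
retained runs to stay in the analysis.
"""

from fcgraph import compute_fd, evaluate_run, flag_frames, generate_motion
from fcgraph.motion import select_participants

clean = generate_motion(n_frames=300, contamination_level=0.0, seed=1)
spiky = generate_motion(n_frames=300, contamination_level=0.25, seed=1)

for name, trace in [("clean", clean), ("spiky", spiky)]:
    fd = compute_fd(trace)
    mask = flag_frames(fd, threshold=0.5)
    print(f"{name:6s} run: mean FD {fd.mean():.3f} mm, "
          f"{mask.n_flagged}/{mask.n_frames} frames flagged "
          f"({100 * mask.flagged_fraction:.0f}%) -> {evaluate_run(mask)}")

# participant-level rule: one bad run out of four excludes the participant
masks = {
    "good_participant": {
        f"run{r}": flag_frames(compute_fd(generate_motion(300, 0.0, seed=10 + r)))
        for r in range(4)
    },
    "bad_participant": {
        f"run{r}": flag_frames(
            compute_fd(generate_motion(300, 0.25 if r == 3 else 0.0, seed=20 + r))
        )
        for r in range(4)
    },
}
table = select_participants(masks)
print("\nparticipant decisions (retained needs 4 clean runs):")
print(table[["participant_id", "n_runs_excluded", "mean_fd", "retained"]]
      .to_string(index=False))
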