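"""Build the 13-feature windowed table for a small simulated study and
summarize the per-class contrast.

Each 60 s labeled segment yields two 30 s windows; per window the table
holds max/sd/mean of saccade velocities and durations, the saccade count,
and the same statistics for fixations.
"""

import gazeload as gl
from gazeload.evaluation import class_statistics
from gazeload.features import WindowSpec, build_feature_table
from gazeload.events import compute_velocity, segment_events

segments = gl.simulate_study(gl.GazeSimSpec(n_subjects=4, seed=5))
events = [segment_events(compute_velocity(s.trace)) for s in segments]
table = build_feature_table(
    events,
    WindowSpec(length=30.0),
    [s.label for s in segments],
    [s.subject_id for s in segments],
    segment_duration=60.0,
)
print(f"feature table: {len(table)} windows x {table.shape[1]} columns "
      f"({(table.label == 0).sum()} baseline, {(table.label == 1).sum()} one-back)")

stats = class_statistics(table)
for feat in ("avg_fixation_duration", "n_saccades"):
    rows = stats[stats.feature == feat].set_index("label")
    print(f"\n{feat}:")
    for label in (0, 1):
        r = rows.loc[label]
        print(f"  class {label}: avg {r['avg']:7.3f}  median {r['median']:7.3f}  "
              f"IQR [{r.q1:.3f}, {r.q3:.3f}]")
print("\nLonger fixations and fewer saccades under load are the separation "
      "the classifiers exploit.")
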