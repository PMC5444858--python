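"""Why the tracker offers several cost functions and solvers.

Slow peristaltic crawling leaves large frame-to-frame contour overlap, so
the Hungarian solver on overlap costs associates animals perfectly.  Fast
lateral displacement ("rolling") leaves zero overlap between consecutive
contours: every overlap-based assignment is rejected and identities
terminate, while a greedy nearest-center-of-mass matcher with a generous
distance threshold still follows the animals.
"""

from larvatrack import RunConfig, TrackingConfig, run_pipeline
from larvatrack.synthetic import make_scenario, render_scene, suggested_segmentation

spec = make_scenario("rolling", seed=0)
frames, truth = render_scene(spec)
seg = suggested_segmentation(spec)

overlap_trajs, _ = run_pipeline(frames, RunConfig(segmentation=seg))
print(f"overlap + Hungarian: {len(overlap_trajs)} trajectories, "
      f"{sum(not t.active for t in overlap_trajs)} terminated "
      f"(no contour overlap between consecutive frames)")

greedy = RunConfig(
    segmentation=seg,
    tracking=TrackingConfig(cost_method="com", solver="greedy", greedy_threshold=100.0),
)
greedy_trajs, _ = run_pipeline(frames, greedy)
print(f"center-of-mass + greedy (tau=100 px): {len(greedy_trajs)} trajectories, "
      f"all spanning {len(frames)} frames: "
      f"{all(len(t.models) == len(frames) for t in greedy_trajs)}")
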