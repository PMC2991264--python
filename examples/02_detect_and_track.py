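"""Segment a rendered movie and link detections into tracks.

Renders a short simulation, segments every frame (noise-floor threshold
+ distance-transform watershed), classifies foci vs patches by the
2.15 µm² area rule, links detections into tracks with merge/split
lineage, and prints what was recovered.
"""

from plaquedyn.detection import segment_stack
from plaquedyn.synthetic import preset_config, project_and_noise, render_movie, simulate_tracks
from plaquedyn.tracking import count_series, link_detections, nucleus_summary, tracks_to_dataframe

config = preset_config("wild_type", seed=4, n_frames=60)
truth = simulate_tracks(config)
stack, _ = render_movie(project_and_noise(truth), pixel_size_um=0.1, seed=4)

detections = segment_stack(stack, pixel_size_um=0.1)
n_foci = (detections["morph_class"] == "focus").sum()
n_patches = (detections["morph_class"] == "patch").sum()
print(f"{len(detections)} detections in {stack.shape[0]} frames: "
      f"{n_foci} foci (<2.15 um^2) and {n_patches} patches (>=2.15 um^2)")

tracks, events = link_detections(detections, gate_um=1.5, frame_interval_s=5.0)
series = count_series(tracks_to_dataframe(tracks), n_frames=stack.shape[0])
mean_n, min_n, max_n = nucleus_summary(series)
print(f"{len(tracks)} track identities; {len(events)} merge/split events in the link log")
print(f"aggregates per frame: mean {mean_n:.2f}, min {min_n:.0f}, max {max_n:.0f}")
print("note: aggregates that drift within a patch-width of each other merge "
      "optically, so segmented counts run below the true number — "
      "exactly why fusion/splitting is counted from the aggregate-number series")
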