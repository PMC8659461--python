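"""Render schematic face frames from a simulated trace and recover the
pupil positions with the vision pipeline (face detection, tracking,
binarize/invert/Sobel, circular Hough).

The printed mean absolute error is the per-frame distance between the
recovered pupil midpoint and the rendered ground truth, in pixels.
"""

import numpy as np

import gazeload as gl
from gazeload.synthetic import FrameRenderSpec, map_trace_to_frame
from gazeload.vision import extract_pupil_positions

trace = gl.simulate_trace(gl.default_class_params()[0], duration=100 / 30, fs=30, seed=7)
spec = FrameRenderSpec()
mapped = map_trace_to_frame(trace, spec)
frames, truth = gl.render_frames(mapped, spec)
recovered = extract_pupil_positions(frames, fps=30)

ok = recovered.valid
err = np.hypot(recovered.x[ok] - truth[ok, 0], recovered.y[ok] - truth[ok, 1])
print(f"frames rendered:      {len(frames)} ({spec.width}x{spec.height} px)")
print(f"pupils recovered in:  {ok.sum()} frames")
print(f"mean absolute error:  {err.mean():.2f} px (max {err.max():.2f} px)")
print("\nErrors at or below ~1 px mean the recovered gaze trace is a "
      "faithful stand-in for the rendered one, so downstream event "
      "segmentation sees the same saccade structure.")
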