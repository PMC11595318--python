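"""Render synthetic eye pairs with known pupil positions.

Builds a normal pair and a pair with an injected esotropic deviation of the
right eye, and prints the ground-truth pupil points.  For the normal pair
both eyes share the same crop-normalized offset from centre (synchronized
gaze); for the deviated pair the right pupil is displaced nasally by
exactly the deviation magnitude.
"""

from strabiscreen import EyeAppearance, GazeSample, StrabismusProfile, render_pair

appearance = EyeAppearance(noise_sd=0.02)

normal = render_pair(GazeSample(gaze_x=0.06, gaze_y=-0.03), appearance, size_px=128)
print("normal pair:")
print("  left pupil  (norm):", tuple(round(v, 4) for v in normal.true_left_pupil))
print("  right pupil (norm):", tuple(round(v, 4) for v in normal.true_right_pupil))
print("  -> identical offsets: the eyes move in synchrony")

profile = StrabismusProfile(
    deviation_magnitude=0.12, deviation_direction="eso", deviated_eye="right"
)
dx, dy = profile.deviation_vector()
deviated = render_pair(
    GazeSample(
        gaze_x=0.06, gaze_y=-0.03, deviation_x=dx, deviation_y=dy,
        deviated_eye="right",
    ),
    appearance,
    size_px=128,
)
print("\nesotropic pair (right eye, magnitude 0.12):")
print("  left pupil  (norm):", tuple(round(v, 4) for v in deviated.true_left_pupil))
print("  right pupil (norm):", tuple(round(v, 4) for v in deviated.true_right_pupil))
print("  -> the right pupil sits 0.12 crop-widths nasal (-x) of the shared gaze,")
print("     i.e.", round(0.12 * 128, 1), "px at the 128-px render size")
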