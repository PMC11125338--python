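"""Detect the takeover onset of one episode and extract windowed features.

Onset = earliest post-TOR crossing of >2 deg steering deviation or >10%
pedal press.  Features are then computed on half-open windows starting
0, 2, ..., 12 s after the onset.
"""

from tostab import (build_window_grid, compute_window_features,
                    detect_takeover_onset, generate_study)
from tostab.config import StudyBlock, StudyConfig

dataset = generate_study(StudyConfig(studies=(StudyBlock(1, 1, 1),)), seed=3)
recording = dataset.recordings[0]

onset = detect_takeover_onset(recording)
print(f"TOR at {recording.tor_time:.2f} s; onset {onset.time:.2f} s after the "
      f"TOR via the {onset.action} (reaction time)")

grid = build_window_grid(length=2.0)
features = compute_window_features(
    recording, onset, grid, variables=("winding", "speed", "eoff", "pd"))
wide = features.pivot_table(index="window_start_s", columns="variable",
                            values="value")
print("\nper-window features (2 s windows):")
print(wide.round(3).to_string())
# winding (deg) and the baseline-shifted pupil diameter (mm) decay toward
# their settled levels; speed (km/h) dips under braking and recovers; the
# eyes-off-road ratio drops to its settled scanning level within ~2 s.
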