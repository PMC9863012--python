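"""Generate one synthetic wrist-accelerometer recording and inspect it.

The generator emulates a 10 Hz, +/-8 g wrist recording: gravity on z, a
daily rest-activity cycle, nocturnal movement bouts, daytime rest episodes
and sensor noise.
"""

import numpy as np

from actipheno import DEFAULT_PROFILES, Group, simulate_recording

profile = DEFAULT_PROFILES[Group.C]
rec = simulate_recording(profile, days=3, seed=1)

print(f"subject {rec.subject_id}: {rec.n_samples} samples "
      f"({rec.duration_seconds / 86400:.1f} days at {rec.sampling_rate:g} Hz)")
print(f"axis ranges (g): x [{rec.x.min():.2f}, {rec.x.max():.2f}], "
      f"z [{rec.z.min():.2f}, {rec.z.max():.2f}]")
print(f"mean z = {rec.z.mean():.3f} g   <- gravity sits on the z axis")
# daytime samples move much more than nighttime ones
day = rec.x[:int(3600 * rec.sampling_rate)]          # first hour (afternoon)
night = rec.x[int(12 * 3600 * rec.sampling_rate):
              int(13 * 3600 * rec.sampling_rate)]    # around midnight
print(f"x-axis sd: afternoon {np.std(day):.4f} g vs night {np.std(night):.4f} g")
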