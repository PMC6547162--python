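"""Sample a line profile between two kinetochores and rank its peaks.

When cohesin sits between bioriented kinetochores, its GFP signal is
read along the segment joining the two tdTomato centroids: both
channels are sampled over the same coordinates and the two brightest
local maxima of the green profile are reported.
"""

import numpy as np

import meioquant as mq

# a synthetic projected frame: two red kinetochore foci with a green
# cohesin peak halfway between them
red = np.full((40, 40), 10.0)
green = np.full((40, 40), 10.0)
yy, xx = np.mgrid[0:40, 0:40]
for cy, cx, amp, img in [(20, 12, 200, red), (20, 28, 200, red), (20, 20, 90, green)]:
    img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 1.5**2))
green += 0.3 * red  # bleed-through makes green peaks at the kinetochores too

profile = mq.sample_line({"red": red, "green": green}, (20.0, 12.0), (20.0, 28.0))
peaks = mq.two_brightest_peaks(profile, "green")

print(f"profile: {profile.n_samples} samples over {profile.positions[-1]:.1f} px")
print(f"two brightest green peaks: {peaks.value_1:.1f} AU at {peaks.position_1:.0f} px, "
      f"{peaks.value_2:.1f} AU at {peaks.position_2:.0f} px")
# The brighter peak is the mid-segment cohesin signal; peak positions
# are distances from the first kinetochore along the profile.
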