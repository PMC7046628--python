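"""Depth-resolved intensity profile and 50%/90% signal-decay depths.

Simulates a uniformly stained sample with a known attenuation length
L = 100 μm, extracts the central-ROI z-profile and compares the measured
decay depths with the Beer–Lambert predictions L·ln2 and L·ln10.
"""

import numpy as np

from spheroquant import SimulationConfig, decay_depths, generate_spheroid, z_profile

L = 100.0
cfg = SimulationConfig(
    diameter=1000.0, n_nuclei=0, channel_names=("TRACKER",),
    channel_kinds=("volume",), attenuation_length=(L,), amplitude=(40000.0,),
    background_offset=0.0, background_sigma=0.0, psf_sigma=(0.0, 0.0, 0.0),
    center_depth=0.0, margin=0.0, pixel_size=3.0, seed=1,
)
stack, _ = generate_spheroid(cfg)
profile = z_profile(stack, "TRACKER", roi_diameter_um=100.0)
metrics = decay_depths(profile)

print(f"attenuation length L = {L} um")
print(f"measured d50 = {metrics.d50_um:.2f} um  (L ln2  = {L*np.log(2):.2f})")
print(f"measured d90 = {metrics.d90_um:.2f} um  (L ln10 = {L*np.log(10):.2f})")
# d50/d90 are the depths where the ROI-mean intensity first falls to 50%
# and 10% of its maximum; on an exact exponential they match the analytic
# crossings to sub-z-step accuracy thanks to linear interpolation.
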