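"""Per-slice SNR and the Rose-criterion cutoff depth, ± z-compensation.

Generates matched spheroid stacks with and without a depth gain that
offsets attenuation (z-compensation) and shows how SNR uniformity and the
usable imaging depth (SNR > 5) change.
"""

import numpy as np

from spheroquant import SimulationConfig, generate_spheroid, rose_cutoff, snr_profile
from spheroquant.synthgen import matched_zcomp_slope

L = 40.0
for label, slope in [("z-compensated", matched_zcomp_slope(L, 1.5)),
                     ("uncompensated", 0.0)]:
    cfg = SimulationConfig(diameter=130.0, n_nuclei=200, pixel_size=0.8,
                           seed=5, attenuation_length=(L, L), zcomp_slope=slope)
    stack, truth = generate_spheroid(cfg)
    prof = snr_profile(stack, "DRAQ5", roi_diameter_um=80.0)
    cut = rose_cutoff(prof)
    # coefficient of variation over slices inside the spheroid
    zmin, zmax = truth.centers[:, 0].min(), truth.centers[:, 0].max()
    sel = (prof.depths_um >= zmin) & (prof.depths_um <= zmax) & np.isfinite(prof.snr)
    cv = prof.snr[sel].std() / prof.snr[sel].mean()
    print(f"{label}: max SNR {np.nanmax(prof.snr):.1f}, "
          f"slice-CV {cv:.2f}, Rose cutoff {cut}")
# SNR = mean nuclear-mask intensity / background SD (scalar, from shallow
# slices). The Rose criterion (SNR > 5) marks the depth to which objects
# remain reliably detectable; a censored cutoff ("> d") means the whole
# stack qualified.
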