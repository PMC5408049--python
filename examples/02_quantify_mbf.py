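"""Quantify myocardial blood flow from a phantom series.

Extracts the arterial input function from the simulated descending aorta
(double sampling over both shuttle stacks), fits the hybrid deconvolution
model per voxel, and compares the sector-mean MBF of the resulting map with
the generating truth.
"""

import numpy as np

from ctmpi import (
    PhantomSpec,
    SectorSpec,
    compute_mbf_map,
    extract_aif,
    generate_phantom,
)
from ctmpi.phantom import myocardium_mask

spec = PhantomSpec(
    sectors=[
        SectorSpec(angle_start_deg=0, angle_end_deg=180, mbf_epi=95.0,
                   transmural_ratio=1.0, territory_label="LAD",
                   reference_ffr=0.9),
        SectorSpec(angle_start_deg=180, angle_end_deg=360, mbf_epi=55.0,
                   transmural_ratio=1.0, territory_label="LCX",
                   reference_ffr=0.7),
    ],
    noise_sd_hu=10.0,
    seed=2,
)
series, truth = generate_phantom(spec)

aif = extract_aif(series)
p = aif.fitted_params
print(f"AIF fit converged: {aif.fit_converged}; peak {aif.max_value_hu:.0f} "
      f"HU above baseline at t = {p.peak_time_s:.1f} s")

mbf_map = compute_mbf_map(series, aif, myocardium_mask(spec))
for i, sec in enumerate(truth.sectors):
    sel = (truth.sector_of_voxel == i) & mbf_map.mask
    est = float(np.mean(mbf_map.mbf[sel]))
    true = truth.true_mean_mbf_per_sector[i]
    print(f"{sec.territory_label}: estimated {est:6.1f} vs true {true:6.1f} "
          f"ml/100 ml/min ({100 * (est - true) / true:+.1f} %)")
# Sector means recover the generating flows to within a few percent even at
# 10 HU attenuation noise; the maximal-slope readout is linear in flow.
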