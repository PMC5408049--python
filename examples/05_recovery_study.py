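"""Recovery study: MBF and TPR accuracy across noise and global flow scale.

Runs the full phantom -> quantification -> TPR chain over a grid of
transmural ratios, noise levels and a global-flow-scaling arm, reporting
bias and RMSE per cell.  The scaling arm demonstrates the motivating
property of the relative TPR index: scaling all true flows by 0.7 shifts
absolute MBF estimates proportionally but leaves the TPR error untouched.
"""

import pandas as pd

from ctmpi import PhantomSpec, SectorSpec, recovery_study

spec = PhantomSpec(
    grid_nx=96, grid_ny=96, endo_radius_mm=5.0, epi_radius_mm=10.0,
    aorta_center_mm=(30.0, 8.0), aorta_radius_mm=2.5,
    sectors=[SectorSpec(angle_start_deg=0, angle_end_deg=360, mbf_epi=90.0,
                        transmural_ratio=1.0, territory_label="LAD",
                        reference_ffr=0.9)],
    seed=0,
)
table = recovery_study(
    spec, ratios=(0.64, 1.0), noise_levels=(0.0, 10.0), seeds=(0, 1),
    flow_scales=(1.0, 0.7),
)
pd.set_option("display.width", 120)
print(table.round(3).to_string(index=False))
# mbf_bias is in ml/100 ml/min against the scaled truth of each arm;
# tpr_bias is dimensionless.  The TPR columns barely move between the
# flow_scale arms, while absolute MBF tracks the global scaling.
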