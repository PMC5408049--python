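"""Measure the transmural perfusion ratio on an estimated MBF map.

Samples radial lines across the wall at 0.4-mm depth steps, averages them
into a transmural MBF profile, and reads subendocardial and subepicardial
MBF from depth bands that avoid the artifact-prone borders.  Also shows the
manual worked example: endo 58 and epi 91 ml/100 ml/min give TPR 0.64.
"""

from ctmpi import (
    PhantomSpec,
    SectorSpec,
    WallBand,
    compute_mbf_map,
    compute_tpr,
    extract_aif,
    generate_phantom,
    sample_profile,
    select_endo_epi,
)
from ctmpi.phantom import myocardium_mask

spec = PhantomSpec(
    endo_radius_mm=8.0, epi_radius_mm=14.0,
    sectors=[SectorSpec(angle_start_deg=0, angle_end_deg=360, mbf_epi=91.0,
                        transmural_ratio=0.64, territory_label="LAD",
                        reference_ffr=0.69)],
    noise_sd_hu=10.0, seed=3,
)
series, truth = generate_phantom(spec)
mbf_map = compute_mbf_map(series, extract_aif(series), myocardium_mask(spec))

band = WallBand(center_mm=spec.center_mm, endo_radius_mm=8.0,
                epi_radius_mm=14.0)
profile = sample_profile(mbf_map, 0, band)
print(f"profile: {len(profile.depths_mm)} depth samples at "
      f"{profile.step_mm} mm steps, averaged over {profile.n_lines} lines")
auto = select_endo_epi(profile, mode="auto")
print(f"auto selection: endo {auto.endo_mbf:.1f} at {auto.endo_depth_mm:.1f} "
      f"mm, epi {auto.epi_mbf:.1f} at {auto.epi_depth_mm:.1f} mm "
      f"-> TPR {auto.tpr:.2f} (generated ratio 0.64)")

print(f"worked example: TPR = 58/91 = {compute_tpr(58.0, 91.0):.2f} "
      "-> positive for ischaemia at the 0.82 threshold")
# The auto-mode TPR recovers the generated endo/epi flow ratio; a value
# at or below 0.82 classifies the territory as ischaemic.
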