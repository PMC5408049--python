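import numpy as np
import pytest

from ctmpi import PhantomSpec, SectorSpec


def uniform_sectors(mbf_epi=90.0, transmural_ratio=1.0, ffr=0.90):
    return [SectorSpec(angle_start_deg=0, angle_end_deg=360,
                       mbf_epi=mbf_epi, transmural_ratio=transmural_ratio,
                       territory_label="LAD", reference_ffr=ffr)]


@pytest.fixture
def make_spec():
    """Factory for small, fast phantom specs (96 px grid, 5/10 mm annulus)."""

    def _make(**kw):
        base = dict(
            grid_nx=96, grid_ny=96, pixel_mm=0.35, n_slices=2,
            endo_radius_mm=5.0, epi_radius_mm=10.0,
            aorta_center_mm=(30.0, 8.0), aorta_radius_mm=2.5,
            noise_sd_hu=0.0, seed=0,
            sectors=uniform_sectors(),
        )
        base.update(kw)
        return PhantomSpec(**base)

    return _make


@pytest.fixture
def make_wide_spec():
    """Thicker-wall variant (9 mm wall) for transmural profiling tests."""

    def _make(**kw):
        base = dict(
            grid_nx=96, grid_ny=96, pixel_mm=0.35, n_slices=2,
            endo_radius_mm=5.0, epi_radius_mm=14.0,
            aorta_center_mm=(29.0, 4.0), aorta_radius_mm=2.5,
            noise_sd_hu=0.0, seed=0,
            sectors=uniform_sectors(),
        )
        base.update(kw)
        return PhantomSpec(**base)

    return _make


@pytest.fixture
def annulus_mask():
    from ctmpi.phantom import myocardium_mask

    return myocardium_mask


@pytest.fixture
def truth_map():
    """Build an MBFMap directly from a phantom's ground truth (isolates the
    transmural stage from estimation error)."""
    from ctmpi import MBFMap
    from ctmpi.phantom import generate_phantom

    def _make(spec):
        _, truth = generate_phantom(spec)
        mask = truth.annulus_mask
        mbf = np.where(mask, truth.true_mbf, np.nan)
        return MBFMap(mbf=mbf, mask=mask, pixel_mm=spec.pixel_mm,
                      slice_thickness_mm=spec.slice_thickness_mm), truth

    return _make
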