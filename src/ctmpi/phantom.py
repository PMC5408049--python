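"""Digital dynamic perfusion phantom with known ground truth.

Emulates a short-axis left-ventricular annulus imaged in shuttle mode: two
slightly overlapping stacks (cranial / caudal) acquired at alternating table
positions, one position per alternate heartbeat, so each stack is sampled
every ``2 * 60 / heart_rate_bpm`` seconds and the two time grids interleave.
A homogeneous disk outside the annulus plays the descending aorta and carries
the arterial input function.  Sector-shaped wedges of the annulus receive a
transmural flow pattern (reduced subendocardial flow for ischaemic sectors),
and every voxel's time-attenuation curve is the flow-scaled box-residue
convolution of the AIF sampled on its stack's time grid plus i.i.d. Gaussian
attenuation noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .kinetics import AifParams, box_response, MBF_UNITS_PER_S

__all__ = [
    "AifParams",
    "SectorSpec",
    "PhantomSpec",
    "DynamicPerfusionSeries",
    "GroundTruth",
    "generate_phantom",
    "myocardium_mask",
]

STACKS = ("cranial", "caudal")


class SectorSpec(BaseModel):
    """One coronary-territory wedge of the myocardial annulus.

    Angles are degrees counter-clockwise from the positive x axis; the wedge
    covers [angle_start_deg, angle_end_deg).  ``mbf_epi`` is the true
    subepicardial flow, ``transmural_ratio`` the true endo/epi flow ratio and
    ``reference_ffr`` the invasive fractional flow reserve assigned to the
    feeding vessel (<= 0.80 marks a haemodynamically significant stenosis).
    """

    angle_start_deg: float
    angle_end_deg: float
    mbf_epi: float = Field(gt=0)
    transmural_ratio: float = Field(gt=0)
    territory_label: Literal["LAD", "LCX", "RCA"]
    reference_ffr: float = Field(gt=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "SectorSpec":
        if not (0 <= self.angle_start_deg < self.angle_end_deg <= 360):
            raise ValueError("sector angles must satisfy 0 <= start < end <= 360")
        return self


class PhantomSpec(BaseModel):
    """Full description of a synthetic dynamic perfusion acquisition."""

    grid_nx: int = Field(default=160, gt=0)
    grid_ny: int = Field(default=160, gt=0)
    pixel_mm: float = Field(default=0.35, gt=0)
    n_slices: int = Field(default=2, gt=0)
    slice_thickness_mm: float = Field(default=3.0, gt=0)
    lv_center_mm: tuple[float, float] | None = None
    endo_radius_mm: float = Field(default=8.0, gt=0)
    epi_radius_mm: float = Field(default=14.0, gt=0)
    sectors: list[SectorSpec]
    baseline_hu: float = 45.0
    noise_sd_hu: float = Field(default=10.0, ge=0)
    heart_rate_bpm: float = Field(default=83.0, gt=0)
    n_timepoints: int = Field(default=12, ge=9, le=14)
    start_time_s: float = Field(default=5.0, ge=0)
    aif_params: AifParams = AifParams(
        amplitude=300.0, onset_s=8.0, shape_alpha=3.0, scale_beta=1.5,
        baseline_hu=45.0,
    )
    transit_time_s: float = Field(default=8.0, gt=0)
    delay_s: float = Field(default=0.0, ge=0)
    profile_shape: Literal["step", "linear"] = "step"
    aorta_center_mm: tuple[float, float] | None = None
    aorta_radius_mm: float = Field(default=4.0, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PhantomSpec":
        if not (self.epi_radius_mm > self.endo_radius_mm > 0):
            raise ValueError("need epi_radius_mm > endo_radius_mm > 0")
        if not self.sectors:
            raise ValueError("sector list must not be empty")
        ordered = sorted(self.sectors, key=lambda s: s.angle_start_deg)
        if ordered[0].angle_start_deg != 0 or ordered[-1].angle_end_deg != 360:
            raise ValueError("sector spans must cover [0, 360) exactly")
        for a, b in zip(ordered, ordered[1:]):
            if not math.isclose(a.angle_end_deg, b.angle_start_deg):
                raise ValueError("sector spans must partition [0, 360) without "
                                 "gaps or overlap")
        return self

    @property
    def center_mm(self) -> tuple[float, float]:
        if self.lv_center_mm is not None:
            return self.lv_center_mm
        return (self.grid_nx * self.pixel_mm / 2.0,
                self.grid_ny * self.pixel_mm / 2.0)

    @property
    def aorta_center(self) -> tuple[float, float]:
        if self.aorta_center_mm is not None:
            return self.aorta_center_mm
        cx, cy = self.center_mm
        return (cx, cy + self.epi_radius_mm + 6.0 + self.aorta_radius_mm)


@dataclass
class DynamicPerfusionSeries:
    """4-D attenuation data with per-stack acquisition times.

    volumes : float array (n_slices, ny, nx, n_timepoints), HU.  The time
        axis of slice ``s`` refers to ``times_s[stack_index(s)]``.
    times_s : float array (2, n_timepoints); row 0 cranial, row 1 caudal.
    stack_of_slice : per-slice stack name ("cranial" / "caudal").
    aif_region : int array (k, 3) of (slice, y, x) voxel indices inside the
        simulated descending aorta.
    """

    volumes: np.ndarray
    times_s: np.ndarray
    stack_of_slice: tuple[str, ...]
    pixel_mm: float
    slice_thickness_mm: float
    aif_region: np.ndarray

    def stack_index(self, slice_index: int) -> int:
        return STACKS.index(self.stack_of_slice[slice_index])

    def times_for_slice(self, slice_index: int) -> np.ndarray:
        return self.times_s[self.stack_index(slice_index)]

    @property
    def merged_times(self) -> np.ndarray:
        return np.sort(self.times_s.ravel())


@dataclass
class GroundTruth:
    """Per-voxel truth emitted alongside the phantom volumes."""

    true_mbf: np.ndarray          # (n_slices, ny, nx), ml/100 ml/min, 0 outside
    sector_of_voxel: np.ndarray   # (n_slices, ny, nx) int, -1 outside annulus
    true_tpr_per_sector: dict[int, float]
    true_mean_mbf_per_sector: dict[int, float]
    true_aif: AifParams
    sectors: list[SectorSpec] = field(default_factory=list)
    annulus_mask: np.ndarray | None = None


def _annulus_geometry(spec: PhantomSpec):
    """Radius, angle and annulus mask on the 2-D pixel grid (mm units)."""
    cx, cy = spec.center_mm
    x = (np.arange(spec.grid_nx) + 0.5) * spec.pixel_mm
    y = (np.arange(spec.grid_ny) + 0.5) * spec.pixel_mm
    xx, yy = np.meshgrid(x, y)          # (ny, nx)
    r = np.hypot(xx - cx, yy - cy)
    theta = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0
    annulus = (r >= spec.endo_radius_mm) & (r <= spec.epi_radius_mm)
    return r, theta, annulus


def true_flow_map(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """2-D (ny, nx) true MBF map and sector-index map (-1 outside annulus).

    Transmural pattern per sector, as a function of wall depth fraction
    w in [0, 1] (0 at the endocardial border):

    - "step": flow = mbf_epi * transmural_ratio for w < 0.5, mbf_epi above —
      the endo-half / epi-half mean ratio then equals transmural_ratio.
    - "linear": flow ramps from mbf_epi * transmural_ratio at the endocardial
      border to mbf_epi at the epicardial border.
    """
    r, theta, annulus = _annulus_geometry(spec)
    w = (r - spec.endo_radius_mm) / (spec.epi_radius_mm - spec.endo_radius_mm)
    flow = np.zeros_like(r)
    sector_idx = np.full(r.shape, -1, dtype=int)
    for i, sec in enumerate(spec.sectors):
        in_sec = annulus & (theta >= sec.angle_start_deg) & (theta < sec.angle_end_deg)
        sector_idx[in_sec] = i
        if spec.profile_shape == "step":
            frac = np.where(w < 0.5, sec.transmural_ratio, 1.0)
        else:
            frac = sec.transmural_ratio + (1.0 - sec.transmural_ratio) * w
        flow[in_sec] = sec.mbf_epi * frac[in_sec]
    return flow, sector_idx


def shuttle_times(spec: PhantomSpec) -> np.ndarray:
    """(2, n_timepoints) acquisition times; one table position per alternate
    heartbeat, so each stack samples every 2 RR intervals and the caudal grid
    is offset by one RR interval from the cranial grid."""
    rr = 60.0 / spec.heart_rate_bpm
    base = spec.start_time_s + 2.0 * rr * np.arange(spec.n_timepoints)
    return np.vstack([base, base + rr])


def _check_bounds(spec: PhantomSpec) -> None:
    fx = spec.grid_nx * spec.pixel_mm
    fy = spec.grid_ny * spec.pixel_mm
    cx, cy = spec.center_mm
    if (cx - spec.epi_radius_mm < 0 or cx + spec.epi_radius_mm > fx
            or cy - spec.epi_radius_mm < 0 or cy + spec.epi_radius_mm > fy):
        raise ValueError("annulus exceeds grid bounds")
    ax, ay = spec.aorta_center
    ra = spec.aorta_radius_mm
    if ax - ra < 0 or ax + ra > fx or ay - ra < 0 or ay + ra > fy:
        raise ValueError("aorta region exceeds grid bounds")
    if np.hypot(ax - cx, ay - cy) < spec.epi_radius_mm + ra:
        raise ValueError("aorta region overlaps the myocardial annulus")


def myocardium_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean (n_slices, ny, nx) annulus mask for a phantom spec — the
    natural quantification mask for its series."""
    _, _, annulus = _annulus_geometry(spec)
    return np.broadcast_to(annulus, (spec.n_slices, *annulus.shape)).copy()


def generate_phantom(spec: PhantomSpec) -> tuple[DynamicPerfusionSeries, GroundTruth]:
    """Generate a seeded dynamic perfusion series plus its ground truth.

    All stochastic draws come from ``numpy.random.default_rng(spec.seed)``;
    the same spec always yields bit-identical volumes.
    """
    _check_bounds(spec)
    flow2d, sector2d = true_flow_map(spec)
    _, _, annulus2d = _annulus_geometry(spec)

    cx, cy = spec.aorta_center
    x = (np.arange(spec.grid_nx) + 0.5) * spec.pixel_mm
    y = (np.arange(spec.grid_ny) + 0.5) * spec.pixel_mm
    xx, yy = np.meshgrid(x, y)
    aorta2d = np.hypot(xx - cx, yy - cy) <= spec.aorta_radius_mm

    times = shuttle_times(spec)
    ns, ny, nx, nt = spec.n_slices, spec.grid_ny, spec.grid_nx, spec.n_timepoints
    n_cranial = math.ceil(ns / 2)
    stack_of_slice = tuple(
        "cranial" if s < n_cranial else "caudal" for s in range(ns)
    )

    # per-stack model ingredients at that stack's sample times
    resp = {
        k: box_response(times[k], spec.aif_params, spec.transit_time_s, spec.delay_s)
        for k in range(2)
    }
    aif_vals = {k: spec.aif_params.curve(times[k]) for k in range(2)}

    volumes = np.empty((ns, ny, nx, nt), dtype=float)
    for s in range(ns):
        k = 0 if stack_of_slice[s] == "cranial" else 1
        sl = np.full((ny, nx, nt), spec.baseline_hu, dtype=float)
        f = flow2d[annulus2d] / MBF_UNITS_PER_S            # (n_annulus,)
        sl[annulus2d] = spec.baseline_hu + f[:, None] * resp[k][None, :]
        sl[aorta2d] = aif_vals[k][None, :]
        volumes[s] = sl

    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        volumes = volumes + rng.normal(0.0, spec.noise_sd_hu, size=volumes.shape)

    aif_idx = np.argwhere(aorta2d)                          # (k, 2) as (y, x)
    aif_region = np.concatenate(
        [np.column_stack([np.full(len(aif_idx), s), aif_idx]) for s in range(ns)]
    ).astype(int)

    series = DynamicPerfusionSeries(
        volumes=volumes,
        times_s=times,
        stack_of_slice=stack_of_slice,
        pixel_mm=spec.pixel_mm,
        slice_thickness_mm=spec.slice_thickness_mm,
        aif_region=aif_region,
    )

    # ground truth replicated over slices
    true_mbf = np.broadcast_to(flow2d, (ns, ny, nx)).copy()
    sector_of_voxel = np.broadcast_to(sector2d, (ns, ny, nx)).copy()
    r, _, _ = _annulus_geometry(spec)
    w = (r - spec.endo_radius_mm) / (spec.epi_radius_mm - spec.endo_radius_mm)
    tpr, mean_mbf = {}, {}
    for i in range(len(spec.sectors)):
        in_sec = sector2d == i
        endo_half = in_sec & (w < 0.5)
        epi_half = in_sec & (w >= 0.5)
        tpr[i] = float(flow2d[endo_half].mean() / flow2d[epi_half].mean())
        mean_mbf[i] = float(flow2d[in_sec].mean())
    truth = GroundTruth(
        true_mbf=true_mbf,
        sector_of_voxel=sector_of_voxel,
        true_tpr_per_sector=tpr,
        true_mean_mbf_per_sector=mean_mbf,
        true_aif=spec.aif_params,
        sectors=list(spec.sectors),
        annulus_mask=np.broadcast_to(annulus2d, (ns, ny, nx)).copy(),
    )
    return series, truth
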