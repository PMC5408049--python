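"""Reading and writing the volume containers used by the pipeline.

A dynamic series is stored as a 4-D NIfTI volume (slice, y, x, time on the
4th axis) with a JSON sidecar carrying acquisition times, stack assignment,
geometry and the AIF region; ground truth as a NIfTI MBF volume plus a
per-sector CSV; MBF maps as a NIfTI volume (NaN outside the mask) plus a
JSON sidecar.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .kinetics import AifParams
from .mbf import MBFMap
from .phantom import DynamicPerfusionSeries, GroundTruth, SectorSpec

__all__ = [
    "save_series",
    "load_series",
    "save_ground_truth",
    "load_ground_truth",
    "save_mbf_map",
    "load_mbf_map",
    "sha256_of",
    "write_json",
]


def _affine(pixel_mm: float, slice_thickness_mm: float) -> np.ndarray:
    return np.diag([slice_thickness_mm, pixel_mm, pixel_mm, 1.0])


def write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def sha256_of(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def save_series(series: DynamicPerfusionSeries, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(series.volumes.astype(np.float32),
                          _affine(series.pixel_mm, series.slice_thickness_mm))
    nib.save(img, out_dir / "series.nii.gz")
    write_json(out_dir / "series.json", {
        "axis_order": ["slice", "y", "x", "time"],
        "times_s": series.times_s.tolist(),
        "stack_of_slice": list(series.stack_of_slice),
        "pixel_mm": series.pixel_mm,
        "slice_thickness_mm": series.slice_thickness_mm,
        "aif_region": series.aif_region.tolist(),
    })
    return out_dir


def load_series(in_dir: str | Path) -> DynamicPerfusionSeries:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "series.json").read_text())
    vol = np.asarray(nib.load(in_dir / "series.nii.gz").get_fdata(),
                     dtype=float)
    return DynamicPerfusionSeries(
        volumes=vol,
        times_s=np.asarray(meta["times_s"], float),
        stack_of_slice=tuple(meta["stack_of_slice"]),
        pixel_mm=float(meta["pixel_mm"]),
        slice_thickness_mm=float(meta["slice_thickness_mm"]),
        aif_region=np.asarray(meta["aif_region"], int),
    )


def save_ground_truth(truth: GroundTruth, out_dir: str | Path,
                      pixel_mm: float = 0.35,
                      slice_thickness_mm: float = 3.0) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(pixel_mm, slice_thickness_mm)
    nib.save(nib.Nifti1Image(truth.true_mbf.astype(np.float32), aff),
             out_dir / "true_mbf.nii.gz")
    nib.save(nib.Nifti1Image(truth.sector_of_voxel.astype(np.int16), aff),
             out_dir / "sector_of_voxel.nii.gz")
    rows = []
    for i, sec in enumerate(truth.sectors):
        rows.append({
            "sector": i,
            "territory": sec.territory_label,
            "angle_start_deg": sec.angle_start_deg,
            "angle_end_deg": sec.angle_end_deg,
            "mbf_epi": sec.mbf_epi,
            "transmural_ratio": sec.transmural_ratio,
            "reference_ffr": sec.reference_ffr,
            "true_tpr": truth.true_tpr_per_sector[i],
            "true_mean_mbf": truth.true_mean_mbf_per_sector[i],
        })
    pd.DataFrame(rows).to_csv(out_dir / "sectors.csv", index=False)
    write_json(out_dir / "truth.json",
               {"true_aif": truth.true_aif.model_dump()})
    return out_dir


def load_ground_truth(in_dir: str | Path) -> GroundTruth:
    in_dir = Path(in_dir)
    true_mbf = np.asarray(
        nib.load(in_dir / "true_mbf.nii.gz").get_fdata(), float)
    sector = np.asarray(
        nib.load(in_dir / "sector_of_voxel.nii.gz").get_fdata()).astype(int)
    tab = pd.read_csv(in_dir / "sectors.csv")
    meta = json.loads((in_dir / "truth.json").read_text())
    sectors = [
        SectorSpec(
            angle_start_deg=r.angle_start_deg, angle_end_deg=r.angle_end_deg,
            mbf_epi=r.mbf_epi, transmural_ratio=r.transmural_ratio,
            territory_label=r.territory, reference_ffr=r.reference_ffr,
        )
        for r in tab.itertuples()
    ]
    return GroundTruth(
        true_mbf=true_mbf,
        sector_of_voxel=sector,
        true_tpr_per_sector={int(r.sector): float(r.true_tpr)
                             for r in tab.itertuples()},
        true_mean_mbf_per_sector={int(r.sector): float(r.true_mean_mbf)
                                  for r in tab.itertuples()},
        true_aif=AifParams(**meta["true_aif"]),
        sectors=sectors,
        annulus_mask=sector >= 0,
    )


def save_mbf_map(mbf_map: MBFMap, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nib.save(
        nib.Nifti1Image(mbf_map.mbf.astype(np.float32),
                        _affine(mbf_map.pixel_mm, mbf_map.slice_thickness_mm)),
        out_dir / "mbf.nii.gz")
    write_json(out_dir / "mbf.json", {
        "pixel_mm": mbf_map.pixel_mm,
        "slice_thickness_mm": mbf_map.slice_thickness_mm,
        "slice_increment_mm": mbf_map.slice_increment_mm,
    })
    return out_dir


def load_mbf_map(in_dir: str | Path) -> MBFMap:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "mbf.json").read_text())
    mbf = np.asarray(nib.load(in_dir / "mbf.nii.gz").get_fdata(), float)
    return MBFMap(
        mbf=mbf,
        mask=np.isfinite(mbf),
        pixel_mm=float(meta["pixel_mm"]),
        slice_thickness_mm=float(meta["slice_thickness_mm"]),
        slice_increment_mm=float(meta["slice_increment_mm"]),
    )
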