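"""File readers/writers: images, manifests, diagnosis CSVs, analysis JSON.

TIFF is the canonical interchange format; PNG and JPEG are accepted (JPEG
with a logged warning about lossy provenance). 16-bit inputs are rescaled to
8-bit. CSVs are UTF-8, comma-separated, with a header row; diagnosis labels
are exactly {DR, NODR, UNG}.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from retscreen.types import FundusImage, ImageAnalysis

logger = logging.getLogger("retscreen")

MANIFEST_COLUMNS = ["patient_id", "eye", "capture", "path"]
DIAGNOSIS_COLUMNS = ["patient_id", "rater_id", "diagnosis"]


def read_fundus_image(
    path: Union[str, Path],
    patient_id: str = "",
    eye: str = "OD",
    capture_index: int = 1,
) -> FundusImage:
    """Read a TIFF/PNG/JPEG capture as an 8-bit RGB :class:`FundusImage`."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(str(path))
        else:
            if suffix in (".jpg", ".jpeg"):
                logger.warning("reading lossy JPEG %s; original TIFFs are preferred", path)
            arr = np.asarray(Image.open(path).convert("RGB"))
    except Exception as exc:  # pragma: no cover - codec-specific
        raise IOError(f"could not decode image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] > 3:
        arr = arr[..., :3]
    if arr.dtype == np.uint16:
        arr = (arr / 257.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return FundusImage(
        pixels=arr,
        patient_id=patient_id,
        eye=eye,
        capture_index=capture_index,
        source_path=str(path),
    )


def write_image(path: Union[str, Path], pixels: np.ndarray) -> None:
    """Write an RGB raster as PNG or TIFF by extension (PNG is lossless)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), pixels)
    else:
        Image.fromarray(pixels).save(path)


def write_manifest(path: Union[str, Path], manifest: pd.DataFrame) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, index=False)


def read_manifest(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    return df


def write_diagnosis_csv(path: Union[str, Path], df: pd.DataFrame) -> None:
    missing = [c for c in DIAGNOSIS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"diagnosis table missing columns: {missing}")
    bad = set(df["diagnosis"]) - {"DR", "NODR", "UNG"}
    if bad:
        raise ValueError(f"invalid diagnosis labels: {sorted(bad)}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_diagnosis_csv(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOError(f"diagnosis CSV not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in DIAGNOSIS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"diagnosis CSV missing columns: {missing}")
    bad = set(df["diagnosis"]) - {"DR", "NODR", "UNG"}
    if bad:
        raise ValueError(f"invalid diagnosis labels in {path}: {sorted(bad)}")
    return df


def analysis_to_dict(analysis: ImageAnalysis) -> dict:
    """Serialize a per-image analysis to the documented JSON schema."""
    q = analysis.quality
    out: dict = {
        "quality": {
            "gradable": q.gradable,
            "sharpness": round(q.sharpness, 4),
            "illuminated_fraction": round(q.illuminated_fraction, 4),
            "saturation_fraction": round(q.saturation_fraction, 4),
            "reasons": list(q.reasons),
        },
        "frame": None,
        "lesions": [],
    }
    if analysis.frame is not None:
        f = analysis.frame
        out["frame"] = {
            "disc_center": [round(v, 2) for v in f.disc_center],
            "disc_radius": round(f.disc_radius, 2),
            "fovea_center": [round(v, 2) for v in f.fovea_center],
            "axis_angle": round(f.axis_angle, 2),
        }
    for lesion in analysis.lesions:
        rec = {
            "type": lesion.type,
            "centroid": [round(v, 2) for v in lesion.centroid],
            "area": lesion.area,
            "circularity": round(lesion.circularity, 3),
            "contrast": round(lesion.contrast, 2),
        }
        if lesion.polar is not None:
            rec["polar"] = [round(lesion.polar[0], 3), round(lesion.polar[1], 2)]
            rec["quadrant"] = lesion.quadrant
        out["lesions"].append(rec)
    return out


def write_analysis_json(path: Union[str, Path], analysis: ImageAnalysis) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(analysis_to_dict(analysis), fh, indent=2)


def write_patient_results(path: Union[str, Path], rows: list[dict]) -> None:
    """Eye/patient grading results: patient_id, status, stage, dme, stdr."""
    df = pd.DataFrame(rows, columns=["patient_id", "status", "stage", "dme", "stdr"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
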