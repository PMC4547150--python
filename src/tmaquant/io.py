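"""Image readers/writers, results CSV, run manifests and batch driving.

Results are exchanged as UTF-8 CSV ('.' decimal, header row) with one row
per image; a JSON manifest written alongside captures the tool version,
the exact configuration snapshot and the input list, so any result row
can be reproduced exactly.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from . import __version__
from .cylinder import CylinderNotFoundError, SegmentationConfig
from .stain import StainQuantification, quantify_image

logger = logging.getLogger(__name__)

__all__ = ["load_image", "save_image", "RunManifest", "run_batch", "results_frame"]

IMAGE_EXTENSIONS = {".tif", ".tiff", ".png"}


class UnsupportedFormatError(ValueError):
    pass


def _to_rgb8(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.dtype == np.uint16:
        logger.warning("%s: 16-bit input rescaled to 8-bit", path)
        arr = (arr.astype(np.float64) / 257.0 + 0.5).astype(np.uint8)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    elif arr.dtype != np.uint8:
        raise UnsupportedFormatError(
            f"{path}: unsupported pixel type {arr.dtype}; expected 8- or 16-bit"
        )
    if arr.ndim == 2:
        logger.warning("%s: grayscale input replicated to three channels", path)
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[-1] == 4:
        logger.warning("%s: alpha channel dropped", path)
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise UnsupportedFormatError(
            f"{path}: cannot interpret array of shape {arr.shape} as RGB"
        )
    return np.ascontiguousarray(arr)


def load_image(path) -> np.ndarray:
    """Read a TIFF or PNG cylinder image as an (H, W, 3) uint8 array.

    16-bit inputs are rescaled to 8-bit with a warning; grayscale is
    replicated to three channels and RGBA alpha is dropped, each with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except UnsupportedFormatError:
        raise
    except Exception as exc:  # truncated/corrupt file
        raise OSError(f"cannot read image {path}: {exc}") from exc
    return _to_rgb8(np.asarray(arr), path)


def save_image(path, img: np.ndarray) -> None:
    """Write an image as uncompressed TIFF or PNG, by extension."""
    path = Path(path)
    img = np.asarray(img)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        Image.fromarray(img).save(path)


@dataclass
class RunManifest:
    """Provenance sidecar: everything needed to reproduce a results CSV."""

    tool_version: str
    config_snapshot: dict
    input_files: list[str]
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
    )
    warnings: list[str] = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def results_frame(results: list[StainQuantification | dict]) -> pd.DataFrame:
    """Tabulate per-image quantifications (or error rows) as a DataFrame."""
    rows = []
    for r in results:
        if isinstance(r, dict):  # error row
            rows.append(r)
        else:
            rows.append(
                {
                    "image_id": r.image_id,
                    "total_area_px": r.total_area,
                    "area_A_px": r.positive_area_A,
                    "area_B_px": r.positive_area_B,
                    "percent_A": round(r.percent_A, 4),
                    "percent_B": round(r.percent_B, 4),
                    "n_objects": r.n_objects,
                    "error": "",
                    "warnings": "; ".join(r.warnings),
                }
            )
    columns = [
        "image_id",
        "total_area_px",
        "area_A_px",
        "area_B_px",
        "percent_A",
        "percent_B",
        "n_objects",
        "error",
        "warnings",
    ]
    return pd.DataFrame(rows, columns=columns)


def run_batch(
    inputs,
    cfg: SegmentationConfig | None = None,
    out_csv=None,
    manifest_path=None,
) -> tuple[pd.DataFrame, RunManifest]:
    """Quantify every image in a directory (or an explicit file list).

    Per-image failures (e.g. no cylinder found in an all-bright image) are
    recorded as rows with a non-empty ``error`` column; the batch never
    aborts on one bad image. Identical inputs and config produce identical
    result values across runs.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    inputs = Path(inputs) if isinstance(inputs, (str, Path)) else inputs
    if isinstance(inputs, Path):
        if inputs.is_dir():
            files = sorted(
                p for p in inputs.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS
            )
        else:
            files = [inputs]
    else:
        files = [Path(p) for p in inputs]
    if not files:
        raise ValueError("no readable images found in the input")

    results: list[StainQuantification | dict] = []
    batch_warnings: list[str] = []
    for f in files:
        try:
            img = load_image(f)
            q = quantify_image(img, cfg, image_id=f.stem)
            results.append(q)
            batch_warnings.extend(f"{f.stem}: {w}" for w in q.warnings)
        except (CylinderNotFoundError, OSError, ValueError) as exc:
            logger.error("%s: %s", f, exc)
            results.append(
                {
                    "image_id": f.stem,
                    "error": f"{type(exc).__name__}: {exc}",
                }
            )
            batch_warnings.append(f"{f.stem}: {type(exc).__name__}")

    frame = results_frame(results)
    manifest = RunManifest(
        tool_version=__version__,
        config_snapshot=cfg.to_dict(),
        input_files=[str(f) for f in files],
        warnings=batch_warnings,
    )
    if out_csv is not None:
        frame.to_csv(out_csv, index=False)
        if manifest_path is None:
            manifest_path = Path(out_csv).with_suffix(".manifest.json")
    if manifest_path is not None:
        manifest.write(manifest_path)
    return frame, manifest
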