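"""Reading and writing of images, masks, ROIs, design tables and result tables.

Images are single-channel grayscale TIFF (8/16-bit) or PNG (8-bit); masks are
written as 8-bit rasters with values {0, 255}. ROIs come in a simple JSON
polygon dialect (canonical) or as ImageJ ``.roi`` polygon files (read-only,
for interoperability with manual ImageJ workflows). All tabular I/O round-trips
at full decimal precision.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .types import (BinaryMask, Channel, ChannelImage, DesignRow,
                    MaskProvenance, QuantRecord, Region, RoiPolygon)

PathLike = Union[str, Path]

NA_TOKEN = "NA"

QUANT_COLUMNS = ["animal_id", "section_id", "region", "metric",
                 "numerator_px", "denominator_px", "value", "scale"]


# ---------------------------------------------------------------------------
# images and masks

def read_channel_image(path: PathLike, channel: Channel,
                       pixel_size_um: float = 1.0,
                       section_id: str = "", animal_id: str = "") -> ChannelImage:
    """Read a grayscale single-plane raster into a :class:`ChannelImage`.

    Integer intensities are preserved losslessly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(
                f"{path}: multi-channel raster; supply single-channel images")
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D image, got shape {arr.shape}")
    return ChannelImage(arr, Channel(channel), pixel_size_um,
                        section_id=section_id, animal_id=animal_id)


def write_channel_image(img: ChannelImage, path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = img.pixels
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        if arr.dtype != np.uint8:
            if np.issubdtype(arr.dtype, np.integer) and arr.max(initial=0) <= 255:
                arr = arr.astype(np.uint8)
            else:
                raise ValueError("PNG output requires 8-bit intensities")
        iio.imwrite(path, arr)


def read_mask(path: PathLike, provenance: MaskProvenance = MaskProvenance.MANUAL,
              label: str = "") -> BinaryMask:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    return BinaryMask(np.asarray(arr) > 0, provenance, label or path.stem)


def write_mask(mask: BinaryMask, path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = (mask.pixels.astype(np.uint8)) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


# ---------------------------------------------------------------------------
# ROIs

def read_roi(path: PathLike, image_shape: Tuple[int, int]) -> List[RoiPolygon]:
    """Read ROI polygons from JSON (one object or a list) or ImageJ ``.roi``.

    Polygons are validated (simple, >= 3 vertices) and clipped to the image
    bounds.
    """
    path = Path(path)
    if path.suffix.lower() == ".roi":
        polys = [_read_imagej_roi(path)]
    else:
        data = json.loads(path.read_text())
        if isinstance(data, dict):
            data = [data]
        polys = [RoiPolygon(Region(d["region"]), [tuple(v) for v in d["vertices"]])
                 for d in data]
    return [p.clipped(image_shape) for p in polys]


def write_roi_json(polys: Sequence[RoiPolygon], path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [{"region": p.region.value,
                "vertices": [[float(x), float(y)] for x, y in p.vertices]}
               for p in polys]
    path.write_text(json.dumps(payload, indent=1))


def _read_imagej_roi(path: Path, region: Region = Region.CORTEX) -> RoiPolygon:
    """Minimal ImageJ .roi reader for polygon-type ROIs (big-endian layout)."""
    blob = path.read_bytes()
    if blob[:4] != b"Iout":
        raise ValueError(f"{path}: not an ImageJ .roi file")
    roi_type = blob[6]
    if roi_type != 0:  # 0 = polygon
        raise ValueError(f"{path}: unsupported ROI type {roi_type} (want polygon)")
    top, left, _bottom, _right = struct.unpack(">4h", blob[8:16])
    n = struct.unpack(">h", blob[16:18])[0]
    xs = struct.unpack(f">{n}h", blob[64:64 + 2 * n])
    ys = struct.unpack(f">{n}h", blob[64 + 2 * n:64 + 4 * n])
    verts = [(left + x, top + y) for x, y in zip(xs, ys)]
    guess = Region.HIPPOCAMPUS if "hipp" in path.stem.lower() else region
    return RoiPolygon(guess, verts)


# ---------------------------------------------------------------------------
# design table and blinding

def read_design_table(path: PathLike) -> List[DesignRow]:
    df = pd.read_csv(path, dtype=str)
    rows = [DesignRow(r.animal_id, r.app_genotype, r.apoa1_genotype,
                      getattr(r, "sex", "F"))
            for r in df.itertuples(index=False)]
    ids = [r.animal_id for r in rows]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate animal_id in design table")
    return rows


def write_design_table(rows: Sequence[DesignRow], path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{"animal_id": r.animal_id, "app_genotype": r.app_genotype,
                   "apoa1_genotype": r.apoa1_genotype, "sex": r.sex}
                  for r in rows]).to_csv(path, index=False)


def assign_blinding_codes(design: Sequence[DesignRow], seed: int) -> Dict[str, str]:
    """Deterministic bijection animal_id -> opaque code, free of genotype info."""
    ids = [r.animal_id for r in design]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate animal ids")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    width = max(3, len(str(len(ids))))
    return {ids[i]: f"B{rank + 1:0{width}d}" for rank, i in enumerate(perm)}


# ---------------------------------------------------------------------------
# quantification tables

def records_to_frame(records: Iterable[QuantRecord]) -> pd.DataFrame:
    rows = [{"animal_id": r.animal_id, "section_id": r.section_id,
             "region": r.region, "metric": r.metric,
             "numerator_px": r.numerator_px, "denominator_px": r.denominator_px,
             "value": np.nan if r.value is None else r.value,
             "scale": r.scale}
            for r in records]
    return pd.DataFrame(rows, columns=QUANT_COLUMNS)


def write_quant_csv(records: Iterable[QuantRecord], path: PathLike) -> None:
    """One row per record, stable column order, NA token for undefined values."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(path, index=False, na_rep=NA_TOKEN,
                                     float_format="%.17g")


def read_quant_csv(path: PathLike) -> List[QuantRecord]:
    df = pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=False,
                     float_precision="round_trip")
    out: List[QuantRecord] = []
    for r in df.itertuples(index=False):
        value = None if pd.isna(r.value) else float(r.value)
        out.append(QuantRecord(str(r.animal_id), str(r.section_id), str(r.region),
                               str(r.metric), int(r.numerator_px),
                               int(r.denominator_px), value, str(r.scale)))
    return out
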