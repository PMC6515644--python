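"""Area-fraction and colocalization metrics as boolean mask algebra within ROIs.

Every reported histology quantity is a ratio of pixel counts:

* total %-positive area:      |marker ∩ Ω| / |Ω|
* marker-associated fraction: |target ∩ reference ∩ Ω| / |reference ∩ Ω|
  (e.g. vascular GFAP: GFAP within the CD31 mask over CD31 area in the ROI)
* parenchymal area:           |marker ∩ Ω| − |marker ∩ reference ∩ Ω|, over |Ω|

with Ω the rasterized ROI polygon. "Associated with" is strict pixel-wise
intersection with the reference mask; an optional reference dilation of
``d`` px (default 0) is exposed for sensitivity analyses.

Metric definitions are data: a numerator/denominator expression over labelled
masks, so new colocalization metrics need no code changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from skimage.morphology import disk
from scipy import ndimage as ndi

from .types import BinaryMask, MaskProvenance, QuantRecord, RoiPolygon


# ---------------------------------------------------------------------------
# ROI rasterization

def rasterize_roi(poly: RoiPolygon, shape: Tuple[int, int]) -> BinaryMask:
    """Pixel positive iff its center lies inside the polygon.

    Pixel centers are at integer coordinates (x = column, y = row); boundary
    centers count as inside (even-odd rule on a simple polygon).
    """
    geom = Polygon(poly.vertices)
    if geom.area == 0 and geom.length == 0:
        raise ValueError("degenerate polygon")
    h, w = shape
    out = np.zeros(shape, dtype=bool)
    minx, miny, maxx, maxy = geom.bounds
    x0 = max(int(np.floor(minx)), 0)
    x1 = min(int(np.ceil(maxx)), w - 1)
    y0 = max(int(np.floor(miny)), 0)
    y1 = min(int(np.ceil(maxy)), h - 1)
    if x1 < x0 or y1 < y0:
        return BinaryMask(out, MaskProvenance.ROI, poly.region.value)
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    # intersects == covers for points: boundary counts as inside
    inside = shapely.intersects_xy(geom, xs.ravel(), ys.ravel())
    out[y0:y1 + 1, x0:x1 + 1] = inside.reshape(xs.shape)
    return BinaryMask(out, MaskProvenance.ROI, poly.region.value)


def dilate_mask(mask: BinaryMask, d_px: int) -> BinaryMask:
    """Morphological dilation with a Euclidean disk of radius ``d_px``."""
    if d_px <= 0:
        return mask
    out = ndi.binary_dilation(mask.pixels, structure=disk(d_px))
    return BinaryMask(out, MaskProvenance.DERIVED, f"dilate({mask.label},{d_px})")


# ---------------------------------------------------------------------------
# core fraction metrics

def _record(metric: str, num: int, den: int, *, animal_id: str = "",
            section_id: str = "", region: str = "",
            scale: str = "percent") -> QuantRecord:
    return QuantRecord(animal_id, section_id, region, metric,
                       int(num), int(den), scale=scale)


def total_area_fraction(marker: BinaryMask, roi: BinaryMask, *,
                        metric: str = "total_area_pct",
                        animal_id: str = "", section_id: str = "",
                        region: str = "", scale: str = "percent") -> QuantRecord:
    """|marker ∩ roi| / |roi|; undefined when the ROI is empty."""
    _check(marker, roi)
    num = int((marker.pixels & roi.pixels).sum())
    den = roi.area_px
    return _record(metric, num, den, animal_id=animal_id,
                   section_id=section_id, region=region, scale=scale)


def associated_fraction(target: BinaryMask, reference: BinaryMask,
                        roi: BinaryMask, *, dilation_px: int = 0,
                        metric: str = "associated_fraction",
                        animal_id: str = "", section_id: str = "",
                        region: str = "", scale: str = "percent") -> QuantRecord:
    """|target ∩ reference ∩ roi| / |reference ∩ roi|.

    The reference mask may optionally be dilated by ``dilation_px`` before
    intersection (default 0: the raw mask is applied).
    """
    _check(target, reference, roi)
    ref = dilate_mask(reference, dilation_px)
    den_mask = ref.pixels & roi.pixels
    num = int((target.pixels & den_mask).sum())
    den = int(den_mask.sum())
    return _record(metric, num, den, animal_id=animal_id,
                   section_id=section_id, region=region, scale=scale)


def parenchymal_fraction(marker: BinaryMask, reference: BinaryMask,
                         roi: BinaryMask, *, dilation_px: int = 0,
                         metric: str = "parenchymal_area_pct",
                         animal_id: str = "", section_id: str = "",
                         region: str = "", scale: str = "percent") -> QuantRecord:
    """Marker area outside the reference: (|M∩Ω| − |M∩R∩Ω|) / |Ω|.

    The decomposition is exact in pixels: total = vascular + parenchymal.
    """
    _check(marker, reference, roi)
    ref = dilate_mask(reference, dilation_px)
    num = int((marker.pixels & ~ref.pixels & roi.pixels).sum())
    den = roi.area_px
    return _record(metric, num, den, animal_id=animal_id,
                   section_id=section_id, region=region, scale=scale)


def _check(*masks: BinaryMask) -> None:
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"mask shape mismatch: {shapes}")


# ---------------------------------------------------------------------------
# declarative metric definitions

@dataclass(frozen=True)
class MetricDefinition:
    """A named ratio of mask-intersection areas.

    ``numerator``/``denominator`` are tuples of mask labels; a leading ``~``
    complements that mask. The ROI is always intersected into both sides.
    An empty denominator tuple means the ROI itself.
    """

    name: str
    numerator: Tuple[str, ...]
    denominator: Tuple[str, ...] = ()
    scale: str = "percent"

    def evaluate(self, masks: Mapping[str, BinaryMask], roi: BinaryMask, *,
                 animal_id: str = "", section_id: str = "",
                 region: str = "") -> QuantRecord:
        num_mask = _expr(self.numerator, masks, roi)
        den_mask = _expr(self.denominator, masks, roi)
        return _record(self.name, int(num_mask.sum()), int(den_mask.sum()),
                       animal_id=animal_id, section_id=section_id,
                       region=region, scale=self.scale)


def _expr(labels: Tuple[str, ...], masks: Mapping[str, BinaryMask],
          roi: BinaryMask) -> np.ndarray:
    out = roi.pixels.copy()
    for lab in labels:
        if lab.startswith("~"):
            out &= ~masks[lab[1:]].pixels
        else:
            out &= masks[lab].pixels
    return out


#: The built-in metric panel covering every reported histology quantity.
#: Mask labels: X34, CD31, GFAP, ICAM1, CAA, VGFAP (= GFAP ∩ CD31).
BUILTIN_METRICS: List[MetricDefinition] = [
    MetricDefinition("total_area_pct.X34", ("X34",)),
    MetricDefinition("total_area_pct.CD31", ("CD31",)),
    MetricDefinition("total_area_pct.GFAP", ("GFAP",)),
    MetricDefinition("total_area_pct.ICAM1", ("ICAM1",)),
    MetricDefinition("vascular_fraction.GFAP", ("GFAP", "CD31"), ("CD31",)),
    MetricDefinition("plaque_assoc_fraction.GFAP", ("GFAP", "X34"), ("X34",)),
    MetricDefinition("vascular_fraction.ICAM1", ("ICAM1", "CD31"), ("CD31",)),
    MetricDefinition("parenchymal_area_pct.ICAM1", ("ICAM1", "~CD31")),
    MetricDefinition("caa_area_pct", ("CAA",)),
    MetricDefinition("caa_assoc_gfap_pct", ("VGFAP", "CAA"), ("CAA",)),
    MetricDefinition("vgfap_assoc_caa_pct", ("CAA", "VGFAP"), ("VGFAP",)),
]


def evaluate_metrics(masks: Mapping[str, BinaryMask], roi: BinaryMask,
                     definitions: Optional[Sequence[MetricDefinition]] = None,
                     *, animal_id: str = "", section_id: str = "",
                     region: str = "") -> List[QuantRecord]:
    """Evaluate a metric panel on one section/ROI.

    The derived vascular-GFAP mask (GFAP ∩ CD31) is added automatically when
    GFAP and CD31 are present, mirroring the mask-application order of the
    manual workflow. Metrics whose masks are missing are skipped.
    """
    defs = list(definitions) if definitions is not None else BUILTIN_METRICS
    masks = dict(masks)
    if "VGFAP" not in masks and "GFAP" in masks and "CD31" in masks:
        masks["VGFAP"] = masks["GFAP"] & masks["CD31"]
    out: List[QuantRecord] = []
    for d in defs:
        needed = {lab.lstrip("~") for lab in d.numerator + d.denominator}
        if not needed.issubset(masks):
            continue
        out.append(d.evaluate(masks, roi, animal_id=animal_id,
                              section_id=section_id, region=region))
    return out


# ---------------------------------------------------------------------------
# per-animal aggregation

def aggregate_per_animal(records: pd.DataFrame,
                         mode: str = "mean") -> pd.DataFrame:
    """Collapse per-section records to one value per animal/region/metric.

    ``mean`` (default) averages the per-section values, dropping undefined
    sections — one plotted point per mouse. ``pooled`` sums numerator and
    denominator pixels across sections before taking the ratio.
    """
    df = records.copy()
    keys = ["animal_id", "region", "metric"]
    if mode == "mean":
        out = (df.groupby(keys, sort=True)["value"]
                 .mean().reset_index())
    elif mode == "pooled":
        g = df.groupby(keys, sort=True).agg(
            numerator_px=("numerator_px", "sum"),
            denominator_px=("denominator_px", "sum"),
            scale=("scale", "first")).reset_index()
        factor = np.where(g["scale"] == "percent", 100.0, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            g["value"] = factor * g["numerator_px"] / g["denominator_px"]
        g.loc[g["denominator_px"] == 0, "value"] = np.nan
        out = g[keys + ["value"]]
    else:
        raise ValueError("mode must be 'mean' or 'pooled'")
    return out
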