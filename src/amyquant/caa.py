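"""Separation of vascular amyloid (CAA) from parenchymal plaques.

Cerebral amyloid angiopathy is amyloid deposited in vessel walls; in
thresholded amyloid-dye images it appears as elongated deposits tracking the
vasculature, while parenchymal plaques are compact, roughly isotropic blobs.
The reference workflow discriminates the two manually on inverted images;
manual masks remain the faithful path (:func:`ingest_manual_caa`). This module
additionally provides an automated morphological surrogate: a connected
component of the amyloid mask is called vascular when it either substantially
overlaps the (dilated) endothelial mask or is strongly elongated. Automated
classifications are flagged as such in mask provenance labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .mask_algebra import dilate_mask
from .types import BinaryMask, MaskProvenance, QuantRecord


@dataclass
class CaaParams:
    """Automated vascular-vs-parenchymal classification parameters.

    A component is vascular iff its overlap with the endothelial mask
    (dilated by ``dilation_px``) is >= ``overlap_min`` OR its best-fit-ellipse
    axis ratio is >= ``elongation_min``. Components smaller than
    ``min_component_px`` are dropped as speckle.
    """

    overlap_min: float = 0.5
    elongation_min: float = 3.0
    dilation_px: int = 2
    min_component_px: int = 20


@dataclass
class AmyloidComponent:
    """One 8-connected component of the segmented amyloid mask."""

    component_id: int
    coords: np.ndarray          # (n, 2) row/col pixel indices
    area_px: int
    eccentricity_ratio: float   # major/minor axis ratio of best-fit ellipse
    vessel_overlap: float = np.nan
    classification: Optional[str] = None  # "vascular" | "parenchymal"


def label_components(x34_mask: BinaryMask,
                     min_component_px: int = 20) -> List[AmyloidComponent]:
    """8-connected components of the amyloid mask with shape features.

    Components below ``min_component_px`` are removed (speckle filter).
    The axis ratio of degenerate (line-like) components, whose minor axis is
    zero, is reported as infinity.
    """
    lab = measure.label(x34_mask.pixels, connectivity=2)
    out: List[AmyloidComponent] = []
    for rp in measure.regionprops(lab):
        if rp.area < min_component_px:
            continue
        minor = rp.axis_minor_length
        major = rp.axis_major_length
        ratio = float("inf") if minor == 0 else max(major / minor, 1.0)
        out.append(AmyloidComponent(rp.label, rp.coords, int(rp.area), ratio))
    return out


def classify_amyloid(components: Sequence[AmyloidComponent],
                     cd31_mask: BinaryMask, params: CaaParams,
                     shape: Optional[Tuple[int, int]] = None
                     ) -> Tuple[BinaryMask, BinaryMask]:
    """Partition amyloid components into a CAA mask and a plaque mask.

    Vascular iff vessel_overlap >= overlap_min OR axis ratio >= elongation_min.
    The two returned masks are disjoint and their union is the union of the
    retained components.
    """
    shape = shape or cd31_mask.shape
    ref = dilate_mask(cd31_mask, params.dilation_px).pixels
    caa = np.zeros(shape, dtype=bool)
    plaque = np.zeros(shape, dtype=bool)
    for comp in components:
        rr, cc = comp.coords[:, 0], comp.coords[:, 1]
        comp.vessel_overlap = float(ref[rr, cc].mean())
        vascular = (comp.vessel_overlap >= params.overlap_min
                    or comp.eccentricity_ratio >= params.elongation_min)
        comp.classification = "vascular" if vascular else "parenchymal"
        (caa if vascular else plaque)[rr, cc] = True
    return (BinaryMask(caa, MaskProvenance.DERIVED, "CAA:auto"),
            BinaryMask(plaque, MaskProvenance.DERIVED, "plaque:auto"))


def ingest_manual_caa(manual: BinaryMask, x34_mask: BinaryMask) -> BinaryMask:
    """Apply a manually drawn vascular-amyloid mask back onto segmented amyloid.

    CAA is always a subset of the segmented amyloid mask:
    ``caa = manual ∩ x34``.
    """
    if manual.shape != x34_mask.shape:
        raise ValueError(f"shape mismatch: {manual.shape} vs {x34_mask.shape}")
    return BinaryMask(manual.pixels & x34_mask.pixels,
                      MaskProvenance.MANUAL, "CAA:manual")


def caa_metrics(caa_mask: BinaryMask, roi: BinaryMask,
                vascular_gfap_mask: BinaryMask, *,
                animal_id: str = "", section_id: str = "",
                region: str = "cortex") -> List[QuantRecord]:
    """CAA area and bidirectional CAA/vascular-GFAP association metrics.

    * caa_area_pct       = |CAA ∩ Ω| / |Ω|
    * caa_assoc_gfap_pct = |vGFAP ∩ CAA ∩ Ω| / |CAA ∩ Ω|
    * vgfap_assoc_caa_pct = |CAA ∩ vGFAP ∩ Ω| / |vGFAP ∩ Ω|

    Empty denominators yield undefined (NA) records, never 0.
    """
    for m in (roi, vascular_gfap_mask):
        if m.shape != caa_mask.shape:
            raise ValueError("mask shape mismatch")
    omega = roi.pixels
    caa = caa_mask.pixels & omega
    vg = vascular_gfap_mask.pixels & omega
    meta = dict(animal_id=animal_id, section_id=section_id, region=region)
    return [
        QuantRecord(metric="caa_area_pct", numerator_px=int(caa.sum()),
                    denominator_px=int(omega.sum()), **meta),
        QuantRecord(metric="caa_assoc_gfap_pct",
                    numerator_px=int((vg & caa).sum()),
                    denominator_px=int(caa.sum()), **meta),
        QuantRecord(metric="vgfap_assoc_caa_pct",
                    numerator_px=int((caa & vg).sum()),
                    denominator_px=int(vg.sum()), **meta),
    ]
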