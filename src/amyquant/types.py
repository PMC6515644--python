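"""Core domain containers shared by every stage of the pipeline.

The atom of all quantification is the :class:`BinaryMask`: every metric in the
package is a ratio of pixel counts between boolean rasters aligned to a single
channel image. Containers validate their invariants at construction so that
downstream mask algebra can assume rectangular, finite, shape-aligned inputs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np


class Channel(str, enum.Enum):
    """Fluorescence channels of the triple/quadruple stain."""

    X34 = "X34"          # fibrillar amyloid (plaques + vascular deposits)
    CD31 = "CD31"        # endothelium / vasculature
    GFAP = "GFAP"        # reactive astrocytes
    ICAM1 = "ICAM1"      # vascular-inflammation adhesion molecule


class Region(str, enum.Enum):
    CORTEX = "cortex"
    HIPPOCAMPUS = "hippocampus"
    HYPOTHALAMUS = "hypothalamus"


class MaskProvenance(str, enum.Enum):
    THRESHOLD_GLOBAL = "threshold_global"
    THRESHOLD_BERNSEN = "threshold_bernsen"
    ROI = "roi"
    MANUAL = "manual"
    DERIVED = "derived"
    GROUND_TRUTH = "ground_truth"


@dataclass
class ChannelImage:
    """A single-channel 2D intensity raster with acquisition metadata."""

    pixels: np.ndarray
    channel: Channel
    pixel_size_um: float = 1.0
    section_id: str = ""
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected 2D raster, got ndim={self.pixels.ndim}")
        if not np.all(np.isfinite(self.pixels.astype(float))):
            raise ValueError("intensities must be finite")
        if np.any(self.pixels.astype(float) < 0):
            raise ValueError("intensities must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        self.channel = Channel(self.channel)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """A boolean raster aligned to a source image."""

    pixels: np.ndarray
    provenance: MaskProvenance = MaskProvenance.DERIVED
    label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected 2D mask, got ndim={self.pixels.ndim}")
        if self.pixels.dtype != bool:
            uniq = np.unique(self.pixels)
            if not np.all(np.isin(uniq, (0, 1, 255))):
                raise ValueError("non-boolean mask raster")
            self.pixels = self.pixels > 0
        self.provenance = MaskProvenance(self.provenance)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        _check_aligned(self, other)
        return BinaryMask(self.pixels & other.pixels, MaskProvenance.DERIVED,
                          f"({self.label})&({other.label})")

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        _check_aligned(self, other)
        return BinaryMask(self.pixels | other.pixels, MaskProvenance.DERIVED,
                          f"({self.label})|({other.label})")

    def __invert__(self) -> "BinaryMask":
        return BinaryMask(~self.pixels, MaskProvenance.DERIVED, f"~({self.label})")

    def __sub__(self, other: "BinaryMask") -> "BinaryMask":
        _check_aligned(self, other)
        return BinaryMask(self.pixels & ~other.pixels, MaskProvenance.DERIVED,
                          f"({self.label})-({other.label})")


def _check_aligned(a: BinaryMask, b: BinaryMask) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")


@dataclass
class RoiPolygon:
    """A named simple closed polygon in pixel coordinates (x right, y down)."""

    region: Region
    vertices: Sequence[Tuple[float, float]]

    def __post_init__(self) -> None:
        self.region = Region(self.region)
        verts = [(float(x), float(y)) for x, y in self.vertices]
        if len(verts) < 3:
            raise ValueError("polygon needs >= 3 vertices")
        self.vertices = verts
        # self-intersection check delegated to shapely simplicity test
        from shapely.geometry import LineString

        ring = LineString(verts + [verts[0]])
        if not ring.is_simple:
            raise ValueError("self-intersecting polygon")

    def clipped(self, image_shape: Tuple[int, int]) -> "RoiPolygon":
        """Clamp vertices to the image bounds (pixel-center coordinates)."""
        h, w = image_shape
        verts = [(min(max(x, 0.0), w - 1.0), min(max(y, 0.0), h - 1.0))
                 for x, y in self.vertices]
        return RoiPolygon(self.region, verts)


@dataclass
class DesignRow:
    """One animal of the 2x2 (APP/PS1 x apoA-I) factorial design."""

    animal_id: str
    app_genotype: str    # WT | APPPS1
    apoa1_genotype: str  # HEM | KO
    sex: str = "F"

    APP_LEVELS = ("WT", "APPPS1")
    APOA1_LEVELS = ("HEM", "KO")

    def __post_init__(self) -> None:
        if self.app_genotype not in self.APP_LEVELS:
            raise ValueError(f"app_genotype must be one of {self.APP_LEVELS}")
        if self.apoa1_genotype not in self.APOA1_LEVELS:
            raise ValueError(f"apoa1_genotype must be one of {self.APOA1_LEVELS}")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be F or M")


@dataclass
class QuantRecord:
    """One measurement: a pixel-count ratio for one metric/region/section.

    ``value`` is ``None`` when the denominator is empty (never coerced to 0,
    which would bias group means).
    """

    animal_id: str
    section_id: str
    region: str
    metric: str
    numerator_px: int
    denominator_px: int
    value: Optional[float] = field(default=None)
    scale: str = "percent"  # percent | fraction

    def __post_init__(self) -> None:
        if self.numerator_px < 0 or self.denominator_px < 0:
            raise ValueError("pixel counts must be non-negative")
        if self.denominator_px == 0:
            self.value = None
        elif self.value is None:
            ratio = self.numerator_px / self.denominator_px
            self.value = 100.0 * ratio if self.scale == "percent" else ratio

    @property
    def undefined(self) -> bool:
        return self.value is None
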