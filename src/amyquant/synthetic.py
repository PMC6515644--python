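"""Synthetic multi-channel brain-section generator with known ground truth.

Emulates the structures the quantification pipeline assumes in a 2D
fluorescence section of an amyloid-model mouse brain:

* **vessels** (CD31): smooth branching tubes — persistent-random-walk
  centrelines dilated to a per-vessel radius;
* **parenchymal plaques** (X-34): compact blobs placed away from vessels;
* **CAA** (X-34): amyloid annuli wrapped around randomly chosen vessel
  segments (vessel-wall deposits), restricted to the cortical compartment;
* **astrocytes** (GFAP): soma + radial-process stars, placed near a vessel
  or a plaque with configurable probabilities, otherwise uniformly;
  vessel-/plaque-associated astrocytes are "reactive" (longer processes);
* **ICAM-1**: endothelial signal on a subset of vessels plus small
  parenchymal blobs.

Each channel is rendered as ``bias × (amplitude × blur(structure) +
background) + noise``, with a unit-mean low-order polynomial bias field
(regional staining variation — the reason the pipeline thresholds CD31
locally) and Gaussian read noise (optional Poisson shot component), clipped
and quantized to 8 bits. Ground-truth masks and the true value of every
built-in metric evaluated on those masks are returned alongside the images.

All randomness flows from one seeded generator; identical spec + seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import disk as disk_fp

from .mask_algebra import BUILTIN_METRICS, evaluate_metrics, rasterize_roi
from .types import (BinaryMask, Channel, ChannelImage, DesignRow,
                    MaskProvenance, QuantRecord, Region, RoiPolygon)


@dataclass
class SectionSpec:
    """Generator parameters for one synthetic section.

    Defaults describe a moderately affected transgenic cortex at desk scale:
    ~6% vascular area, ~10 plaques and 3 vascular-amyloid segments per
    256x256 field, 60 astrocytes of which ~40%/30% are vessel-/plaque-
    associated, 8-bit intensities with amplitude 180 over background 15,
    read-noise SD 8 (SNR ~ 20) and ±8% illumination bias.
    """

    shape_px: Tuple[int, int] = (256, 256)
    pixel_size_um: float = 1.0
    vessel_density: float = 0.06
    vessel_radius_choices: Tuple[int, ...] = (2, 3)
    n_plaques: int = 10
    plaque_radius_range_px: Tuple[int, int] = (4, 10)
    caa_segment_count: int = 3
    caa_segment_len_px: Tuple[int, int] = (15, 40)
    astro_count: int = 60
    astro_vessel_assoc_prob: float = 0.4
    astro_plaque_assoc_prob: float = 0.3
    icam_vessel_prob: float = 0.3
    icam_vascular_amp: float = 180.0
    icam_parenchymal_blob_count: int = 8
    channel_amplitudes: Dict[str, float] = field(
        default_factory=lambda: {"X34": 180.0, "CD31": 180.0,
                                 "GFAP": 180.0, "ICAM1": 180.0})
    background_level: float = 15.0
    noise_sd: float = 8.0
    shot_noise: bool = False
    bias_field_strength: float = 0.08
    render_blur_sigma: float = 0.8
    cortex_frac: float = 0.6   # left fraction of the field labelled cortex
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vessel_density", "astro_vessel_assoc_prob",
                     "astro_plaque_assoc_prob", "icam_vessel_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if (self.astro_vessel_assoc_prob + self.astro_plaque_assoc_prob) > 1.0:
            raise ValueError("association probabilities sum to > 1")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        for ch, amp in self.channel_amplitudes.items():
            if amp <= self.background_level:
                raise ValueError(f"amplitude for {ch} must exceed background")


@dataclass
class SyntheticGroundTruth:
    """True structure masks, ROIs and true metric values for one section."""

    masks: Dict[str, BinaryMask]
    rois: List[RoiPolygon]
    true_records: List[QuantRecord]
    vessel_chains: List[Tuple[List[Tuple[int, int]], int]]  # (centerline, radius)
    caa_component_labels: np.ndarray  # label image over true amyloid: 1=plaque, 2=caa


class InfeasibleSpecError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# structure synthesis helpers

def _walk_vessel(rng: np.random.Generator, shape: Tuple[int, int],
                 start: Tuple[float, float], theta: float,
                 max_steps: int = 500, turn_sd: float = 0.10
                 ) -> List[Tuple[int, int]]:
    """Persistent random-walk centreline, rasterized to an 8-connected chain."""
    h, w = shape

    def _px(r: float, c: float) -> Tuple[int, int]:
        return (min(max(int(round(r)), 0), h - 1),
                min(max(int(round(c)), 0), w - 1))

    r, c = start
    pts = [_px(r, c)]
    for _ in range(max_steps):
        theta += rng.normal(0.0, turn_sd)
        r += np.sin(theta)
        c += np.cos(theta)
        if not (0 <= r < h and 0 <= c < w):
            break
        p = _px(r, c)
        if p != pts[-1]:
            pts.append(p)
    # join rounded points with digital lines to guarantee connectivity
    chain: List[Tuple[int, int]] = [pts[0]]
    for p0, p1 in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(*p0, *p1)
        for q in zip(rr.tolist()[1:], cc.tolist()[1:]):
            chain.append(q)
    return chain


def _chain_mask(chain: Sequence[Tuple[int, int]],
                shape: Tuple[int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    rr = np.array([p[0] for p in chain])
    cc = np.array([p[1] for p in chain])
    m[rr, cc] = True
    return m


def _make_vessels(rng: np.random.Generator, spec: SectionSpec
                  ) -> Tuple[np.ndarray, List[Tuple[List[Tuple[int, int]], int]]]:
    h, w = spec.shape_px
    target = spec.vessel_density * h * w
    vessel = np.zeros(spec.shape_px, dtype=bool)
    chains: List[Tuple[List[Tuple[int, int]], int]] = []
    attempts = 0
    while vessel.sum() < target:
        attempts += 1
        if attempts > 200:
            raise InfeasibleSpecError(
                f"vessel_density {spec.vessel_density} unreachable in "
                f"{spec.shape_px} after {attempts} attempts")
        side = rng.integers(4)
        if side == 0:
            start, theta = (0.0, rng.uniform(0, w)), np.pi / 2
        elif side == 1:
            start, theta = (h - 1.0, rng.uniform(0, w)), -np.pi / 2
        elif side == 2:
            start, theta = (rng.uniform(0, h), 0.0), 0.0
        else:
            start, theta = (rng.uniform(0, h), w - 1.0), np.pi
        theta += rng.normal(0, 0.4)
        chain = _walk_vessel(rng, spec.shape_px, start, theta)
        if len(chain) < 20:
            continue
        radius = int(rng.choice(spec.vessel_radius_choices))
        vessel |= ndi.binary_dilation(_chain_mask(chain, spec.shape_px),
                                      structure=disk_fp(radius))
        chains.append((chain, radius))
        # occasional branch from a random point of the parent
        if rng.uniform() < 0.5 and len(chain) > 60:
            k = int(rng.integers(10, len(chain) - 10))
            btheta = rng.uniform(0, 2 * np.pi)
            bchain = _walk_vessel(rng, spec.shape_px,
                                  tuple(map(float, chain[k])), btheta,
                                  max_steps=int(rng.integers(60, 200)))
            if len(bchain) >= 20:
                bradius = max(radius - 1, min(spec.vessel_radius_choices))
                vessel |= ndi.binary_dilation(
                    _chain_mask(bchain, spec.shape_px),
                    structure=disk_fp(bradius))
                chains.append((bchain, bradius))
    return vessel, chains


def _make_plaques(rng: np.random.Generator, spec: SectionSpec,
                  vessel: np.ndarray) -> np.ndarray:
    h, w = spec.shape_px
    plaque = np.zeros(spec.shape_px, dtype=bool)
    if spec.n_plaques == 0:
        return plaque
    dist_to_vessel = ndi.distance_transform_edt(~vessel)
    lo, hi = spec.plaque_radius_range_px
    for _ in range(spec.n_plaques):
        radius = int(rng.integers(lo, hi + 1))
        placed = False
        for _try in range(200):
            r = int(rng.integers(radius, h - radius))
            c = int(rng.integers(radius, w - radius))
            if dist_to_vessel[r, c] >= radius + 1:
                placed = True
                break
        if not placed:
            raise InfeasibleSpecError(
                "could not place a parenchymal plaque clear of vessels")
        rr, cc = draw_disk((r, c), radius, shape=spec.shape_px)
        plaque[rr, cc] = True
    return plaque


def _make_caa(rng: np.random.Generator, spec: SectionSpec,
              chains: Sequence[Tuple[List[Tuple[int, int]], int]]
              ) -> np.ndarray:
    caa = np.zeros(spec.shape_px, dtype=bool)
    if spec.caa_segment_count == 0 or not chains:
        return caa
    cortex_limit = spec.cortex_frac * spec.shape_px[1]
    lengths = np.array([len(ch) for ch, _ in chains], dtype=float)
    for _ in range(spec.caa_segment_count):
        for _try in range(100):
            idx = int(rng.choice(len(chains), p=lengths / lengths.sum()))
            chain, radius = chains[idx]
            seg_len = int(rng.integers(*spec.caa_segment_len_px))
            if len(chain) <= seg_len + 2:
                continue
            k = int(rng.integers(0, len(chain) - seg_len))
            seg = chain[k:k + seg_len]
            # keep vascular amyloid in the cortical compartment
            if np.mean([p[1] < cortex_limit for p in seg]) < 0.9:
                continue
            seg_mask = _chain_mask(seg, spec.shape_px)
            outer = ndi.binary_dilation(seg_mask, structure=disk_fp(radius + 2))
            inner_r = radius - 2
            inner = (ndi.binary_dilation(seg_mask, structure=disk_fp(inner_r))
                     if inner_r > 0 else seg_mask)
            caa |= outer & ~inner
            break
    return caa


def _make_astrocytes(rng: np.random.Generator, spec: SectionSpec,
                     vessel: np.ndarray, plaque: np.ndarray) -> np.ndarray:
    h, w = spec.shape_px
    astro = np.zeros(spec.shape_px, dtype=bool)
    vessel_px = np.argwhere(vessel)
    plaque_px = np.argwhere(plaque)
    for _ in range(spec.astro_count):
        u = rng.uniform()
        reactive = False
        if u < spec.astro_vessel_assoc_prob and len(vessel_px):
            base = vessel_px[int(rng.integers(len(vessel_px)))]
            center = base + rng.normal(0, 2.0, size=2)
            reactive = True
        elif (u < spec.astro_vessel_assoc_prob + spec.astro_plaque_assoc_prob
              and len(plaque_px)):
            base = plaque_px[int(rng.integers(len(plaque_px)))]
            center = base + rng.normal(0, 3.0, size=2)
            reactive = True
        else:
            center = np.array([rng.uniform(0, h), rng.uniform(0, w)])
        r0 = int(np.clip(round(center[0]), 0, h - 1))
        c0 = int(np.clip(round(center[1]), 0, w - 1))
        soma_r = int(rng.integers(2, 4))
        rr, cc = draw_disk((r0, c0), soma_r, shape=spec.shape_px)
        astro[rr, cc] = True
        n_proc = int(rng.integers(4, 8))
        base_angle = rng.uniform(0, 2 * np.pi)
        length_scale = 1.7 if reactive else 1.0
        star = np.zeros(spec.shape_px, dtype=bool)
        for k in range(n_proc):
            ang = base_angle + 2 * np.pi * k / n_proc + rng.normal(0, 0.2)
            length = rng.uniform(6, 10) * length_scale
            r1 = int(np.clip(round(r0 + length * np.sin(ang)), 0, h - 1))
            c1 = int(np.clip(round(c0 + length * np.cos(ang)), 0, w - 1))
            lr, lc = draw_line(r0, c0, r1, c1)
            star[lr, lc] = True
        astro |= ndi.binary_dilation(star, structure=disk_fp(1))
    return astro


def _make_icam(rng: np.random.Generator, spec: SectionSpec,
               chains: Sequence[Tuple[List[Tuple[int, int]], int]],
               vessel: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    h, w = spec.shape_px
    icam_v = np.zeros(spec.shape_px, dtype=bool)
    if chains and spec.icam_vessel_prob > 0:
        # at least one ICAM-positive vessel per section
        n_pos = max(1, int(round(spec.icam_vessel_prob * len(chains))))
        idx = rng.choice(len(chains), size=min(n_pos, len(chains)),
                         replace=False)
        for i in idx:
            chain, radius = chains[int(i)]
            icam_v |= ndi.binary_dilation(_chain_mask(chain, spec.shape_px),
                                          structure=disk_fp(radius))
    icam_v &= vessel
    icam_p = np.zeros(spec.shape_px, dtype=bool)
    dist_to_vessel = ndi.distance_transform_edt(~vessel)
    for _ in range(spec.icam_parenchymal_blob_count):
        radius = int(rng.integers(2, 5))
        for _try in range(100):
            r = int(rng.integers(radius, h - radius))
            c = int(rng.integers(radius, w - radius))
            if dist_to_vessel[r, c] >= radius + 1:
                rr, cc = draw_disk((r, c), radius, shape=spec.shape_px)
                icam_p[rr, cc] = True
                break
    return icam_v, icam_p


def _bias_field(rng: np.random.Generator, shape: Tuple[int, int],
                strength: float) -> np.ndarray:
    """Unit-mean low-order 2D polynomial illumination bias."""
    if strength == 0:
        return np.ones(shape)
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    X = 2.0 * x / max(w - 1, 1) - 1.0
    Y = 2.0 * y / max(h - 1, 1) - 1.0
    coef = rng.normal(size=5)
    f = (coef[0] * X + coef[1] * Y + coef[2] * X * Y
         + coef[3] * (X * X - 1 / 3) + coef[4] * (Y * Y - 1 / 3))
    peak = np.abs(f).max()
    if peak > 0:
        f = f / peak
    b = 1.0 + strength * f
    return b / b.mean()


def _render_channel(rng: np.random.Generator, spec: SectionSpec,
                    signal: np.ndarray, bias: np.ndarray) -> np.ndarray:
    img = bias * (signal + spec.background_level)
    if spec.shot_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _soft(mask: np.ndarray, sigma: float) -> np.ndarray:
    return ndi.gaussian_filter(mask.astype(float), sigma)


# ---------------------------------------------------------------------------
# public API

def default_rois(spec: SectionSpec) -> List[RoiPolygon]:
    """Two rectangular compartments: cortex (left) and hippocampus (right)."""
    h, w = spec.shape_px
    split = spec.cortex_frac * (w - 1)
    cortex = RoiPolygon(Region.CORTEX,
                        [(0, 0), (split, 0), (split, h - 1), (0, h - 1)])
    hipp = RoiPolygon(Region.HIPPOCAMPUS,
                      [(split + 1, 0), (w - 1, 0), (w - 1, h - 1),
                       (split + 1, h - 1)])
    return [cortex, hipp]


def generate_section(spec: SectionSpec, *, section_id: str = "",
                     animal_id: str = ""
                     ) -> Tuple[Dict[Channel, ChannelImage], SyntheticGroundTruth]:
    """Generate one synthetic section: 4 channel images plus ground truth."""
    rng = np.random.default_rng(spec.seed)
    vessel, chains = _make_vessels(rng, spec)
    plaque = _make_plaques(rng, spec, vessel)
    caa = _make_caa(rng, spec, chains)
    amyloid = plaque | caa
    astro = _make_astrocytes(rng, spec, vessel, plaque)
    icam_v, icam_p = _make_icam(rng, spec, chains, vessel)
    icam = icam_v | icam_p
    bias = _bias_field(rng, spec.shape_px, spec.bias_field_strength)

    amps = spec.channel_amplitudes
    sig = {
        Channel.X34: amps["X34"] * _soft(amyloid, spec.render_blur_sigma),
        Channel.CD31: amps["CD31"] * _soft(vessel, spec.render_blur_sigma),
        Channel.GFAP: amps["GFAP"] * _soft(astro, spec.render_blur_sigma),
        Channel.ICAM1: (spec.icam_vascular_amp
                        * _soft(icam_v, spec.render_blur_sigma)
                        + amps["ICAM1"] * _soft(icam_p, spec.render_blur_sigma)),
    }
    images = {ch: ChannelImage(_render_channel(rng, spec, s, bias), ch,
                               spec.pixel_size_um, section_id=section_id,
                               animal_id=animal_id)
              for ch, s in sig.items()}

    gt = MaskProvenance.GROUND_TRUTH
    masks = {
        "vessel": BinaryMask(vessel, gt, "vessel"),
        "plaque": BinaryMask(plaque, gt, "plaque"),
        "caa": BinaryMask(caa, gt, "caa"),
        "astro": BinaryMask(astro, gt, "astro"),
        "astro_vascular": BinaryMask(astro & vessel, gt, "astro_vascular"),
        "icam_vascular": BinaryMask(icam_v, gt, "icam_vascular"),
        "icam_parenchymal": BinaryMask(icam_p, gt, "icam_parenchymal"),
    }
    # component labels over true amyloid: plaque=1, caa=2 (caa wins overlaps)
    comp_labels = np.zeros(spec.shape_px, dtype=np.uint8)
    comp_labels[plaque] = 1
    comp_labels[caa] = 2

    true_records = _true_metrics(masks, spec, section_id=section_id,
                                 animal_id=animal_id)
    truth = SyntheticGroundTruth(masks, default_rois(spec), true_records,
                                 chains, comp_labels)
    return images, truth


def truth_metric_masks(masks: Mapping[str, BinaryMask]) -> Dict[str, BinaryMask]:
    """Relabel ground-truth structure masks to the metric-panel mask labels."""
    return {
        "X34": masks["plaque"] | masks["caa"],
        "CD31": masks["vessel"],
        "GFAP": masks["astro"],
        "ICAM1": masks["icam_vascular"] | masks["icam_parenchymal"],
        "CAA": masks["caa"],
    }


def _true_metrics(masks: Mapping[str, BinaryMask], spec: SectionSpec, *,
                  section_id: str = "", animal_id: str = ""
                  ) -> List[QuantRecord]:
    metric_masks = truth_metric_masks(masks)
    out: List[QuantRecord] = []
    for poly in default_rois(spec):
        roi = rasterize_roi(poly, spec.shape_px)
        out.extend(evaluate_metrics(metric_masks, roi, BUILTIN_METRICS,
                                    animal_id=animal_id, section_id=section_id,
                                    region=poly.region.value))
    return out


# ---------------------------------------------------------------------------
# cohorts

GROUPS: List[Tuple[str, str]] = [("WT", "HEM"), ("WT", "KO"),
                                 ("APPPS1", "HEM"), ("APPPS1", "KO")]


def generate_cohort(group_specs: Mapping[Tuple[str, str], SectionSpec],
                    n_per_group: int, sections_per_animal: int = 3,
                    seed: int = 0, animal_cv: float = 0.15):
    """Generate a 2x2 cohort of synthetic animals.

    ``group_specs`` maps every (app_genotype, apoa1_genotype) pair to the
    SectionSpec describing that group's structural parameters; per-animal
    variability multiplies the structure counts by a lognormal factor with
    coefficient of variation ``animal_cv``. All section seeds derive
    deterministically from ``seed``.

    Returns ``(sections, design, truth_table)`` where ``sections`` maps
    section_id to ``(images, truth, animal_id)``, ``design`` is the list of
    :class:`DesignRow`, and ``truth_table`` is the tidy per-section true
    metric table.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    missing = [g for g in GROUPS if g not in group_specs]
    if missing:
        raise ValueError(f"missing group spec(s): {missing}")
    ss = np.random.SeedSequence(seed)
    design: List[DesignRow] = []
    sections = {}
    truth_rows = []
    sigma = float(np.sqrt(np.log1p(animal_cv ** 2)))
    aidx = 0
    for (app, apoa1) in GROUPS:
        base = group_specs[(app, apoa1)]
        for _ in range(n_per_group):
            aidx += 1
            animal_id = f"A{aidx:03d}"
            child = ss.spawn(1)[0]
            arng = np.random.default_rng(child)
            design.append(DesignRow(animal_id, app, apoa1,
                                    "F" if arng.uniform() < 0.5 else "M"))
            mult = float(np.exp(arng.normal(-sigma ** 2 / 2, sigma)))
            aspec = replace(
                base,
                n_plaques=int(round(base.n_plaques * mult)),
                caa_segment_count=int(round(base.caa_segment_count * mult)),
                astro_count=max(int(round(base.astro_count * mult)), 1),
            )
            for s in range(sections_per_animal):
                section_id = f"{animal_id}_s{s + 1}"
                sseed = int(arng.integers(0, 2 ** 31 - 1))
                spec_s = replace(aspec, seed=sseed)
                images, truth = generate_section(spec_s, section_id=section_id,
                                                 animal_id=animal_id)
                sections[section_id] = (images, truth, animal_id)
                truth_rows.extend(truth.true_records)
    from .io import records_to_frame

    return sections, design, records_to_frame(truth_rows)


def simulate_metric_table(group_means: Mapping[Tuple[str, str], float],
                          n_per_group: int, cv: float = 0.35, seed: int = 0,
                          metric: str = "vascular_fraction.GFAP",
                          region: str = "cortex") -> pd.DataFrame:
    """Draw a per-animal metric table directly from group-level parameters.

    A fast surrogate for full image synthesis when only the statistics stage
    is exercised (power/type-I calibration at hundreds of replicates):
    per-animal values are lognormal with the configured group mean and
    coefficient of variation, so group effects are exactly the configured
    mean ratios.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(cv ** 2)))
    rows = []
    aidx = 0
    for (app, apoa1) in GROUPS:
        mean = float(group_means[(app, apoa1)])
        mu = np.log(mean) - sigma ** 2 / 2
        for _ in range(n_per_group):
            aidx += 1
            rows.append({"animal_id": f"A{aidx:03d}", "app_genotype": app,
                         "apoa1_genotype": apoa1, "region": region,
                         "metric": metric,
                         "value": float(np.exp(rng.normal(mu, sigma)))})
    return pd.DataFrame(rows)


def export_cohort(sections, design, truth_table: pd.DataFrame,
                  outdir, pixel_size_um: float = 1.0, seed: int = 0) -> "Path":
    """Write a generated cohort to disk as a ready-to-run input bundle.

    Layout: ``images/<section>_<CH>.png``, ``rois/<section>.json``,
    ``design.csv``, ``truth_records.csv`` and a ``config.yaml`` consumable by
    the pipeline. Returns the path to the config file.
    """
    from pathlib import Path

    from . import io as aio

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "rois").mkdir(parents=True, exist_ok=True)
    manifest_sections = []
    for section_id in sorted(sections):
        images, truth, animal_id = sections[section_id]
        chan_paths = {}
        for ch, img in images.items():
            rel = f"images/{section_id}_{ch.value}.png"
            from .io import write_channel_image

            write_channel_image(img, outdir / rel)
            chan_paths[ch.value] = rel
        roi_rel = f"rois/{section_id}.json"
        aio.write_roi_json(truth.rois, outdir / roi_rel)
        manifest_sections.append({"section_id": section_id,
                                  "animal_id": animal_id,
                                  "channels": chan_paths, "roi": roi_rel})
    aio.write_design_table(design, outdir / "design.csv")
    truth_table.to_csv(outdir / "truth_records.csv", index=False,
                       na_rep=aio.NA_TOKEN)
    import yaml

    config = {"design_table": "design.csv", "pixel_size_um": pixel_size_um,
              "seed": seed, "sections": manifest_sections}
    cfg_path = outdir / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return cfg_path
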