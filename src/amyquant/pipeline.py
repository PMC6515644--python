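"""End-to-end orchestration: segment → ROI → metrics → CAA → morphometry →
per-animal aggregation → statistics, driven by one YAML config.

The pipeline is deterministic under a fixed config and seed: re-running with
identical inputs produces byte-identical CSV outputs. Per-section failures
are caught, logged with section id and stage, and summarized; the remaining
sections are still processed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi

from . import __version__
from . import io as aio
from .caa import CaaParams, classify_amyloid, ingest_manual_caa, \
    label_components
from .mask_algebra import BUILTIN_METRICS, aggregate_per_animal, \
    evaluate_metrics, rasterize_roi
from .segmentation import ThresholdConfig, apply_bernsen_threshold, \
    apply_global_threshold, suggest_global_threshold
from .stats import DEFAULT_COMPARISONS, analyze_metric_table, mann_whitney, \
    unpaired_t
from .types import BinaryMask, Channel, ChannelImage, QuantRecord, \
    RoiPolygon

log = logging.getLogger("amyquant")

PathLike = Union[str, Path]

GLOBAL_CHANNELS = (Channel.X34, Channel.GFAP, Channel.ICAM1)


@dataclass
class SectionEntry:
    section_id: str
    animal_id: str
    channels: Dict[Channel, Path]
    roi: Path
    manual_caa: Optional[Path] = None


@dataclass
class RunConfig:
    """Validated run configuration (see ``load_run_config`` for the YAML)."""

    sections: List[SectionEntry]
    design_table: Path
    outdir: Path
    pixel_size_um: float = 1.0
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    global_threshold_method: str = "midpeak"
    presmooth_sigma_global: float = 0.0
    presmooth_sigma_bernsen: float = 1.2
    caa_params: CaaParams = field(default_factory=CaaParams)
    caa_auto: bool = True
    caa_regions: Tuple[str, ...] = ("cortex",)
    min_branch_px: float = 10.0
    morphometry_weighted: bool = True
    aggregation: str = "mean"
    posthoc_gate: bool = True
    simple_test_plan: Dict[str, str] = field(
        default_factory=lambda: {"total_area_pct.X34": "t",
                                 "caa_area_pct": "mannwhitney"})
    seed: int = 0
    qc_overlays: bool = False

    def validate(self) -> None:
        if not self.design_table.exists():
            raise FileNotFoundError(self.design_table)
        design = aio.read_design_table(self.design_table)
        known = {r.animal_id for r in design}
        for s in self.sections:
            if s.animal_id not in known:
                raise ValueError(
                    f"section {s.section_id}: animal {s.animal_id} "
                    f"not in design table")
            for ch, p in s.channels.items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"section {s.section_id}: {p}")
            if not Path(s.roi).exists():
                raise FileNotFoundError(f"section {s.section_id}: {s.roi}")
            if s.manual_caa is not None and not Path(s.manual_caa).exists():
                raise FileNotFoundError(
                    f"section {s.section_id}: {s.manual_caa}")


def load_run_config(path: PathLike, outdir: Optional[PathLike] = None,
                    **overrides) -> RunConfig:
    """Load a YAML run config; relative paths resolve against the YAML file."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    def _p(rel) -> Path:
        rel = Path(rel)
        return rel if rel.is_absolute() else base / rel

    sections = [SectionEntry(
        section_id=s["section_id"], animal_id=s["animal_id"],
        channels={Channel(k): _p(v) for k, v in s["channels"].items()},
        roi=_p(s["roi"]),
        manual_caa=_p(s["manual_caa"]) if s.get("manual_caa") else None)
        for s in raw["sections"]]
    thr = raw.get("threshold", {})
    tc = ThresholdConfig(
        global_thresholds={Channel(k): float(v) for k, v in
                           thr.get("global_thresholds", {}).items()},
        bernsen_radius_px=int(thr.get("bernsen_radius_px", 15)),
        bernsen_contrast_min=float(thr.get("bernsen_contrast_min", 15)),
        bernsen_low_contrast_assignment=thr.get(
            "bernsen_low_contrast_assignment", "background"))
    caa_raw = raw.get("caa", {})
    cp = CaaParams(
        overlap_min=float(caa_raw.get("overlap_min", 0.5)),
        elongation_min=float(caa_raw.get("elongation_min", 3.0)),
        dilation_px=int(caa_raw.get("dilation_px", 2)),
        min_component_px=int(caa_raw.get("min_component_px", 20)))
    cfg = RunConfig(
        sections=sections,
        design_table=_p(raw["design_table"]),
        outdir=Path(outdir) if outdir else _p(raw.get("outdir", "results")),
        pixel_size_um=float(raw.get("pixel_size_um", 1.0)),
        threshold=tc,
        global_threshold_method=raw.get("global_threshold_method", "midpeak"),
        presmooth_sigma_global=float(raw.get("presmooth_sigma_global", 0.0)),
        presmooth_sigma_bernsen=float(raw.get("presmooth_sigma_bernsen", 1.2)),
        caa_params=cp,
        caa_auto=bool(caa_raw.get("auto", True)),
        caa_regions=tuple(caa_raw.get("regions", ["cortex"])),
        min_branch_px=float(raw.get("min_branch_px", 10)),
        morphometry_weighted=bool(raw.get("morphometry_weighted", True)),
        aggregation=raw.get("aggregation", "mean"),
        posthoc_gate=bool(raw.get("posthoc_gate", True)),
        simple_test_plan=dict(raw.get("simple_test_plan",
                                      {"total_area_pct.X34": "t",
                                       "caa_area_pct": "mannwhitney"})),
        seed=int(raw.get("seed", 0)),
        qc_overlays=bool(raw.get("qc_overlays", False)))
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class PipelineResult:
    records: pd.DataFrame
    per_animal: pd.DataFrame
    anova: pd.DataFrame
    comparisons: pd.DataFrame
    simple_tests: pd.DataFrame
    vessel_edges: pd.DataFrame
    vessel_summary: pd.DataFrame
    failures: List[Dict[str, str]]
    thresholds: Dict[str, float]


def _presmooth(img: ChannelImage, sigma: float) -> ChannelImage:
    if sigma <= 0:
        return img
    arr = ndi.gaussian_filter(np.asarray(img.pixels, dtype=float), sigma)
    return ChannelImage(arr, img.channel, img.pixel_size_um,
                        section_id=img.section_id, animal_id=img.animal_id)


def segment_section(images: Mapping[Channel, ChannelImage],
                    cfg: RunConfig,
                    thresholds: Mapping[Channel, float]
                    ) -> Dict[str, BinaryMask]:
    """Threshold every channel of one section: Bernsen for CD31, global
    cutoffs (pre-determined per channel) for the rest."""
    masks: Dict[str, BinaryMask] = {}
    for ch, img in images.items():
        if ch == Channel.CD31:
            sm = _presmooth(img, cfg.presmooth_sigma_bernsen)
            masks[ch.value] = apply_bernsen_threshold(sm, cfg.threshold)
        else:
            sm = _presmooth(img, cfg.presmooth_sigma_global)
            masks[ch.value] = apply_global_threshold(sm, thresholds[ch])
    return masks


def determine_thresholds(all_images: Sequence[Mapping[Channel, ChannelImage]],
                         cfg: RunConfig) -> Dict[Channel, float]:
    """One global cutoff per channel: configured value if present, otherwise
    suggested from the pooled histogram of all (pre-smoothed) sections."""
    out: Dict[Channel, float] = {}
    for ch in GLOBAL_CHANNELS:
        if ch in cfg.threshold.global_thresholds:
            out[ch] = float(cfg.threshold.global_thresholds[ch])
            continue
        imgs = [_presmooth(sec[ch], cfg.presmooth_sigma_global)
                for sec in all_images if ch in sec]
        if imgs:
            out[ch] = suggest_global_threshold(
                imgs, method=cfg.global_threshold_method)
    return out


def quantify_section(section_id: str, animal_id: str,
                     images: Mapping[Channel, ChannelImage],
                     rois: Sequence[RoiPolygon], cfg: RunConfig,
                     thresholds: Mapping[Channel, float],
                     manual_caa: Optional[BinaryMask] = None):
    """All per-section measurements: metric records + vessel tables."""
    from .vessels import analyze_vessels, summarize_morphometry

    shape = next(iter(images.values())).shape
    masks = segment_section(images, cfg, thresholds)

    caa_mask: Optional[BinaryMask] = None
    if Channel.X34.value in masks:
        if manual_caa is not None:
            caa_mask = ingest_manual_caa(manual_caa, masks[Channel.X34.value])
        elif cfg.caa_auto and Channel.CD31.value in masks:
            comps = label_components(masks[Channel.X34.value],
                                     cfg.caa_params.min_component_px)
            caa_mask, _ = classify_amyloid(comps, masks[Channel.CD31.value],
                                           cfg.caa_params, shape)

    records: List[QuantRecord] = []
    edge_frames, summary_rows = [], []
    for poly in rois:
        roi = rasterize_roi(poly, shape)
        region = poly.region.value
        sec_masks = dict(masks)
        if caa_mask is not None and region in cfg.caa_regions:
            sec_masks["CAA"] = caa_mask
        records.extend(evaluate_metrics(sec_masks, roi, BUILTIN_METRICS,
                                        animal_id=animal_id,
                                        section_id=section_id, region=region))
        if Channel.CD31.value in masks:
            regional = BinaryMask(masks[Channel.CD31.value].pixels & roi.pixels)
            graph = analyze_vessels(regional, cfg.pixel_size_um,
                                    cfg.min_branch_px)
            summ = summarize_morphometry(graph, cfg.morphometry_weighted)
            ef = graph.to_frame(section_id)
            ef.insert(1, "region", region)
            edge_frames.append(ef)
            summary_rows.append({"section_id": section_id,
                                 "animal_id": animal_id, "region": region,
                                 **summ})
            for key in ("mean_diameter_um", "mean_tortuosity"):
                v = summ[key]
                records.append(QuantRecord(
                    animal_id, section_id, region,
                    "vessel_tortuosity_mean" if key == "mean_tortuosity"
                    else "vessel_diameter_mean_um",
                    0, 0 if not np.isfinite(v) else 1,
                    None if not np.isfinite(v) else float(v), scale="raw"))
    edge_frames = [f for f in edge_frames if len(f)]
    edges = (pd.concat(edge_frames, ignore_index=True) if edge_frames
             else pd.DataFrame())
    return records, edges, summary_rows


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run the full analysis and write the results bundle to ``cfg.outdir``."""
    cfg.validate()
    design = aio.read_design_table(cfg.design_table)
    design_df = pd.DataFrame([dataclasses.asdict(r) for r in design])

    loaded: List[Dict[Channel, ChannelImage]] = []
    for s in cfg.sections:
        loaded.append({ch: aio.read_channel_image(p, ch, cfg.pixel_size_um,
                                                  section_id=s.section_id,
                                                  animal_id=s.animal_id)
                       for ch, p in s.channels.items()})
    thresholds = determine_thresholds(loaded, cfg)
    log.info("global thresholds: %s",
             {ch.value: round(t, 3) for ch, t in thresholds.items()})

    all_records: List[QuantRecord] = []
    edge_frames, summary_rows, failures = [], [], []
    for s, images in zip(cfg.sections, loaded):
        stage = "roi"
        try:
            shape = next(iter(images.values())).shape
            rois = aio.read_roi(s.roi, shape)
            manual = (aio.read_mask(s.manual_caa) if s.manual_caa else None)
            stage = "quantify"
            recs, edges, summ = quantify_section(
                s.section_id, s.animal_id, images, rois, cfg, thresholds,
                manual)
            all_records.extend(recs)
            if len(edges):
                edge_frames.append(edges)
            summary_rows.extend(summ)
            log.info("section %s: %d records", s.section_id, len(recs))
        except Exception as exc:  # noqa: BLE001 - summarize, keep going
            failures.append({"section_id": s.section_id, "stage": stage,
                             "error": str(exc)})
            log.error("section %s failed at %s: %s", s.section_id, stage, exc)

    records = aio.records_to_frame(all_records)
    per_animal = aggregate_per_animal(records, cfg.aggregation)
    per_animal = per_animal.merge(design_df, on="animal_id", how="left")

    anova, comparisons = analyze_metric_table(
        per_animal, DEFAULT_COMPARISONS, posthoc_gate=cfg.posthoc_gate)
    simple = _simple_tests(per_animal, cfg.simple_test_plan)

    vessel_edges = (pd.concat(edge_frames, ignore_index=True)
                    if edge_frames else pd.DataFrame(
                        columns=["section_id", "region", "edge_id",
                                 "path_length_um", "chord_length_um",
                                 "diameter_um", "tortuosity"]))
    vessel_summary = pd.DataFrame(summary_rows)

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records.to_csv(outdir / "quant_records.csv", index=False,
                   na_rep=aio.NA_TOKEN)
    per_animal.to_csv(outdir / "per_animal.csv", index=False,
                      na_rep=aio.NA_TOKEN)
    anova.to_csv(outdir / "anova.csv", index=False, na_rep=aio.NA_TOKEN)
    comparisons.to_csv(outdir / "comparisons.csv", index=False,
                       na_rep=aio.NA_TOKEN)
    simple.to_csv(outdir / "simple_tests.csv", index=False,
                  na_rep=aio.NA_TOKEN)
    vessel_edges.to_csv(outdir / "vessel_edges.csv", index=False,
                        na_rep=aio.NA_TOKEN)
    vessel_summary.to_csv(outdir / "vessel_summary.csv", index=False,
                          na_rep=aio.NA_TOKEN)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "n_sections": len(cfg.sections),
        "thresholds": {ch.value: thresholds[ch] for ch in thresholds},
        "bernsen": {"radius_px": cfg.threshold.bernsen_radius_px,
                    "contrast_min": cfg.threshold.bernsen_contrast_min,
                    "low_contrast": cfg.threshold.bernsen_low_contrast_assignment},
        "caa": dataclasses.asdict(cfg.caa_params),
        "aggregation": cfg.aggregation,
        "posthoc_gate": cfg.posthoc_gate,
        "failures": failures,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1,
                                                         sort_keys=True))
    if cfg.qc_overlays:
        qcdir = outdir / "qc"
        for s, images in zip(cfg.sections, loaded):
            try:
                masks = segment_section(images, cfg, thresholds)
                overlays = make_qc_overlays(images, masks)
                for name, arr in overlays.items():
                    aio.iio.imwrite(qcdir / f"{s.section_id}_{name}.png", arr)
            except Exception as exc:  # noqa: BLE001
                log.error("QC overlay failed for %s: %s", s.section_id, exc)
    return PipelineResult(records, per_animal, anova, comparisons, simple,
                          vessel_edges, vessel_summary, failures,
                          {ch.value: float(t) for ch, t in thresholds.items()})


def _simple_tests(per_animal: pd.DataFrame,
                  plan: Mapping[str, str]) -> pd.DataFrame:
    """Two-group tests (transgenic KO vs HEM) for the metrics in the plan."""
    rows = []
    for metric, test in sorted(plan.items()):
        for region, sub in per_animal[per_animal["metric"] == metric] \
                .groupby("region", sort=True):
            sub = sub.dropna(subset=["value"])
            x = sub[(sub.app_genotype == "APPPS1")
                    & (sub.apoa1_genotype == "KO")]["value"].to_numpy()
            y = sub[(sub.app_genotype == "APPPS1")
                    & (sub.apoa1_genotype == "HEM")]["value"].to_numpy()
            if len(x) < 2 or len(y) < 2:
                continue
            if test == "t":
                t, df, p = unpaired_t(x, y)
                stat, statname = t, "t"
            elif test == "welch":
                t, df, p = unpaired_t(x, y, welch=True)
                stat, statname = t, "t_welch"
            else:
                u, p = mann_whitney(x, y)
                stat, statname, df = u, "U", np.nan
            rows.append({"metric": metric, "region": region, "test": statname,
                         "group_i": "APPPS1/KO", "group_j": "APPPS1/HEM",
                         "mean_i": float(x.mean()), "mean_j": float(y.mean()),
                         "stat": float(stat), "df": df, "p": float(p)})
    return pd.DataFrame(rows, columns=["metric", "region", "test", "group_i",
                                       "group_j", "mean_i", "mean_j", "stat",
                                       "df", "p"])


# ---------------------------------------------------------------------------
# QC overlays

_TINTS = {Channel.X34: (0, 130, 255), Channel.CD31: (255, 60, 60),
          Channel.GFAP: (60, 255, 60), Channel.ICAM1: (255, 200, 0)}
CAA_COLOR = (0, 190, 190)      # vascular amyloid: teal
PLAQUE_COLOR = (60, 220, 60)   # parenchymal amyloid: green


def make_qc_overlays(images: Mapping[Channel, ChannelImage],
                     masks: Mapping[str, BinaryMask],
                     caa_mask: Optional[BinaryMask] = None,
                     plaque_mask: Optional[BinaryMask] = None
                     ) -> Dict[str, np.ndarray]:
    """Color overlays of each segmented mask on its channel; optional CAA
    classification overlay with vascular/parenchymal coloring."""
    out: Dict[str, np.ndarray] = {}
    for ch, img in images.items():
        base = np.asarray(img.pixels, dtype=float)
        if base.max() > 0:
            base = base / base.max() * 255.0
        rgb = np.stack([base] * 3, axis=-1)
        mask = masks.get(ch.value)
        if mask is not None:
            if mask.shape != img.shape:
                raise ValueError(f"{ch.value}: mask/image shape mismatch")
            color = np.array(_TINTS[ch], dtype=float)
            rgb[mask.pixels] = 0.5 * rgb[mask.pixels] + 0.5 * color
        out[ch.value] = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    if caa_mask is not None and plaque_mask is not None:
        base = np.asarray(images[Channel.X34].pixels, dtype=float)
        if base.max() > 0:
            base = base / base.max() * 255.0
        rgb = np.stack([base] * 3, axis=-1)
        rgb[caa_mask.pixels] = (0.4 * rgb[caa_mask.pixels]
                                + 0.6 * np.array(CAA_COLOR, dtype=float))
        rgb[plaque_mask.pixels] = (0.4 * rgb[plaque_mask.pixels]
                                   + 0.6 * np.array(PLAQUE_COLOR, dtype=float))
        out["caa_classification"] = np.clip(np.round(rgb), 0,
                                            255).astype(np.uint8)
    return out
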