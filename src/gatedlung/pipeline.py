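"""End-to-end orchestration: load pair -> (filter) -> calibrate -> segment
-> measure -> FRC/VT -> study table -> statistics -> report.

All tunables live in :class:`RunConfig`; every output row carries the
animal, week and a hash of the configuration, and a fixed seed makes the
whole run reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import calibrate, metrics, segment, stats
from .image import Box, VolumeImage, load_volume

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Analysis configuration (defaults follow the acquisition protocol:
    -160 HU growing threshold, CT#_air = -1000 HU, alpha = 0.05, 350 ms
    second-trigger delay, 0.075 mm isotropic voxels)."""

    threshold_hu: float = -160.0
    ct_air_hu: float = -1000.0
    connectivity: int = 26
    alpha: float = 0.05
    bilateral: bool = False
    sigma_spatial_mm: float = 0.075
    sigma_range_hu: float = 100.0
    histogram_bin_width_hu: float = 25.0
    histogram_range_hu: tuple[float, float] = (-1000.0, 200.0)
    compute_histograms: bool = True
    superior_margin_mm: float = 2.0
    leak_max_faces: int = 2
    leak_max_volume_fraction: float = 0.9
    max_retries: int = 3
    retry_step_mm: float = 0.5
    gating_delay_ms: float = 350.0
    week_baseline: float = 12.0
    voxel_spacing_mm: float = 0.075
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.histogram_range_hu, list):
            cfg.histogram_range_hu = tuple(cfg.histogram_range_hu)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SubjectResult:
    rows: list[dict]
    function: metrics.FunctionMetrics
    masks: dict
    measurements: dict
    histograms: list[metrics.CTHistogram] = field(default_factory=list)


def _prepare_phase(image: VolumeImage, config: RunConfig):
    """Filter (optional), calibrate, and segment one phase image."""
    img = image
    if config.bilateral and img.scale == "raw":
        slope = abs(img.meta.get("raw_per_hu", 1.0))
        img = calibrate.bilateral_filter(
            img, config.sigma_spatial_mm, config.sigma_range_hu * slope
        )
    if img.scale == "raw":
        refs = calibrate.refs_from_image(img)
        img = calibrate.rescale_to_hu(img, refs)
    carina = img.meta.get("carina_voxel")
    if carina is None:
        raise ValueError("no carina landmark in image metadata")
    roi = segment.define_lung_roi(img, carina, margin_mm=config.superior_margin_mm)
    seed_voxel = img.meta.get("seed_voxel")
    if seed_voxel is None or not roi.box.contains(tuple(seed_voxel)):
        seed_voxel = segment.choose_seed(img, roi)
    lung = segment.segment_with_retry(
        img,
        tuple(seed_voxel),
        roi,
        threshold_hu=config.threshold_hu,
        connectivity=config.connectivity,
        max_retries=config.max_retries,
        step_mm=config.retry_step_mm,
        max_faces=config.leak_max_faces,
        max_volume_fraction=config.leak_max_volume_fraction,
    )
    return img, lung


def run_subject(
    expiration: VolumeImage,
    inspiration: VolumeImage,
    config: RunConfig | None = None,
    animal_id: str | None = None,
    group: str | None = None,
    week: float | None = None,
) -> SubjectResult:
    """Analyze one paired-phase scan into study-table rows plus FRC/VT."""
    config = config or RunConfig()
    if expiration.phase != "expiration" or inspiration.phase != "inspiration":
        raise ValueError("run_subject expects (expiration, inspiration) in that order")
    animal_id = animal_id or expiration.subject or "subject"
    week = week if week is not None else (expiration.timepoint or 0.0)

    results = {}
    masks = {}
    for img in (expiration, inspiration):
        hu_img, lung = _prepare_phase(img, config)
        results[img.phase] = (hu_img, lung)
        masks[img.phase] = lung

    meas = {
        phase: metrics.measure_lung(hu_img, lung)
        for phase, (hu_img, lung) in results.items()
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fun = metrics.lung_function(
            meas["expiration"], meas["inspiration"], config.ct_air_hu
        )
    if fun.negative_vt:
        log.warning("%s wk%s: negative VT (%.4g mL)", animal_id, week, fun.vt_ml)

    rows = []
    for phase in ("expiration", "inspiration"):
        m = meas[phase]
        rows.append(
            dict(
                animal_id=animal_id,
                group=group,
                week=week,
                phase=phase,
                volume_ml=m.volume_ml,
                mean_ct_hu=m.mean_ct_hu,
                frc_ml=fun.frc_ml,
                vt_ml=fun.vt_ml,
                leak_flag=bool(masks[phase].leak_flag),
                negative_vt=fun.negative_vt,
                retries=masks[phase].retries,
                config_hash=config.config_hash,
            )
        )

    hists = []
    if config.compute_histograms:
        for phase, (hu_img, lung) in results.items():
            hists.append(
                metrics.ct_histogram(
                    hu_img, lung, config.histogram_bin_width_hu, config.histogram_range_hu
                )
            )
    return SubjectResult(rows=rows, function=fun, masks=masks,
                         measurements=meas, histograms=hists)


@dataclass
class StudyResult:
    study: pd.DataFrame
    deltas: pd.DataFrame | None
    percent_change: pd.DataFrame | None
    comparisons: dict
    histograms: pd.DataFrame | None
    skipped: list
    config_hash: str


def _load_manifest_records(manifest: str | Path) -> list[dict]:
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    records = []
    for _, row in df.iterrows():
        meta = {}
        for key in ("carina_voxel", "seed_voxel"):
            if key in row and isinstance(row[key], str):
                meta[key] = tuple(json.loads(row[key]))
        for key in ("trachea_roi", "water_roi"):
            if key in row and isinstance(row[key], str):
                meta[key] = Box.from_json(json.loads(row[key]))
        rec = dict(animal_id=row["animal_id"], group=row["group"], week=row["week"])
        for phase in ("expiration", "inspiration"):
            img = load_volume(
                manifest.parent / row[f"path_{phase}"],
                phase=phase,
                scale="raw",
                subject=row["animal_id"],
                timepoint=row["week"],
                meta=meta,
            )
            rec[phase] = img
        records.append(rec)
    return records


def run_study(
    records: Sequence[dict] | str | Path,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> StudyResult:
    """Analyze a whole study: per-subject measurements, per-endpoint group
    statistics, longitudinal deltas and percent changes.

    ``records`` is either the in-memory cohort from
    :func:`gatedlung.phantom.generate_cohort` or a path to a manifest CSV
    (columns: animal_id, group, week, path_expiration, path_inspiration
    and the calibration/landmark JSON columns).  Unreadable or failing
    subjects are recorded and skipped; the run continues.
    """
    config = config or RunConfig()
    if isinstance(records, (str, Path)):
        records = _load_manifest_records(records)

    rows: list[dict] = []
    hist_rows: list[dict] = []
    skipped: list[dict] = []
    for rec in records:
        try:
            res = run_subject(
                rec["expiration"], rec["inspiration"], config,
                animal_id=rec.get("animal_id"), group=rec.get("group"),
                week=rec.get("week"),
            )
        except Exception as exc:  # noqa: BLE001 - per-row robustness
            log.error("subject %s wk%s failed: %s", rec.get("animal_id"),
                      rec.get("week"), exc)
            skipped.append(dict(animal_id=rec.get("animal_id"),
                                week=rec.get("week"), error=str(exc)))
            continue
        rows.extend(res.rows)
        for h in res.histograms:
            for lo, hi, c in zip(h.bin_edges_hu[:-1], h.bin_edges_hu[1:], h.counts):
                hist_rows.append(
                    dict(animal_id=rec.get("animal_id"), group=rec.get("group"),
                         week=rec.get("week"), phase=h.phase,
                         bin_lo_hu=lo, bin_hi_hu=hi, count=c)
                )

    study = pd.DataFrame(rows)
    if study.empty:
        raise ValueError("no subject could be analyzed")

    n_leak = int(study["leak_flag"].sum())
    if n_leak:
        log.warning("%d study rows carry leak flags; group summaries include them "
                    "with visible counts", n_leak)

    # endpoint = each animal's latest week
    wide = metrics._study_wide(metrics.validate_study_table(study))
    endpoint_idx = wide.groupby("animal_id")["week"].idxmax()
    endpoint = wide.loc[endpoint_idx]
    comparisons = {}
    group_sizes = endpoint.groupby("group").size()
    if len(group_sizes) >= 2 and (group_sizes >= 2).all():
        for metric in ("frc_ml", "vt_ml", "volume_expiration_ml", "volume_inspiration_ml"):
            try:
                comparisons[metric] = stats.compare_groups(
                    endpoint, metric, method="anova_tukey", alpha=config.alpha
                )
            except ValueError as exc:
                log.warning("comparison on %s skipped: %s", metric, exc)

    deltas = pct = None
    if study["week"].nunique() > 1:
        try:
            deltas = metrics.longitudinal_change(study, week_a=config.week_baseline)
            pct = pd.concat(
                [
                    metrics.group_percent_change(study, m, week_a=config.week_baseline)
                    for m in ("frc_ml", "vt_ml", "volume_expiration_ml",
                              "volume_inspiration_ml")
                ],
                ignore_index=True,
            )
        except ValueError as exc:
            log.warning("longitudinal analysis skipped: %s", exc)

    hist_df = pd.DataFrame(hist_rows) if hist_rows else None
    result = StudyResult(
        study=study, deltas=deltas, percent_change=pct, comparisons=comparisons,
        histograms=hist_df, skipped=skipped, config_hash=config.config_hash,
    )
    if out_dir is not None:
        _write_report(result, config, Path(out_dir))
    return result


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash} seed={config.seed}\n")
        df.to_csv(fh, index=False)


def _write_report(result: StudyResult, config: RunConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_csv(result.study, out_dir / "study.csv", config)
    if result.deltas is not None:
        _write_csv(result.deltas, out_dir / "longitudinal_deltas.csv", config)
    if result.percent_change is not None:
        _write_csv(result.percent_change, out_dir / "percent_change.csv", config)
    if result.histograms is not None:
        _write_csv(result.histograms, out_dir / "histograms.csv", config)
    if result.comparisons:
        omni = pd.DataFrame(
            [
                dict(metric=m, method=r.method, statistic=r.statistic,
                     df1=r.df[0], df2=r.df[1], p_value=r.p_value, alpha=r.alpha)
                for m, r in result.comparisons.items()
            ]
        )
        _write_csv(omni, out_dir / "stats_omnibus.csv", config)
        pairs = pd.concat(
            [r.pairwise.assign(metric=m) for m, r in result.comparisons.items()],
            ignore_index=True,
        )
        _write_csv(pairs, out_dir / "stats_pairwise.csv", config)
    meta = dict(
        config=config.to_dict(), config_hash=config.config_hash,
        seed=config.seed, skipped=result.skipped,
        versions={"numpy": np.__version__, "pandas": pd.__version__},
    )
    (out_dir / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=str))


def flag_abnormal(
    measurement: metrics.LungMeasurement,
    control_mean_ct: Sequence[float],
    n_sd: float = 2.0,
) -> bool:
    """Quantitative injury flag: the lung's mean CT number exceeds the
    control-group mean by more than ``n_sd`` control SDs (density
    increase = reduced air content)."""
    control = np.asarray(control_mean_ct, float)
    if control.size < 2:
        raise ValueError("need at least 2 control values for a reference distribution")
    return bool(
        measurement.mean_ct_hu > control.mean() + n_sd * control.std(ddof=1)
    )
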