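"""Lung-function metrics from segmented gated micro-CT pairs.

With the lung segmented at each respiratory phase, the measured quantities
are the segmented volume V (mL) and the mean CT number over the mask
(HU).  Because lung tissue is an air/tissue mixture on a scale anchored at
air = -1000 HU and tissue/water = 0 HU, the mean CT number measures the
air fraction, giving the functional residual capacity and tidal volume

    FRC = V_exp  * CT#_exp  / CT#_air
    VT  = V_insp * CT#_insp / CT#_air - FRC

with CT#_air = -1000 HU by convention (config-overridable).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image import VolumeImage
from .segment import LungMask

log = logging.getLogger(__name__)

CT_AIR_HU = -1000.0
MM3_PER_ML = 1000.0


@dataclass(frozen=True)
class LungMeasurement:
    """Segmented lung volume and mean CT number for one respiratory phase."""

    phase: str
    volume_ml: float
    mean_ct_hu: float
    voxel_count: int


@dataclass
class FunctionMetrics:
    """FRC and VT in mL, with quality flags."""

    frc_ml: float
    vt_ml: float
    ct_air_hu: float = CT_AIR_HU
    positive_mean_ct: bool = False
    negative_vt: bool = False


@dataclass(frozen=True)
class CTHistogram:
    """Histogram of CT numbers within the lung mask."""

    bin_edges_hu: np.ndarray
    counts: np.ndarray
    phase: str
    normalized: bool

    @property
    def mean_hu(self) -> float:
        centers = 0.5 * (self.bin_edges_hu[:-1] + self.bin_edges_hu[1:])
        total = self.counts.sum()
        return float((centers * self.counts).sum() / total)


def measure_lung(image: VolumeImage, lung: LungMask | np.ndarray) -> LungMeasurement:
    """Volume (voxel count x voxel volume) and mean HU over the mask."""
    if image.scale != "HU":
        raise ValueError("lung measurement requires a calibrated (HU-scale) image")
    mask = lung.mask if isinstance(lung, LungMask) else np.asarray(lung, bool)
    if mask.shape != image.shape:
        raise ValueError("mask is not aligned to the image grid")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty lung mask")
    return LungMeasurement(
        phase=image.phase,
        volume_ml=n * image.voxel_volume_mm3 / MM3_PER_ML,
        mean_ct_hu=float(image.values[mask].mean()),
        voxel_count=n,
    )


def compute_frc(expiration: LungMeasurement, ct_air_hu: float = CT_AIR_HU) -> float:
    """Functional residual capacity: ``V_exp * CT#_exp / CT#_air`` (mL)."""
    if ct_air_hu == 0:
        raise ValueError("CT number of air cannot be zero")
    if expiration.phase == "inspiration":
        raise ValueError("FRC is computed from the end-expiration measurement")
    if expiration.mean_ct_hu > 0:
        warnings.warn(
            f"mean expiratory CT number is positive ({expiration.mean_ct_hu:.1f} HU); "
            "FRC returned unclamped",
            stacklevel=2,
        )
    return expiration.volume_ml * expiration.mean_ct_hu / ct_air_hu


def compute_vt(
    inspiration: LungMeasurement, frc_ml: float, ct_air_hu: float = CT_AIR_HU
) -> float:
    """Tidal volume: ``V_insp * CT#_insp / CT#_air - FRC`` (mL).

    Negative values are permitted but indicate probable phase
    misassignment; a warning is emitted.
    """
    if ct_air_hu == 0:
        raise ValueError("CT number of air cannot be zero")
    if inspiration.phase == "expiration":
        raise ValueError("VT is computed from the peak-inspiration measurement")
    vt = inspiration.volume_ml * inspiration.mean_ct_hu / ct_air_hu - frc_ml
    if vt < 0:
        warnings.warn(
            f"negative tidal volume ({vt:.4g} mL): possible phase misassignment",
            stacklevel=2,
        )
    return vt


def lung_function(
    expiration: LungMeasurement,
    inspiration: LungMeasurement,
    ct_air_hu: float = CT_AIR_HU,
) -> FunctionMetrics:
    """FRC and VT from the paired phase measurements, with flags."""
    frc = compute_frc(expiration, ct_air_hu)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vt = compute_vt(inspiration, frc, ct_air_hu)
    return FunctionMetrics(
        frc_ml=frc,
        vt_ml=vt,
        ct_air_hu=ct_air_hu,
        positive_mean_ct=expiration.mean_ct_hu > 0 or inspiration.mean_ct_hu > 0,
        negative_vt=vt < 0,
    )


def ct_histogram(
    image: VolumeImage,
    lung: LungMask | np.ndarray,
    bin_width_hu: float = 25.0,
    hu_range: tuple[float, float] = (-1000.0, 200.0),
    normalize: bool = False,
) -> CTHistogram:
    """Histogram of masked CT numbers over half-open bins [e_i, e_{i+1}).

    Values outside ``hu_range`` are clipped into the end bins, so counts
    always sum to the masked voxel count (or 1 when normalized).
    """
    if bin_width_hu <= 0:
        raise ValueError("bin width must be positive")
    mask = lung.mask if isinstance(lung, LungMask) else np.asarray(lung, bool)
    vals = image.values[mask]
    if vals.size == 0:
        raise ValueError("empty lung mask")
    lo, hi = hu_range
    n_bins = int(np.ceil((hi - lo) / bin_width_hu))
    edges = lo + bin_width_hu * np.arange(n_bins + 1)
    clipped = np.clip(vals, lo, np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(clipped, bins=edges)
    counts = counts.astype(float)
    if normalize:
        counts = counts / counts.sum()
    return CTHistogram(
        bin_edges_hu=edges, counts=counts, phase=image.phase, normalized=normalize
    )


# ---------------------------------------------------------------------------
# Study table and longitudinal analysis

STUDY_COLUMNS = [
    "animal_id", "group", "week", "phase",
    "volume_ml", "mean_ct_hu", "frc_ml", "vt_ml", "leak_flag",
]

_METRICS_WIDE = ["volume_expiration_ml", "volume_inspiration_ml", "frc_ml", "vt_ml"]


def validate_study_table(study: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in STUDY_COLUMNS if c not in study.columns]
    if missing:
        raise ValueError(f"study table is missing columns: {missing}")
    if (study["week"] < 0).any():
        raise ValueError("weeks must be non-negative")
    dup = study.duplicated(subset=["animal_id", "week", "phase"])
    if dup.any():
        raise ValueError("duplicate (animal, week, phase) rows in study table")
    return study


def _study_wide(study: pd.DataFrame) -> pd.DataFrame:
    """One row per (animal, week) with per-phase volumes and FRC/VT."""
    piv = study.pivot_table(
        index=["animal_id", "group", "week"],
        columns="phase",
        values="volume_ml",
        aggfunc="first",
    ).rename(
        columns={
            "expiration": "volume_expiration_ml",
            "inspiration": "volume_inspiration_ml",
        }
    )
    fun = study.groupby(["animal_id", "group", "week"])[["frc_ml", "vt_ml"]].first()
    return piv.join(fun).reset_index()


def longitudinal_change(
    study: pd.DataFrame, week_a: float = 12.0, week_b: float | None = None
) -> pd.DataFrame:
    """Per-animal change between ``week_a`` and ``week_b`` (default: each
    animal's latest week, the study endpoint).

    Deltas are ``value(week_b) - value(week_a)``: negative means a
    reduction at the endpoint.  Animals missing either week are skipped
    (logged).  Also reports per-animal percent change.
    """
    validate_study_table(study)
    wide = _study_wide(study)
    rows = []
    skipped = 0
    for (animal, group), sub in wide.groupby(["animal_id", "group"]):
        wa = sub[sub["week"] == week_a]
        endpoint = week_b if week_b is not None else sub["week"].max()
        wb = sub[sub["week"] == endpoint]
        if wa.empty or wb.empty or endpoint == week_a:
            skipped += 1
            continue
        row = dict(animal_id=animal, group=group, week_a=week_a, week_b=endpoint)
        for m in _METRICS_WIDE:
            a = float(wa[m].iloc[0])
            b = float(wb[m].iloc[0])
            row[f"delta_{m}"] = b - a
            row[f"pct_change_{m}"] = 100.0 * (b - a) / a if a != 0 else np.nan
        rows.append(row)
    if skipped:
        log.info("longitudinal change: %d animal(s) lacked both weeks and were skipped", skipped)
    if not rows:
        raise ValueError(f"no animal has measurements at both week {week_a} and the endpoint")
    return pd.DataFrame(rows)


def group_percent_change(
    study: pd.DataFrame,
    metric: str = "frc_ml",
    week_a: float = 12.0,
    week_b: float | None = None,
) -> pd.DataFrame:
    """Per-group percent change of the group mean between two weeks.

    The primary column (``pct_change_of_mean``) is the percent change of
    the group means; ``mean_pct_change`` (mean of per-animal percent
    changes) is also reported since the two summaries differ under
    animal-level variation.
    """
    deltas = longitudinal_change(study, week_a, week_b)
    wide = _study_wide(validate_study_table(study))
    if metric not in _METRICS_WIDE:
        raise ValueError(f"metric must be one of {_METRICS_WIDE}")
    rows = []
    for group, sub in deltas.groupby("group"):
        animals = sub["animal_id"]
        ga = wide[(wide["group"] == group) & (wide["week"] == week_a)
                  & wide["animal_id"].isin(animals)]
        gb_week = sub["week_b"].iloc[0]
        gb = wide[(wide["group"] == group) & (wide["week"] == gb_week)
                  & wide["animal_id"].isin(animals)]
        if ga.empty or gb.empty:
            raise ValueError(f"group {group!r} has no complete animals")
        mean_a = float(ga[metric].mean())
        mean_b = float(gb[metric].mean())
        rows.append(
            dict(
                group=group,
                metric=metric,
                n=len(sub),
                week_a=week_a,
                week_b=gb_week,
                mean_a=mean_a,
                mean_b=mean_b,
                pct_change_of_mean=100.0 * (mean_b - mean_a) / mean_a,
                mean_pct_change=float(sub[f"pct_change_{metric}"].mean()),
            )
        )
    return pd.DataFrame(rows)
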