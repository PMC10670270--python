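"""Attenuation sampling, net water uptake and cohort summaries.

Net water uptake (NWU) expresses the relative attenuation drop of ischemic
tissue against the homologous contralateral tissue:

    NWU (%) = (1 - HU_ischemic / HU_normal) x 100

Cohort results are grouped by onset-to-CT time window (0-6, >6-12, >12-24,
>24-36 h).  The window NWU summary is the mean of per-case NWU values, which
differs in general from the NWU of the window-mean HU values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, EmptySelectionError, OutOfRangeError, ValidationError
from .images import SegmentationMask, VolumeImage

TIME_WINDOWS: tuple[tuple[str, float, float], ...] = (
    ("0–6 h", 0.0, 6.0),
    (">6–12 h", 6.0, 12.0),
    (">12–24 h", 12.0, 24.0),
    (">24–36 h", 24.0, 36.0),
)
WINDOW_LABELS = tuple(w[0] for w in TIME_WINDOWS)


def mean_hu(img: VolumeImage, mask: SegmentationMask) -> float:
    """Arithmetic mean intensity of ``img`` over the mask voxels."""
    mask.check_aligned(img)
    if mask.count == 0:
        raise EmptySelectionError("cannot average over an empty mask")
    return float(img.data[mask.boolean()].mean())


def compute_nwu(hu_ischemic: float, hu_normal: float) -> float:
    """Net water uptake in percent; negative values are kept, not clipped."""
    if not hu_normal > 0:
        raise DomainError(f"hu_normal must be positive, got {hu_normal}")
    return (1.0 - hu_ischemic / hu_normal) * 100.0


def assign_time_window(hours: float) -> str:
    """Onset-to-CT time window label.

    Boundaries are lower-exclusive / upper-inclusive, except that 0 belongs to
    the first window; values outside [0, 36] h are outside the study design.
    """
    if not 0.0 <= hours <= 36.0:
        raise OutOfRangeError(f"onset-to-CT time must be within [0, 36] h, got {hours}")
    for label, lo, hi in TIME_WINDOWS:
        if (hours > lo or (lo == 0.0 and hours == 0.0)) and hours <= hi:
            return label
    raise OutOfRangeError(f"no time window for {hours} h")  # pragma: no cover


@dataclass
class LesionMeasurement:
    """Per-case attenuation and NWU measurement."""

    case_id: str
    hu_ischemic: float
    hu_normal: float
    nwu_pct: float
    onset_to_ct_hours: float
    time_window: str

    def __post_init__(self) -> None:
        if not self.hu_normal > 0:
            raise ValidationError(f"hu_normal must be positive, got {self.hu_normal}")
        expected = compute_nwu(self.hu_ischemic, self.hu_normal)
        if not math.isclose(self.nwu_pct, expected, abs_tol=1e-9):
            raise ValidationError(
                f"nwu_pct {self.nwu_pct} inconsistent with HU values (expected {expected})"
            )
        if self.time_window != assign_time_window(self.onset_to_ct_hours):
            raise ValidationError(
                f"time_window {self.time_window!r} inconsistent with "
                f"{self.onset_to_ct_hours} h"
            )

    @classmethod
    def from_values(cls, case_id: str, hu_ischemic: float, hu_normal: float,
                    onset_to_ct_hours: float) -> "LesionMeasurement":
        return cls(
            case_id=case_id,
            hu_ischemic=float(hu_ischemic),
            hu_normal=float(hu_normal),
            nwu_pct=compute_nwu(hu_ischemic, hu_normal),
            onset_to_ct_hours=float(onset_to_ct_hours),
            time_window=assign_time_window(onset_to_ct_hours),
        )


def measure_case(
    ct: VolumeImage,
    lesion_mask: SegmentationMask,
    contralateral_mask: SegmentationMask,
    onset_to_ct_hours: float,
    case_id: str = "case",
) -> LesionMeasurement:
    """Sample lesion and contralateral attenuation on CT and compute NWU."""
    return LesionMeasurement.from_values(
        case_id,
        mean_hu(ct, lesion_mask),
        mean_hu(ct, contralateral_mask),
        onset_to_ct_hours,
    )


@dataclass
class WindowSummary:
    """Per-time-window cohort statistics (sample SDs, n-1 denominator)."""

    time_window: str
    n: int
    hu_ischemic_mean: float
    hu_ischemic_sd: float | None
    hu_normal_mean: float
    hu_normal_sd: float | None
    nwu_mean_pct: float
    nwu_sd_pct: float | None
    p_value: float | None  # paired two-sided t-test, ischemic vs normal


@dataclass
class CohortSummary:
    windows: list[WindowSummary]
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(w) for w in self.windows])

    def to_dict(self) -> dict:
        return {"n_total": self.n_total, "windows": [vars(w) for w in self.windows]}


def _sd(values: np.ndarray) -> float | None:
    return float(np.std(values, ddof=1)) if len(values) >= 2 else None


def _paired_p(ischemic: np.ndarray, normal: np.ndarray) -> float | None:
    if len(ischemic) < 2:
        return None
    diffs = ischemic - normal
    if np.allclose(diffs, diffs[0]) and np.allclose(diffs[0], 0.0):
        return 1.0  # identical pairs: t = 0 by convention
    res = stats.ttest_rel(ischemic, normal)
    return float(res.pvalue)


def summarize_cohort(measurements: list[LesionMeasurement]) -> CohortSummary:
    """Per-window means/SDs and paired t-tests; windows with n < 2 carry no p-value.

    The summary is invariant to the ordering of the measurements, and the NWU
    column is the mean of per-case NWU values.
    """
    windows: list[WindowSummary] = []
    for label in WINDOW_LABELS:
        group = [m for m in measurements if m.time_window == label]
        if not group:
            continue
        isch = np.array([m.hu_ischemic for m in group])
        norm = np.array([m.hu_normal for m in group])
        nwu = np.array([m.nwu_pct for m in group])
        windows.append(
            WindowSummary(
                time_window=label,
                n=len(group),
                hu_ischemic_mean=float(isch.mean()),
                hu_ischemic_sd=_sd(isch),
                hu_normal_mean=float(norm.mean()),
                hu_normal_sd=_sd(norm),
                nwu_mean_pct=float(nwu.mean()),
                nwu_sd_pct=_sd(nwu),
                p_value=_paired_p(isch, norm),
            )
        )
    return CohortSummary(windows=windows, n_total=len(measurements))


# -- CSV round-trip ---------------------------------------------------------

MEASUREMENT_COLUMNS = (
    "case_id", "hu_ischemic", "hu_normal", "nwu_pct", "onset_to_ct_hours", "time_window",
)


def measurements_to_csv(measurements: list[LesionMeasurement], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([vars(m) for m in measurements])[list(MEASUREMENT_COLUMNS)].to_csv(
        path, index=False
    )
    return path


def measurements_from_csv(path: str | Path) -> list[LesionMeasurement]:
    df = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return [
        LesionMeasurement(
            case_id=str(r.case_id),
            hu_ischemic=float(r.hu_ischemic),
            hu_normal=float(r.hu_normal),
            nwu_pct=float(r.nwu_pct),
            onset_to_ct_hours=float(r.onset_to_ct_hours),
            time_window=str(r.time_window),
        )
        for r in df.itertuples()
    ]
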