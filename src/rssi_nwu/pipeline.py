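"""End-to-end pipeline: segmentation -> registration -> mirroring -> NWU
-> display optimization, with provenance sidecars and per-stage logging.
"""

from __future__ import annotations

import dataclasses
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as _io
from .enhance import FSNLBParams, WindowParams, derive_window_params, enhance_volume
from .errors import PipelineStageError, ValidationError
from .images import SegmentationMask, VolumeImage
from .phantom import load_manifest
from .quantify import (
    CohortSummary,
    LesionMeasurement,
    measure_case,
    measurements_to_csv,
    summarize_cohort,
)
from .spatial import (
    default_template,
    extract_brain,
    mirror_mask_across_midline,
    normalize_to_template,
    register_rigid,
    resample_mask,
    segment_lesion_dwi,
    shrink_mask,
)

logger = logging.getLogger("rssi_nwu.pipeline")


@dataclass
class CaseInput:
    case_id: str
    ct_path: Path
    dwi_path: Path
    onset_to_ct_hours: float


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``cohort_dir`` (a directory with a phantom-cohort ``manifest.json``)
    or an explicit ``cases`` list must be given.  CLI flags override config
    values; the file value is used where no flag is passed.
    """

    out_dir: Path
    cohort_dir: Path | None = None
    cases: list[CaseInput] = field(default_factory=list)
    brain_hu_low: float = 0.0
    brain_hu_high: float = 100.0
    dwi_foreground_threshold: float = 50.0
    lesion_k_sd: float = 3.0
    shrink_target_fraction: float = 0.9
    registration_iterations: int = 300
    enhance_modes: tuple[str, ...] = ("window", "fsnlb")
    write_enhanced: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cases = [
            CaseInput(
                case_id=str(c["case_id"]),
                ct_path=Path(c["ct"]),
                dwi_path=Path(c["dwi"]),
                onset_to_ct_hours=float(c["onset_to_ct_hours"]),
            )
            for c in raw.pop("cases", [])
        ]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ValidationError("config must set out_dir")
        raw["out_dir"] = Path(raw["out_dir"])
        if raw.get("cohort_dir"):
            raw["cohort_dir"] = Path(raw["cohort_dir"])
        if "enhance_modes" in raw:
            raw["enhance_modes"] = tuple(raw["enhance_modes"])
        return cls(cases=cases, **raw)

    def resolve_cases(self) -> list[CaseInput]:
        if self.cohort_dir is not None:
            manifest = load_manifest(Path(self.cohort_dir) / "manifest.json")
            root = Path(self.cohort_dir)
            return [
                CaseInput(
                    case_id=c["case_id"],
                    ct_path=root / c["ct"],
                    dwi_path=root / c["dwi"],
                    onset_to_ct_hours=float(c["onset_to_ct_hours"]),
                )
                for c in manifest
            ]
        return list(self.cases)

    def validate(self) -> None:
        if self.cohort_dir is None and not self.cases:
            raise ValidationError("config needs either cohort_dir or an explicit case list")
        if self.cohort_dir is not None:
            manifest = Path(self.cohort_dir) / "manifest.json"
            if not manifest.exists():
                raise ValidationError(f"cohort manifest not found: {manifest}")
        for case in self.resolve_cases():
            for p in (case.ct_path, case.dwi_path):
                if not Path(p).exists():
                    raise ValidationError(f"{case.case_id}: input path does not exist: {p}")


@dataclass
class CaseResult:
    measurement: LesionMeasurement
    lesion_mask_ct: SegmentationMask
    contralateral_mask_ct: SegmentationMask


@dataclass
class PipelineResult:
    measurements: list[LesionMeasurement]
    summary: CohortSummary
    window_params: WindowParams
    out_dir: Path
    measurements_csv: Path
    summary_json: Path


STAGES = (
    "brain_extraction",
    "lesion_segmentation",
    "lesion_shrink",
    "rigid_registration",
    "lesion_to_ct",
    "template_normalization",
    "midline_mirroring",
    "quantification",
    "enhancement",
)


def _stage(name: str, fn, *args, **kwargs):
    logger.info("stage %s", name)
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineStageError(name, str(exc)) from exc


def process_case(
    case: CaseInput,
    config: RunConfig,
    template: VolumeImage | None = None,
) -> CaseResult:
    """Run the per-case spatial workflow and measure NWU."""
    ct = _io.read_volume(case.ct_path, "CT")
    dwi = _io.read_volume(case.dwi_path, "DWI")
    template = template if template is not None else default_template()
    seed = int(config.seed) % (2**31 - 1)

    _stage("brain_extraction", extract_brain, ct, config.brain_hu_low, config.brain_hu_high)
    dwi_brain = _stage(
        "brain_extraction", extract_brain, dwi, config.dwi_foreground_threshold, float("inf")
    )
    lesion_dwi = _stage(
        "lesion_segmentation", segment_lesion_dwi, dwi, dwi_brain, config.lesion_k_sd
    )
    lesion_dwi = _stage("lesion_shrink", shrink_mask, lesion_dwi, config.shrink_target_fraction)
    dwi_to_ct = _stage(
        "rigid_registration",
        register_rigid,
        ct,
        dwi,
        max_iterations=config.registration_iterations,
        seed=seed + 13,
    )
    lesion_ct = _stage("lesion_to_ct", resample_mask, lesion_dwi, dwi_to_ct, ct)
    to_template = _stage(
        "template_normalization",
        normalize_to_template,
        ct,
        template,
        max_iterations=config.registration_iterations,
        seed=seed + 17,
    )
    contra_ct = _stage("midline_mirroring", mirror_mask_across_midline, lesion_ct, to_template)
    measurement = _stage(
        "quantification",
        measure_case,
        ct,
        lesion_ct,
        contra_ct,
        case.onset_to_ct_hours,
        case.case_id,
    )
    return CaseResult(measurement, lesion_ct, contra_ct)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full workflow over all configured cases.

    Writes a measurement CSV, a cohort-summary JSON, optimized-display
    volumes, per-stage logs and provenance sidecars under ``config.out_dir``.
    A failing stage aborts the run; partial outputs of the failing case are
    preserved under ``out_dir/quarantine/<case_id>``.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    template = default_template()
    results: list[CaseResult] = []
    try:
        for case in config.resolve_cases():
            logger.info(
                "case %s (onset %.1f h): %s", case.case_id, case.onset_to_ct_hours, case.ct_path
            )
            case_dir = out_dir / case.case_id
            try:
                result = process_case(case, config, template)
            except PipelineStageError as exc:
                quarantine = out_dir / "quarantine" / case.case_id
                quarantine.mkdir(parents=True, exist_ok=True)
                if case_dir.exists():
                    shutil.copytree(case_dir, quarantine, dirs_exist_ok=True)
                (quarantine / "failure.txt").write_text(
                    f"case {case.case_id} failed at stage {exc.stage}: {exc}\n"
                )
                logger.error("case %s failed at stage %s: %s", case.case_id, exc.stage, exc)
                raise
            case_dir.mkdir(parents=True, exist_ok=True)
            _io.write_mask(result.lesion_mask_ct, case_dir / "lesion_ct.nii.gz")
            _io.write_mask(result.contralateral_mask_ct, case_dir / "contralateral_ct.nii.gz")
            results.append(result)

        measurements = [r.measurement for r in results]
        summary = _stage("quantification", summarize_cohort, measurements)
        csv_path = measurements_to_csv(measurements, out_dir / "measurements.csv")
        _io.write_sidecar(csv_path, seed=config.seed, stage="quantification",
                          n_cases=len(measurements))
        summary_path = _io.write_json(out_dir / "cohort_summary.json", summary.to_dict())

        # display optimization from the measured infarct attenuations
        hu_values = [m.hu_ischemic for m in measurements]
        try:
            window = derive_window_params(hu_values)
        except ValidationError:
            window = WindowParams(level=30.0, width=6.0)  # fallback for n < 2 cohorts
        fsnlb_params = FSNLBParams(center=window.level, delta=window.width, slope=5.0)
        if config.write_enhanced:
            for case, result in zip(config.resolve_cases(), results):
                ct = _io.read_volume(case.ct_path, "CT")
                case_dir = out_dir / case.case_id
                if "window" in config.enhance_modes:
                    _stage("enhancement", enhance_volume, ct, "window", window,
                           case_dir / "ct_window.nii.gz", config.seed)
                if "fsnlb" in config.enhance_modes:
                    _stage("enhancement", enhance_volume, ct, "fsnlb", fsnlb_params,
                           case_dir / "ct_fsnlb.nii.gz", config.seed)
        _io.write_sidecar(out_dir / "run.log", seed=config.seed,
                          window_level=window.level, window_width=window.width,
                          fsnlb=vars(fsnlb_params), stages=list(STAGES))
        logger.info("run complete: %d case(s)", len(results))
        return PipelineResult(
            measurements=measurements,
            summary=summary,
            window_params=window,
            out_dir=out_dir,
            measurements_csv=csv_path,
            summary_json=summary_path,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()
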