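"""End-to-end orchestration: simulate a cohort, preprocess every recording,
build the ERD/S tables, and run the four mixed RM-ANOVAs (task x band).

The pipeline is streaming — one participant's recording is simulated,
cleaned and reduced to ERD/S tables before the next is generated — and every
nondeterministic choice (seeds, removed ICA components, rejected epochs) is
written to a JSON run manifest so results can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import erds, stats
from .preprocess import RejectionReport, preprocess_raw
from .simulate import SimulationConfig, iter_cohort

logger = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    flat_std_uV: float = 1e-2
    l_freq: float = 1.0
    h_freq: float = 40.0
    corr_threshold: float = 0.7
    skip_ica: bool = False
    tmin: float = -2.0
    tmax: float = 7.0
    ptp_threshold_uV: float = 120.0


@dataclass
class ErdsParams:
    ref_window: tuple[float, float] = (-1.5, 0.0)
    act_window: tuple[float, float] = (2.0, 6.0)
    rois: dict[str, list[str]] | None = None  # None -> default six ROIs


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_left: int = 14
    n_right: int = 14
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    erds: ErdsParams = field(default_factory=ErdsParams)
    alpha_level: float = 0.05
    out_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.get("simulation", {}))
        pre = PreprocessParams(**raw.get("preprocess", {}))
        erds_raw = dict(raw.get("erds", {}))
        for key in ("ref_window", "act_window"):
            if key in erds_raw:
                erds_raw[key] = tuple(erds_raw[key])
        return cls(
            simulation=sim,
            n_left=raw.get("n_left", 14),
            n_right=raw.get("n_right", 14),
            preprocess=pre,
            erds=ErdsParams(**erds_raw),
            alpha_level=raw.get("alpha_level", 0.05),
            out_dir=raw.get("out_dir"),
            seed=raw.get("seed", 0),
        )


@dataclass
class CohortSummary:
    n_participants: int
    epochs_total: int
    epochs_rejected: int

    @property
    def epochs_kept(self) -> int:
        return self.epochs_total - self.epochs_rejected

    @property
    def kept_percent(self) -> float:
        if self.epochs_total == 0:
            return 0.0
        return 100.0 * self.epochs_kept / self.epochs_total

    def display(self) -> str:
        return (
            f"{self.epochs_rejected} of {self.epochs_total} epochs rejected; "
            f"{self.epochs_kept} kept ({self.kept_percent:.2f}%)"
        )


def summarize_cohort(reports: list[RejectionReport], n_participants: int | None = None) -> CohortSummary:
    """Totals over per-run/per-participant rejection reports."""
    return CohortSummary(
        n_participants=n_participants if n_participants is not None else len(reports),
        epochs_total=sum(r.n_total for r in reports),
        epochs_rejected=sum(r.n_rejected for r in reports),
    )


@dataclass
class PipelineResult:
    channel_table: pd.DataFrame
    roi_table: pd.DataFrame
    grand_average: pd.DataFrame
    anovas: dict  # (task, band) -> AnovaResult or error string
    summary: CohortSummary
    manifest: dict


def long_design_from_roi_table(roi_table: pd.DataFrame, task: str, band: str) -> pd.DataFrame:
    """Shape the ROI-level ERD/S table into the ANOVA's long design."""
    sub = roi_table[(roi_table["task"] == task) & (roi_table["band"] == band)]
    return pd.DataFrame(
        {
            "participant": sub["participant"].to_numpy(),
            "handedness": sub["group"].to_numpy(),
            "sex": sub["sex"].to_numpy(),
            "roi": sub["level"].to_numpy(),
            "condition": sub["condition"].to_numpy(),
            "erds_percent": sub["erds_percent"].to_numpy(),
        }
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute simulate -> preprocess -> ERD/S -> stats for a whole cohort."""
    pre = config.preprocess
    rois = config.erds.rois
    reports: list[RejectionReport] = []
    participant_logs = {}
    tables = []
    stage = "simulate"
    try:
        for row, rec in iter_cohort(
            config.simulation, config.n_left, config.n_right, config.seed
        ):
            pid = row["participant_id"]
            stage = f"preprocess[{pid}]"
            epochs, report, info = preprocess_raw(
                rec,
                flat_std_uV=pre.flat_std_uV, l_freq=pre.l_freq, h_freq=pre.h_freq,
                corr_threshold=pre.corr_threshold, skip_ica=pre.skip_ica,
                tmin=pre.tmin, tmax=pre.tmax, ptp_threshold_uV=pre.ptp_threshold_uV,
            )
            reports.append(report)
            participant_logs[pid] = {"seed": int(row["seed"]), **info}
            stage = f"erds[{pid}]"
            tables.append(
                erds.erds_table_for_participant(
                    epochs, pid, row["group"], row["sex"],
                    ref_window=config.erds.ref_window, act_window=config.erds.act_window,
                )
            )
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    channel_table = pd.concat(tables, ignore_index=True)
    roi_table = erds.roi_means(channel_table, rois)
    grand = erds.grand_average(roi_table)
    summary = summarize_cohort(reports, n_participants=len(participant_logs))

    anovas: dict = {}
    for task in ("ME", "MI"):
        for band in ("alpha", "beta"):
            if not ((roi_table["task"] == task) & (roi_table["band"] == band)).any():
                continue
            design = long_design_from_roi_table(roi_table, task, band)
            try:
                anovas[(task, band)] = stats.mixed_rm_anova(design)
            except stats.DesignError as err:
                logger.warning("stats stage for (%s, %s): %s", task, band, err)
                anovas[(task, band)] = f"design error: {err}"

    manifest = {
        "config": _config_dict(config),
        "participants": participant_logs,
        "summary": {
            "n_participants": summary.n_participants,
            "epochs_total": summary.epochs_total,
            "epochs_rejected": summary.epochs_rejected,
            "epochs_kept": summary.epochs_kept,
            "kept_percent": round(summary.kept_percent, 2),
        },
    }
    result = PipelineResult(channel_table, roi_table, grand, anovas, summary, manifest)
    if config.out_dir:
        _write_outputs(result, Path(config.out_dir))
    return result


def _config_dict(config: PipelineConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        return obj

    return clean(config)


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.channel_table.to_csv(outdir / "erds_channels.csv", index=False)
    result.roi_table.to_csv(outdir / "erds_rois.csv", index=False)
    result.grand_average.to_csv(outdir / "erds_grand_average.csv", index=False)
    for (task, band), res in result.anovas.items():
        stem = f"anova_{task}_{band}".lower()
        if isinstance(res, str):
            (outdir / f"{stem}_error.txt").write_text(res + "\n")
            continue
        res.effects.to_csv(outdir / f"{stem}_effects.csv", index=False)
        stats.emmeans(res, "ROI").to_csv(outdir / f"{stem}_emmeans_roi.csv", index=False)
        stats.posthoc_for_effect(res, "ROI").to_csv(
            outdir / f"{stem}_posthoc_roi.csv", index=False
        )
    (outdir / "run_manifest.json").write_text(json.dumps(result.manifest, indent=1))
    (outdir / "cohort_summary.txt").write_text(result.summary.display() + "\n")
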