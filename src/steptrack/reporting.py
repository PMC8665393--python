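"""End-to-end pipeline orchestration and chart rendering."""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import adherence, analysis, msas, volatility
from .cohort import Cohort, read_cohort
from .util import Absent

log = logging.getLogger("steptrack")


class PipelineError(RuntimeError):
    """An orchestration stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    input_dir: Path
    out_dir: Path
    make_charts: bool = True
    age_threshold: float = 60.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            input_dir=Path(raw["input_dir"]),
            out_dir=Path(raw["out_dir"]),
            make_charts=bool(raw.get("make_charts", True)),
            age_threshold=float(raw.get("age_threshold", 60.0)),
            log_level=str(raw.get("log_level", "INFO")),
        )


def to_jsonable(obj):
    """Recursively convert results (dataclasses, Absent, numpy scalars,
    tuple-keyed dicts) into plain JSON-serializable structures."""
    if isinstance(obj, Absent):
        return {"absent": True, "reason": obj.reason}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {_key(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if hasattr(obj, "item") and not isinstance(obj, (str, bytes)):
        try:
            return obj.item()
        except (AttributeError, ValueError):
            pass
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    if isinstance(obj, adherence.DayClass):
        return obj.value
    return str(obj)


def _key(k) -> str:
    if isinstance(k, tuple):
        return ":".join(str(p) for p in k)
    return str(k)


def run_pipeline(config: RunConfig) -> dict:
    """read -> filter -> completeness -> scoring -> volatility -> analyses.

    Writes results.json, CSV tables, and (optionally) charts into
    ``config.out_dir``; returns the results dictionary.  Any stage
    failure removes files written so far and raises PipelineError.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run_stages(config, out_dir, written)
    except PipelineError:
        _cleanup(written)
        raise
    except Exception as exc:  # pragma: no cover - defensive
        _cleanup(written)
        raise PipelineError("unknown", exc)


def _cleanup(written: list[Path]) -> None:
    for path in written:
        try:
            path.unlink(missing_ok=True)
        except OSError:
            pass


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrapper

    return deco


@_stage("read")
def _read(config: RunConfig) -> Cohort:
    cohort = read_cohort(config.input_dir)
    if not cohort.patients:
        raise ValueError("empty cohort: no patients in input")
    log.info("[read] %d patients, %d step series", len(cohort.patients), len(cohort.steps))
    return cohort


def _run_stages(config: RunConfig, out_dir: Path, written: list[Path]) -> dict:
    cohort = _read(config)
    results: dict = {"n_enrolled": len(cohort.patients)}

    results["completeness"] = _completeness(cohort)
    included, exclusions = _filter(cohort)
    results["inclusion"] = {
        "n_included": len(included.patients),
        "n_excluded": len(exclusions),
        "pct_included": None
        if not cohort.patients
        else round(100.0 * len(included.patients) / len(cohort.patients), 1),
        "exclusions": to_jsonable(exclusions),
    }
    results["msas"] = _msas(included)
    vol_results, vol_series = _volatility(included)
    results["volatility"] = vol_results
    results["analysis"] = _analyses(included, config)

    _write_tables(included, out_dir, written)
    results_path = out_dir / "results.json"
    results_path.write_text(
        json.dumps(to_jsonable(results), indent=2, sort_keys=True) + "\n"
    )
    written.append(results_path)

    if config.make_charts:
        _charts(included, vol_series, out_dir, written)
    return results


@_stage("completeness")
def _completeness(cohort: Cohort) -> dict:
    out = {}
    for phase in ("pre", "post"):
        report = adherence.completeness_report(cohort, phase)
        log.info(
            "[completeness] %s: full=%d partial=%d none=%d",
            phase, report.n_full, report.n_partial, report.n_none,
        )
        out[phase] = report.to_dict()
    return out


@_stage("filter")
def _filter(cohort: Cohort):
    included, exclusions = adherence.filter_cohort(cohort)
    log.info("[filter] %d included / %d excluded", len(included.patients), len(exclusions))
    return included, exclusions


@_stage("msas")
def _msas(cohort: Cohort) -> dict:
    improvements: dict[str, dict] = {}
    n_scored = 0
    counts = {name: {"improved": 0, "total": 0} for name in msas.SUBSCALES}
    for pid in cohort.patient_ids:
        if pid not in cohort.msas_pre or pid not in cohort.msas_post:
            continue
        n_scored += 1
        change = msas.msas_improvement(
            msas.score_msas(cohort.msas_pre[pid]), msas.score_msas(cohort.msas_post[pid])
        )
        improvements[pid] = to_jsonable(change)
        for name, res in change.items():
            if not isinstance(res, Absent):
                counts[name]["total"] += 1
                counts[name]["improved"] += int(res.improved)
    pct = {
        name: (None if c["total"] == 0 else round(100.0 * c["improved"] / c["total"], 1))
        for name, c in counts.items()
    }
    log.info("[msas] scored both visits for %d patients", n_scored)
    return {"n_scored": n_scored, "improvement_counts": counts, "pct_improved": pct,
            "per_patient": improvements}


@_stage("volatility")
def _volatility(cohort: Cohort):
    series_out = []
    for s in cohort.steps:
        for phase in ("pre", "post"):
            series_out.append(volatility.daily_volatility(s, phase))
    directions = {
        phase: to_jsonable(volatility.direction_day_counts(cohort, phase))
        for phase in ("pre", "post")
    }
    summary = volatility.annualized_change_summary(cohort)
    log.info(
        "[volatility] annualized variance increased for %d of %d patients",
        summary.n_increased, len(summary.per_patient),
    )
    results = {
        "direction_day_counts": directions,
        "annualized_change": to_jsonable(summary),
        "n_increased": summary.n_increased,
        "n_decreased_or_flat": summary.n_decreased_or_flat,
    }
    return results, series_out


@_stage("analysis")
def _analyses(cohort: Cohort, config: RunConfig) -> dict:
    out: dict = {}
    try:
        matrix = analysis.prepost_summary_correlation(cohort)
        out["prepost_correlation"] = to_jsonable(matrix)
    except analysis.InsufficientDataError as exc:
        out["prepost_correlation"] = {"absent": True, "reason": str(exc)}
    out["daywise_correlation"] = {
        phase: {
            stat: to_jsonable(analysis.daywise_correlation(cohort, phase, stat))
            for stat in analysis.SUMMARY_STATS
        }
        for phase in ("pre", "post")
    }
    out["steps_vs_ecog"] = {
        phase: to_jsonable(analysis.steps_vs_ecog(cohort, phase))
        for phase in ("pre", "post")
    }
    out["improvement_split"] = {
        subscale: to_jsonable(analysis.improvement_step_comparison(cohort, subscale))
        for subscale in msas.SUBSCALES
    }
    out["age_split"] = {
        phase: to_jsonable(
            analysis.age_split_comparison(cohort, phase, config.age_threshold)
        )
        for phase in ("pre", "post")
    }
    log.info("[analysis] done")
    return out


@_stage("tables")
def _write_tables(cohort: Cohort, out_dir: Path, written: list[Path]) -> None:
    # per-day correlation profile (one row per phase day x statistic)
    rows = []
    for phase in ("pre", "post"):
        for stat in analysis.SUMMARY_STATS:
            for day, res in analysis.daywise_correlation(cohort, phase, stat).items():
                if isinstance(res, Absent):
                    rows.append(
                        {"phase": phase, "study_day": day, "statistic": stat,
                         "estimate": None, "p_value": None, "n": None, "note": res.reason}
                    )
                else:
                    rows.append(
                        {"phase": phase, "study_day": day, "statistic": stat,
                         "estimate": round(res.estimate, 3), "p_value": res.p_value,
                         "n": res.n, "note": ""}
                    )
    path = out_dir / "daywise_correlation.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    written.append(path)

    try:
        matrix = analysis.prepost_summary_correlation(cohort)
    except analysis.InsufficientDataError:
        return
    table = pd.DataFrame(
        [
            [round(matrix[(i, j)].estimate, 3) for j in analysis.SUMMARY_STATS]
            for i in analysis.SUMMARY_STATS
        ],
        index=[f"post_{s}" for s in analysis.SUMMARY_STATS],
        columns=[f"pre_{s}" for s in analysis.SUMMARY_STATS],
    )
    path = out_dir / "prepost_correlation.csv"
    table.to_csv(path)
    written.append(path)


def render_volatility_chart(series_list, path) -> Path:
    """Per-patient daily sigma(t) bar panels across the study timeline."""
    by_patient: dict[str, list] = {}
    for vs in series_list:
        by_patient.setdefault(vs.patient_id, []).append(vs)
    by_patient = {
        pid: group for pid, group in by_patient.items()
        if any(vs.values for vs in group)
    }
    if not by_patient:
        raise ValueError("nothing to plot: no volatility values")
    n = len(by_patient)
    ncols = min(4, n)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.2 * nrows), squeeze=False, sharex=True
    )
    for ax in axes.flat:
        ax.set_visible(False)
    for idx, (pid, group) in enumerate(by_patient.items()):
        ax = axes[idx // ncols][idx % ncols]
        ax.set_visible(True)
        days, sigmas = [], []
        for vs in group:
            for d, s in sorted(vs.values.items()):
                days.append(d)
                sigmas.append(s)
        ax.bar(days, sigmas, color=["tab:green" if s >= 0 else "tab:red" for s in sigmas])
        ax.axvline(0, color="grey", linewidth=0.8, linestyle="--")
        ax.axhline(0, color="black", linewidth=0.6)
        ax.set_title(pid, fontsize=8)
    fig.suptitle("Daily step-count volatility (relative day-over-day change)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def render_annualized_chart(change_summary, path) -> Path:
    """Paired pre/post annualized-variance marks, one pair per patient."""
    if not change_summary.per_patient:
        raise ValueError("nothing to plot: no paired annualized values")
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for i, (pid, change) in enumerate(change_summary.per_patient.items()):
        color = "tab:red" if change.increased else (
            "tab:blue" if change.post_var < change.pre_var else "tab:grey"
        )
        ax.plot([i, i], [change.pre_var, change.post_var], color=color, linewidth=1)
        ax.plot(i, change.pre_var, "o", color="black", markersize=3)
        ax.plot(i, change.post_var, "s", color=color, markersize=4)
    ax.set_xticks(range(len(change_summary.per_patient)))
    ax.set_xticklabels(list(change_summary.per_patient), rotation=90, fontsize=6)
    ax.set_ylabel("annualized variance")
    ax.set_title("Annualized step-count variance, baseline (o) vs follow-up (s)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


@_stage("charts")
def _charts(cohort: Cohort, vol_series, out_dir: Path, written: list[Path]) -> None:
    summary = volatility.annualized_change_summary(cohort)
    if any(vs.values for vs in vol_series):
        written.append(render_volatility_chart(vol_series, out_dir / "volatility.png"))
    if summary.per_patient:
        written.append(render_annualized_chart(summary, out_dir / "annualized.png"))
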