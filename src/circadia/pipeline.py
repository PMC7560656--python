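"""End-to-end orchestration: ingest → filter → profiles → bootstraps → phase
test → content analysis, with tabular/figure outputs and a reproducibility
manifest.

Everything here is a thin composition of the library modules; no statistic is
computed in this file that is not available from those modules directly.  The
cubic-spline smoother exists for plotting only — the day wraps, so the spline
is periodic — and no inference is drawn from smoothed curves.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from . import __version__ as _pkg_version
from .circadian import (
    BootstrapSummary,
    DifferenceSummary,
    PhaseShiftResult,
    bootstrap_difference,
    bootstrap_profile,
    cohort_activity_profile,
    cohort_hourly_counts,
    cross_correlation_phase,
    relative_difference,
)
from .content import (
    PrevalenceResult,
    TokenCategory,
    consistent_tokens,
    hourly_prevalence_series,
    load_lexicon,
    top_tokens_per_hour,
)
from .exceptions import ConfigurationError
from .ingest import FilterReport, filter_events, localize_hours, read_events, read_profiles
from .synth import SyntheticConfig, generate_dataset

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "spline_smooth"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Either ``synthetic`` or both ``events_path`` and ``profiles_path`` must be
    given.  Defaults follow the study conventions: 10,000 bootstrap
    replicates, significance at α = 0.05, per-hour top-250 token lists.
    """

    out_dir: str = "circadia_run"
    synthetic: Optional[SyntheticConfig] = None
    events_path: Optional[str] = None
    profiles_path: Optional[str] = None
    lexicon_path: Optional[str] = None
    n_replicates: int = 10_000
    alpha: float = 0.05
    top_k: int = 250
    seed: int = 0
    run_content: bool = True
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")
        if self.synthetic is None and not (self.events_path and self.profiles_path):
            raise ConfigurationError(
                "either synthetic config or events_path+profiles_path is required"
            )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        if isinstance(raw.get("synthetic"), dict):
            raw["synthetic"] = SyntheticConfig.from_dict(raw["synthetic"])
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory results of a run; files live under ``out_dir``."""

    out_dir: Path
    filter_report: FilterReport
    profile_d: np.ndarray
    profile_rs: np.ndarray
    boot_d: BootstrapSummary
    boot_rs: BootstrapSummary
    difference: DifferenceSummary
    ratio: np.ndarray
    phase: PhaseShiftResult
    prevalence: List[PrevalenceResult] = field(default_factory=list)
    consistent: Optional[set] = None


def spline_smooth(values, n_points: int = 241) -> Tuple[np.ndarray, np.ndarray]:
    """Periodic cubic-spline interpolation of a 24-point hourly series.

    The interpolant passes through every input point exactly and wraps around
    midnight; it is used for plotting only.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (24,) or not np.all(np.isfinite(values)):
        raise ValueError("spline_smooth requires 24 finite values")
    x = np.arange(25.0)
    spline = CubicSpline(x, np.append(values, values[0]), bc_type="periodic")
    xs = np.linspace(0.0, 24.0, n_points)
    return xs, spline(xs)


def _load_inputs(cfg: RunConfig) -> Tuple[pd.DataFrame, pd.DataFrame, int]:
    if cfg.synthetic is not None:
        events, profiles = generate_dataset(cfg.synthetic)
        return events, profiles, 0
    events, malformed_e = read_events(cfg.events_path)
    profiles, malformed_p = read_profiles(cfg.profiles_path)
    return events, profiles, malformed_e + malformed_p


def _summary_frame(boot: BootstrapSummary, point: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "hour": np.arange(24),
            "activity_pct": point,
            "median": boot.median,
            "lo95": boot.lower95,
            "hi95": boot.upper95,
        }
    )


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _content_analysis(
    cfg: RunConfig,
    tweets_d: pd.DataFrame,
    tweets_rs: pd.DataFrame,
    lexicon: Dict[str, List[str]],
) -> Tuple[List[PrevalenceResult], set]:
    top_d = top_tokens_per_hour(tweets_d, cfg.top_k)
    top_rs = top_tokens_per_hour(tweets_rs, cfg.top_k)
    consistent = consistent_tokens(top_d, top_rs)
    results: List[PrevalenceResult] = []
    for name, tokens in lexicon.items():
        kept = sorted(set(tokens) & consistent)
        dropped = sorted(set(tokens) - consistent)
        if dropped:
            logger.warning(
                "category %s: %d token(s) not hour-consistent, dropped: %s",
                name, len(dropped), dropped,
            )
        if not kept:
            logger.warning("category %s has no hour-consistent tokens; skipped", name)
            continue
        category = TokenCategory(name, frozenset(kept))
        results.append(hourly_prevalence_series(category, tweets_d, tweets_rs))
    return results, consistent


def _plot_all(result: PipelineResult, fig_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir.mkdir(parents=True, exist_ok=True)
    hours = np.arange(24)
    sig_hours = np.flatnonzero(result.difference.significant)

    def shade(ax):
        for h in sig_hours:
            ax.axvspan(h - 0.5, h + 0.5, color="0.85", zorder=0)

    fig, ax = plt.subplots(figsize=(9, 4.5))
    shade(ax)
    for boot, point, label, color in [
        (result.boot_d, result.profile_d, "Depressed", "tab:red"),
        (result.boot_rs, result.profile_rs, "Random", "tab:blue"),
    ]:
        ax.errorbar(
            hours, boot.median,
            yerr=[boot.median - boot.lower95, boot.upper95 - boot.median],
            fmt="o", ms=4, color=color, label=label, zorder=3,
        )
        xs, ys = spline_smooth(boot.median)
        ax.plot(xs, ys, color=color, lw=1, zorder=2)
    ax.axhline(100 / 24, ls="--", color="k", lw=0.8, label="uniform (100/24%)")
    ax.set_xlabel("local hour of day")
    ax.set_ylabel("hourly activity (% of daily tweets)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(fig_dir / "activity.png", dpi=150)
    plt.close(fig)

    fig, axes = plt.subplots(2, 1, figsize=(9, 7), sharex=True)
    shade(axes[0])
    axes[0].plot(hours, result.ratio, "ko", ms=4)
    xs, ys = spline_smooth(result.ratio)
    axes[0].plot(xs, ys, "k-", lw=1)
    axes[0].axhline(1.0, ls="--", color="k", lw=0.8)
    axes[0].set_ylabel("activity ratio D / RS")
    shade(axes[1])
    diff = result.difference
    axes[1].errorbar(
        hours, diff.median,
        yerr=[diff.median - diff.lower95, diff.upper95 - diff.median],
        fmt="D", ms=4, color="k",
    )
    axes[1].axhline(0.0, ls="--", color="k", lw=0.8)
    axes[1].set_xlabel("local hour of day")
    axes[1].set_ylabel("activity difference D − RS (pp)")
    fig.tight_layout()
    fig.savefig(fig_dir / "difference.png", dpi=150)
    plt.close(fig)

    if result.prevalence:
        fig, ax = plt.subplots(figsize=(9, 4.5))
        shade(ax)
        for res in result.prevalence:
            ax.plot(hours, res.z_hourly, "o", ms=3, label=res.category)
            xs, ys = spline_smooth(res.z_hourly)
            ax.plot(xs, ys, lw=1)
        ax.axhline(0.0, ls="--", color="k", lw=0.8)
        ax.set_xlabel("local hour of day")
        ax.set_ylabel("z-scored hourly prevalence ratio")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(fig_dir / "content_z.png", dpi=150)
        plt.close(fig)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full two-cohort circadian analysis and write its outputs.

    Writes per-cohort bootstrapped activity tables, the bootstrapped
    difference table with significance flags, the hourly activity ratio, the
    phase-shift test, category prevalence tables with z-scored hourly series,
    figures, and a manifest sufficient to reproduce the run (seed, config,
    versions, filter report).  Reruns with the same config and seed produce
    byte-identical tables.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    events, profiles, malformed = _load_inputs(cfg)
    events, report = filter_events(events, profiles, malformed=malformed)

    cohorts = profiles.set_index("user_id")["cohort"]
    event_cohort = events["user_id"].map(cohorts)
    events_d = events.loc[event_cohort == "D"].reset_index(drop=True)
    events_rs = events.loc[event_cohort == "RS"].reset_index(drop=True)

    _, counts_d = cohort_hourly_counts(events_d, profiles)
    _, counts_rs = cohort_hourly_counts(events_rs, profiles)
    profile_d = cohort_activity_profile(counts_d)
    profile_rs = cohort_activity_profile(counts_rs)

    boot_d = bootstrap_profile(counts_d, cfg.n_replicates, seed=cfg.seed + 1, alpha=cfg.alpha)
    boot_rs = bootstrap_profile(counts_rs, cfg.n_replicates, seed=cfg.seed + 2, alpha=cfg.alpha)
    diff = bootstrap_difference(
        counts_d, counts_rs, cfg.n_replicates, seed=cfg.seed + 3, alpha=cfg.alpha
    )
    ratio = relative_difference(profile_d, profile_rs)
    phase = cross_correlation_phase(profile_d, profile_rs)

    result = PipelineResult(
        out_dir=out_dir,
        filter_report=report,
        profile_d=profile_d,
        profile_rs=profile_rs,
        boot_d=boot_d,
        boot_rs=boot_rs,
        difference=diff,
        ratio=ratio,
        phase=phase,
    )

    if cfg.run_content:
        lexicon: Optional[Dict[str, List[str]]] = None
        if cfg.lexicon_path:
            lexicon = {c.name: sorted(c.tokens) for c in load_lexicon(cfg.lexicon_path)}
        elif cfg.synthetic is not None and cfg.synthetic.token_model is not None:
            lexicon = cfg.synthetic.token_model.lexicon()
        if lexicon:
            tweets_d = events_d.assign(hour=localize_hours(events_d, profiles))
            tweets_rs = events_rs.assign(hour=localize_hours(events_rs, profiles))
            result.prevalence, result.consistent = _content_analysis(
                cfg, tweets_d, tweets_rs, lexicon
            )

    # --- tabular outputs -------------------------------------------------
    _write_tsv(_summary_frame(boot_d, profile_d), out_dir / "activity_D.tsv")
    _write_tsv(_summary_frame(boot_rs, profile_rs), out_dir / "activity_RS.tsv")
    _write_tsv(
        pd.DataFrame(
            {
                "hour": np.arange(24),
                "median": diff.median,
                "lo95": diff.lower95,
                "hi95": diff.upper95,
                "significant": diff.significant,
            }
        ),
        out_dir / "difference.tsv",
    )
    _write_tsv(
        pd.DataFrame({"hour": np.arange(24), "ratio_D_over_RS": ratio}),
        out_dir / "relative_difference.tsv",
    )
    with open(out_dir / "phase_shift.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "lags_h": phase.lags.tolist(),
                "correlation": phase.correlation.tolist(),
                "best_lag_h": phase.best_lag,
                "best_r": phase.best_r,
            },
            fh,
            indent=2,
        )
    with open(out_dir / "filter_report.json", "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2)

    if result.prevalence:
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "category": r.category,
                        "f_D": r.f_d,
                        "f_RS": r.f_rs,
                        "prevalence_ratio": r.pr,
                        "hourly_mean_pr": r.hourly_mean,
                    }
                    for r in result.prevalence
                ]
            ),
            out_dir / "content_prevalence.tsv",
        )
        z_frame = pd.DataFrame({"hour": np.arange(24)})
        for r in result.prevalence:
            z_frame[r.category] = r.z_hourly
        _write_tsv(z_frame, out_dir / "z_hourly.tsv")

    if cfg.make_plots:
        _plot_all(result, out_dir / "figures")

    manifest = {
        "seed": cfg.seed,
        "n_replicates": cfg.n_replicates,
        "alpha": cfg.alpha,
        "top_k": cfg.top_k,
        "synthetic": cfg.synthetic is not None,
        "generated_at": datetime.now(timezone.utc).isoformat(),
        "versions": {
            "circadia": _pkg_version,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "filter_report": report.to_dict(),
        "n_users": {"D": int(counts_d.shape[0]), "RS": int(counts_rs.shape[0])},
        "n_events": {"D": int(counts_d.sum()), "RS": int(counts_rs.sum())},
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)

    return result
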