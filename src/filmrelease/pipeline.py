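"""End-to-end panel analysis: burst fit, diffusion coefficients, long-time model.

For every film in a panel the pipeline

1. normalises the cumulative release curve to fractions,
2. fits the Higuchi constant on the burst window (default first 30 min),
3. converts it to a diffusion coefficient via k_H = 2 sqrt(sigma)/d,
4. fits the truncated erfc-series model (default N = 2) over the full
   time range and reports its correlation with the observations, and
5. summarises how the diffusion coefficients track release efficiency
   across films with a Spearman rank correlation (the across-panel
   ordering claim, which is about ranks rather than linearity).

Degenerate inputs (all-zero curves) are flagged in the results table, not
raised, so a batch run over a mixed panel completes with exit code 0.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import io as frio
from .kinetics import (
    DEFAULT_BURST_WINDOW,
    FilmRecord,
    HiguchiResult,
    InsufficientDataError,
    ReleaseCurve,
    diffusion_from_higuchi,
    fit_higuchi,
    fit_series,
    release_efficiency,
)

__all__ = ["RunConfig", "PanelReport", "analyze_curve", "run_panel_analysis"]

logger = logging.getLogger("filmrelease")

RESULT_COLUMNS = [
    "sample_id",
    "k_h_per_sqrt_min",
    "window_lo",
    "window_hi",
    "corr",
    "D_mm2_per_s",
    "sigma_mm2_per_min",
    "sigma_series_mm2_per_min",
    "series_corr",
    "release_efficiency_pct",
    "degenerate",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a panel run; every field has a usable default."""

    curves_dir: str | None = None
    panel_path: str | None = None
    window: tuple[float, float] = DEFAULT_BURST_WINDOW
    truncation_n: int = 2
    normalization: str = "last_value"  # or "loaded_mass"
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.window[0] < self.window[1]:
            raise ValueError("window lo must be < hi")
        if self.truncation_n < 0:
            raise ValueError("truncation_n must be >= 0")
        if self.normalization not in ("last_value", "loaded_mass"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a flat key-value YAML config; absent keys keep defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        if "window" in raw:
            raw["window"] = tuple(float(x) for x in raw["window"])
        return cls(**raw)


@dataclass
class PanelReport:
    """Results table plus across-panel summary of a run."""

    results: pd.DataFrame
    rank_corr_D_vs_efficiency: float
    n_films: int
    n_degenerate: int
    n_skipped: int


def analyze_curve(
    curve: ReleaseCurve,
    thickness_mm: float,
    window: tuple[float, float] = DEFAULT_BURST_WINDOW,
    truncation_n: int = 2,
) -> dict:
    """Burst fit + diffusion conversion + long-time series fit for one film."""
    hig = fit_higuchi(curve, window=window)
    est = diffusion_from_higuchi(hig.k_h, thickness_mm)
    row = {
        "sample_id": curve.sample_id,
        "k_h_per_sqrt_min": hig.k_h,
        "window_lo": hig.window[0],
        "window_hi": hig.window[1],
        "corr": hig.corr,
        "D_mm2_per_s": est.sigma_mm2_per_s,
        "sigma_mm2_per_min": est.sigma_mm2_per_min,
        "sigma_series_mm2_per_min": math.nan,
        "series_corr": math.nan,
        "degenerate": hig.degenerate,
    }
    if not hig.degenerate:
        sfit = fit_series(
            curve,
            thickness_d=thickness_mm,
            truncation_n=truncation_n,
            sigma_init=est.sigma_mm2_per_min if est.sigma_mm2_per_min > 0 else None,
        )
        if sfit.model is not None:
            row["sigma_series_mm2_per_min"] = sfit.model.sigma
            row["series_corr"] = sfit.corr
        row["degenerate"] = row["degenerate"] or sfit.degenerate
    return row


def run_panel_analysis(
    config: RunConfig,
    curves: list[ReleaseCurve] | None = None,
    panel: list[FilmRecord] | None = None,
) -> PanelReport:
    """Run the full panel workflow.

    Inputs may be passed in memory (``curves``/``panel``) or read from
    ``config.curves_dir`` (one ``<sample_id>.csv`` per film) and
    ``config.panel_path``.  Films without a thickness are skipped with a
    logged warning; an empty panel is an error.  When ``config.out_dir``
    is set the results table is written as ``results.csv``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if panel is None:
        if config.panel_path is None:
            raise ValueError("need a panel (in memory or panel_path)")
        panel = frio.read_film_panel(config.panel_path)
    by_id = {rec.sample_id: rec for rec in panel}

    if curves is None:
        if config.curves_dir is None:
            raise ValueError("need curves (in memory or curves_dir)")
        curves = []
        for rec in panel:
            path = Path(config.curves_dir) / f"{rec.sample_id}.csv"
            if not path.exists():
                logger.warning("no curve file for %s; skipping", rec.sample_id)
                continue
            m_inf = (
                rec.loaded_mt
                if config.normalization == "loaded_mass" and not math.isnan(rec.loaded_mt)
                else None
            )
            curves.append(frio.read_release_curve(path, m_inf=m_inf))
    if not curves:
        raise ValueError("empty panel: no curves to analyse")

    rows, n_skipped = [], 0
    for curve in curves:
        rec = by_id.get(curve.sample_id)
        if rec is None:
            logger.warning("no thickness for %s; skipping", curve.sample_id)
            n_skipped += 1
            continue
        try:
            row = analyze_curve(
                curve, rec.thickness_d, window=config.window,
                truncation_n=config.truncation_n,
            )
        except InsufficientDataError as exc:
            logger.warning("%s: %s; skipping", curve.sample_id, exc)
            n_skipped += 1
            continue
        if not math.isnan(rec.loaded_mt) and not math.isnan(rec.released_max):
            row["release_efficiency_pct"] = release_efficiency(
                rec.released_max, rec.loaded_mt
            )
        else:
            row["release_efficiency_pct"] = math.nan
        rows.append(row)
    if not rows:
        raise ValueError("no film could be analysed")

    results = pd.DataFrame(rows)[RESULT_COLUMNS]
    ok = results["release_efficiency_pct"].notna() & ~results["degenerate"]
    if ok.sum() >= 3:
        rho = float(
            stats.spearmanr(
                results.loc[ok, "D_mm2_per_s"],
                results.loc[ok, "release_efficiency_pct"],
            ).statistic
        )
    else:
        rho = math.nan

    report = PanelReport(
        results=results,
        rank_corr_D_vs_efficiency=rho,
        n_films=len(results),
        n_degenerate=int(results["degenerate"].sum()),
        n_skipped=n_skipped,
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frio.write_results(results, out / "results.csv")
    return report
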