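"""Delimited-text I/O for release curves, film panels and results tables.

File dialects
-------------
Release curve: CSV with header ``time_min,released`` (cumulative amount in
mg/mL) and/or ``fraction``.  Per-curve metadata (sample_id, thickness_mm,
loaded_mg, m_inf) may live in a YAML sidecar ``<stem>.meta.yaml`` next to
the curve file; explicit keyword arguments override the sidecar.

Film panel: CSV with header
``sample_id,thickness_mm,loaded_mg,released_max,swelling_pct,yield_pct``.

Results: CSV with header ``sample_id,k_h_per_sqrt_min,window_lo,window_hi,
corr,D_mm2_per_s,sigma_mm2_per_min`` (plus any extra columns the pipeline
adds).  Floats are written with 17 significant digits so a write/read round
trip is lossless and repeated runs are byte-identical.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import FilmRecord, ReleaseCurve

__all__ = [
    "ParseError",
    "read_release_curve",
    "write_release_curve",
    "read_film_panel",
    "write_results",
    "load_film_panel",
    "load_higuchi_table",
    "FLOAT_FORMAT",
]

logger = logging.getLogger("filmrelease")

FLOAT_FORMAT = "%.17g"

CURVE_TIME_COL = "time_min"
CURVE_AMOUNT_COL = "released"
CURVE_FRACTION_COL = "fraction"
PANEL_COLUMNS = [
    "sample_id",
    "thickness_mm",
    "loaded_mg",
    "released_max",
    "swelling_pct",
    "yield_pct",
]


class ParseError(ValueError):
    """Malformed input file; carries the offending path and line number."""

    def __init__(self, path, lineno: int | None, message: str):
        loc = f"{path}" + (f", line {lineno}" if lineno is not None else "")
        super().__init__(f"{loc}: {message}")
        self.path = path
        self.lineno = lineno


def _read_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix("").with_suffix(".meta.yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
        if not isinstance(meta, dict):
            raise ParseError(sidecar, None, "sidecar must be a flat mapping")
        return meta
    return {}


def read_release_curve(
    path,
    sample_id: str | None = None,
    m_inf: float | None = None,
) -> ReleaseCurve:
    """Read one release curve from a delimited text file.

    A ``fraction`` column takes precedence over ``released``; with only
    ``released``, ``m_inf`` (argument, sidecar, or — with a logged notice —
    the last observed value) normalises amounts.  Unsorted rows are sorted
    with a warning; negative values and malformed rows raise
    :class:`ParseError` naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _read_sidecar(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(path, None, f"unreadable CSV: {exc}") from exc
    if CURVE_TIME_COL not in df.columns:
        raise ParseError(path, 1, f"missing required column {CURVE_TIME_COL!r}")
    use_fraction = CURVE_FRACTION_COL in df.columns
    value_col = CURVE_FRACTION_COL if use_fraction else CURVE_AMOUNT_COL
    if value_col not in df.columns:
        raise ParseError(
            path, 1, f"need a {CURVE_AMOUNT_COL!r} or {CURVE_FRACTION_COL!r} column"
        )
    # +2: header line plus 1-based indexing
    for idx, row in df.iterrows():
        lineno = int(idx) + 2
        t, v = row[CURVE_TIME_COL], row[value_col]
        if pd.isna(t) or pd.isna(v):
            raise ParseError(path, lineno, "missing value")
        if t < 0:
            raise ParseError(path, lineno, f"negative time {t}")
        if v < 0:
            raise ParseError(path, lineno, f"negative released value {v}")
    if not df[CURVE_TIME_COL].is_monotonic_increasing:
        logger.warning("%s: times not sorted; sorting", path)
        df = df.sort_values(CURVE_TIME_COL, kind="stable").reset_index(drop=True)

    sample_id = sample_id or meta.get("sample_id") or path.stem
    if m_inf is None:
        m_inf = meta.get("m_inf")
    if use_fraction:
        return ReleaseCurve(
            sample_id=sample_id,
            times=df[CURVE_TIME_COL].to_numpy(float),
            values=df[value_col].to_numpy(float),
            value_kind="fraction",
            m_inf=m_inf,
        )
    if m_inf is None:
        last = float(df[value_col].iloc[-1])
        if last <= 0:
            # all-zero amounts: any positive reference keeps fractions at 0
            last = 1.0
        logger.info(
            "%s: no m_inf given; defaulting to last observed value %g", path, last
        )
        m_inf = last
    return ReleaseCurve(
        sample_id=sample_id,
        times=df[CURVE_TIME_COL].to_numpy(float),
        values=df[value_col].to_numpy(float),
        value_kind="amount",
        m_inf=float(m_inf),
    )


def write_release_curve(curve: ReleaseCurve, path) -> None:
    """Write a curve as ``time_min,released[,fraction]`` text."""
    path = Path(path)
    cols = {CURVE_TIME_COL: curve.times}
    if curve.value_kind == "fraction":
        cols[CURVE_FRACTION_COL] = curve.values
    else:
        cols[CURVE_AMOUNT_COL] = curve.values
    pd.DataFrame(cols).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_film_panel(path) -> list[FilmRecord]:
    """Read per-film metadata records from a panel CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(path, None, f"unreadable CSV: {exc}") from exc
    missing = [c for c in ("sample_id", "thickness_mm") if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"missing required column(s) {missing}")
    records = []
    for idx, row in df.iterrows():
        lineno = int(idx) + 2
        try:
            records.append(
                FilmRecord(
                    sample_id=str(row["sample_id"]),
                    thickness_d=float(row["thickness_mm"]),
                    loaded_mt=float(row.get("loaded_mg", np.nan)),
                    released_max=float(row.get("released_max", np.nan)),
                    swelling_degree=float(row.get("swelling_pct", np.nan)),
                    yield_pct=float(row.get("yield_pct", np.nan)),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(path, lineno, str(exc)) from exc
    return records


def write_results(table: pd.DataFrame, path) -> None:
    """Write a results table losslessly (17 significant digits)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("filmrelease.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_film_panel() -> list[FilmRecord]:
    """The packaged seven-film study panel (geometry, loading, swelling, yield)."""
    rows = _load_fixture("film_panel.csv")
    return [
        FilmRecord(
            sample_id=r.sample_id,
            thickness_d=r.thickness_mm,
            loaded_mt=r.loaded_mg,
            released_max=r.released_max,
            swelling_degree=r.swelling_pct,
            yield_pct=r.yield_pct,
        )
        for r in rows.itertuples()
    ]


def load_higuchi_table() -> pd.DataFrame:
    """The packaged per-film fitted constants: k_H (1/sqrt(min)), thickness
    d (mm) and the reported diffusion coefficient D (mm^2/s)."""
    return _load_fixture("higuchi_table.csv")
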