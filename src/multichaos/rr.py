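"""R-R interval file I/O, pipeline orchestration and group summaries.

R-R interval series arrive as plain text, one inter-beat interval per line
(seconds or milliseconds), ``#`` lines being comments. Analysis follows
the beat index, so a series' sampling period is 1 per beat-step and every
rate below is "per beat". The default analysis window is the first 5000
intervals (roughly one hour of recording).

The pipeline runs, per subject: truncation to the window, delay estimation
(correlation-integral method by default), Cao embedding dimension, the
GLLE spectrum over the seven-point R-R p-grid with its width delta_W, the
correlation dimension D2, the x100 feature vector, and both fixed logistic
scorers. Identical config + inputs + seeds give identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import classify
from .corrdim import estimate_d2
from .embedding import EmbeddingParams, estimate_delay_acf, estimate_delay_ci, \
    estimate_delay_mi, estimate_dim_cao
from .errors import FormatError, MultichaosError, ParameterError
from .glle import RR_P_GRID, GLLEConfig, glle_spectrum, spectrum_width
from .series import TimeSeries

__all__ = [
    "RRRecord",
    "RunConfig",
    "PipelineResult",
    "read_rr",
    "read_series",
    "write_series",
    "run_pipeline",
    "summarize_groups",
]

logger = logging.getLogger("multichaos")

GROUPS = ("hs", "chf", "af", "unknown")


@dataclass(frozen=True)
class RRRecord:
    """One subject's R-R interval series (seconds) with provenance."""

    subject_id: str
    series: TimeSeries
    group: str = "unknown"
    source: str = ""

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ParameterError(f"group must be one of {GROUPS}, got {self.group!r}")
        if np.any(self.series.values <= 0):
            raise ParameterError("R-R intervals must be positive")


def read_rr(path, units: str = "s", subject_id: str | None = None,
            group: str = "unknown") -> RRRecord:
    """Read a one-interval-per-line text file into an :class:`RRRecord`.

    ``units`` is "s" or "ms"; everything is converted to seconds. Lines
    starting with ``#`` are comments. Non-numeric or non-positive lines
    are rejected (with 1-based line numbers); more than 1% rejected lines,
    or an empty file, is a format error.
    """
    if units not in ("s", "ms"):
        raise ParameterError("units must be 's' or 'ms'")
    path = Path(path)
    values: list[float] = []
    bad: list[int] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            v = float(line)
        except ValueError:
            bad.append(lineno)
            continue
        if not (np.isfinite(v) and v > 0):
            bad.append(lineno)
            continue
        values.append(v)
    total = len(values) + len(bad)
    if total == 0:
        raise FormatError(f"{path}: no interval lines found")
    if bad and len(bad) / total > 0.01:
        raise FormatError(f"{path}: {len(bad)} invalid interval lines "
                          f"(first at line {bad[0]})")
    if bad:
        logger.warning("%s: skipped %d invalid lines (first at line %d)",
                       path, len(bad), bad[0])
    scale = 1e-3 if units == "ms" else 1.0
    ts = TimeSeries(np.asarray(values) * scale, dt=1.0,
                    meta={"units": "s", "source": str(path)})
    return RRRecord(subject_id=subject_id or path.stem, series=ts,
                    group=group, source=str(path))


def write_series(path, ts: TimeSeries, fmt: str = "%.12g") -> None:
    """Write a series as plain text, one sample per line, with '#' headers."""
    path = Path(path)
    lines = [f"# dt = {ts.dt!r}"]
    lines += [f"# {k} = {v!r}" for k, v in ts.meta.items()]
    lines += [fmt % v for v in ts.values]
    path.write_text("\n".join(lines) + "\n")


def read_series(path) -> TimeSeries:
    """Read a plain-text series written by :func:`write_series`.

    '#' header lines of the form ``# key = value`` are restored into meta;
    a ``dt`` header sets the sampling period (default 1.0).
    """
    path = Path(path)
    dt = 1.0
    meta = {}
    values: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, sep, val = line[1:].partition("=")
            if sep:
                key = key.strip()
                val = val.strip().strip("'\"")
                if key == "dt":
                    dt = float(val)
                else:
                    meta[key] = val
            continue
        try:
            values.append(float(line))
        except ValueError:
            raise FormatError(f"{path}: non-numeric sample at line {lineno}") from None
    if not values:
        raise FormatError(f"{path}: no samples found")
    return TimeSeries(np.asarray(values), dt=dt, meta=meta)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a pipeline run.

    Serializes to/from a flat ``key = value`` text file.
    """

    delay_method: str = "ci"  # acf | mi | ci
    m_max: int = 8
    window: int = 5000  # analysis window: first N intervals
    p_grid: tuple[float, ...] = RR_P_GRID
    k_max: int | None = None
    min_sep: int | None = None
    fit_window: tuple[int, int] | None = None
    seed: int = 0
    out_dir: str | None = None

    def glle_config(self) -> GLLEConfig:
        return GLLEConfig(min_sep=self.min_sep, k_max=self.k_max,
                          fit_window=self.fit_window)

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        kwargs = {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if val == "None":
                kwargs[key] = None
            elif key == "p_grid":
                kwargs[key] = tuple(float(x) for x in val.split(","))
            elif key == "fit_window":
                kwargs[key] = tuple(int(x) for x in val.split(","))
            elif key in ("m_max", "window", "k_max", "min_sep", "seed"):
                kwargs[key] = int(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


_DELAY_ESTIMATORS = {"acf": estimate_delay_acf, "mi": estimate_delay_mi,
                     "ci": estimate_delay_ci}


@dataclass
class PipelineResult:
    """Feature table, spectra, predictions and the run log."""

    features: pd.DataFrame
    spectra: dict
    predictions: pd.DataFrame
    log: list[str] = field(default_factory=list)
    n_failed: int = 0


def run_pipeline(config: RunConfig, records: Sequence[RRRecord]) -> PipelineResult:
    """Run the full per-subject analysis over a batch of records.

    Subjects that fail a stage are logged and skipped; ``n_failed`` counts
    them. Subjects shorter than the analysis window are analyzed at full
    available length with a warning.
    """
    if not records:
        raise ParameterError("run_pipeline needs at least one record")
    if config.delay_method not in _DELAY_ESTIMATORS:
        raise ParameterError(f"unknown delay method {config.delay_method!r}")
    delay_est = _DELAY_ESTIMATORS[config.delay_method]

    rows = []
    preds = []
    spectra = {}
    log: list[str] = []
    n_failed = 0
    for rec in records:
        sid = rec.subject_id
        try:
            ts = rec.series
            if len(ts) < config.window:
                msg = (f"{sid}: series has {len(ts)} < {config.window} intervals; "
                       "analyzing full available length")
                log.append(msg)
                logger.warning(msg)
            ts = ts.truncate(config.window)
            J = int(delay_est(ts))
            m_max = config.m_max
            while m_max > 3 and len(ts) <= (m_max + 1) * J + 1:
                m_max -= 1
            cao = estimate_dim_cao(ts, J, m_max=m_max)
            params = EmbeddingParams(m=cao.m, J=J)
            spec = glle_spectrum(ts, params, p_grid=config.p_grid,
                                 config=config.glle_config())
            d2 = estimate_d2(ts, params)
            feat_values = {f"glle_{p:g}": 100.0 * est.glle
                           for p, est in zip(spec.p_grid, spec.estimates)}
            row = {"subject_id": sid, "group": rec.group, "n": len(ts),
                   "m": params.m, "J": params.J,
                   **feat_values,
                   "glle2": spec[2].glle if 2 in spec.p_grid else np.nan,
                   "delta_w": spectrum_width(spec),
                   "d2": d2.d2, "d2_r2": d2.r2}
            # the fixed scorers need the full 7-point R-R grid
            if all(name in feat_values for name in classify.FEATURE_NAMES):
                fv = classify.FeatureVector(
                    values=feat_values, subject_id=sid,
                    group=rec.group if rec.group != "unknown" else None)
                preds.append({"subject_id": sid, "group": rec.group,
                              "p_model1": classify.score_model1(fv),
                              "label_model1": classify.MODEL1.label(fv),
                              "p_model2": classify.score_model2(fv),
                              "label_model2": classify.MODEL2.label(fv)})
            rows.append(row)
            spectra[sid] = spec
            log.append(f"{sid}: ok (m={params.m}, J={params.J})")
        except MultichaosError as exc:
            n_failed += 1
            msg = f"{sid}: failed: {exc}"
            log.append(msg)
            logger.error(msg)
    features = pd.DataFrame(rows)
    predictions = pd.DataFrame(preds)
    return PipelineResult(features=features, spectra=spectra,
                          predictions=predictions, log=log, n_failed=n_failed)


def summarize_groups(features: pd.DataFrame,
                     columns: Iterable[str] = ("glle2", "delta_w", "d2")) -> pd.DataFrame:
    """Per-group median and quartiles, Me (Q1-Q3), for the headline metrics.

    Quartiles use linear interpolation. Groups with fewer than 3 subjects
    are omitted with a warning in the log.
    """
    if "group" not in features.columns or features.empty:
        raise ParameterError("feature table must be non-empty with a 'group' column")
    out = []
    for group, sub in features.groupby("group"):
        if len(sub) < 3:
            logger.warning("group %r has %d < 3 subjects; omitted", group, len(sub))
            continue
        row = {"group": group, "n": len(sub)}
        for col in columns:
            if col not in sub.columns:
                continue
            q1, me, q3 = np.quantile(sub[col].to_numpy(), [0.25, 0.5, 0.75])
            row[f"{col}_median"] = me
            row[f"{col}_q1"] = q1
            row[f"{col}_q3"] = q3
        out.append(row)
    if not out:
        raise ParameterError("no group had at least 3 subjects")
    return pd.DataFrame(out)
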