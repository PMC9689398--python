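"""Reading, writing and conditioning of cardiotocography (CTG) recordings.

A CTG recording is a pair of simultaneously sampled series — fetal heart
rate (FHR, beats/min) and uterine activity (UC, arbitrary pressure units)
— at 4 samples per second, optionally tagged with the umbilical-cord pH
measured at delivery.  Transducer loss is ubiquitous in real recordings;
here it is carried as an explicit per-sample mask (an FHR reading of 0 is
the conventional loss sentinel).

File format: plain CSV with header ``time_s,fhr,uc`` preceded by optional
metadata comment lines ``#id=...`` and ``#ph=...``.  Masked samples are
written with ``fhr`` 0.  A sidecar CSV with columns
``record_id,channel,type,onset_s,offset_s`` carries event annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_RATE_HZ = 4.0

__all__ = [
    "SAMPLE_RATE_HZ",
    "CTGRecord",
    "SmoothingConfig",
    "CTGError",
    "ParseError",
    "ParameterError",
    "UnrecoverableSignalError",
    "read_ctg",
    "write_ctg",
    "smooth",
    "interpolate_gaps",
    "standardize",
    "destandardize",
]


class CTGError(Exception):
    """Base class for CTG processing errors."""


class ParseError(CTGError):
    """A file could not be parsed; the message names the offending line."""


class ParameterError(CTGError, ValueError):
    """An argument violates a documented precondition."""


class UnrecoverableSignalError(CTGError):
    """Too little usable signal to compute the requested quantity."""


@dataclass
class CTGRecord:
    """One CTG recording: paired FHR/UC series at 4 Hz plus optional pH.

    Parameters
    ----------
    record_id : str
        Identifier carried through feature tables and reports.
    fhr : ndarray of float
        Fetal heart rate in beats/min.  Masked (lost) samples hold NaN.
    uc : ndarray of float
        Uterine activity in monitor units, same length as ``fhr``.
    ph : float or None
        Umbilical-cord pH (~6.8-7.5) if measured.
    missing_mask : ndarray of bool
        True where the transducer lost signal.
    """

    record_id: str
    fhr: np.ndarray
    uc: np.ndarray
    ph: float | None = None
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.fhr = np.asarray(self.fhr, dtype=float)
        self.uc = np.asarray(self.uc, dtype=float)
        if self.fhr.ndim != 1 or self.uc.ndim != 1:
            raise ParameterError("fhr and uc must be 1-D sample series")
        if len(self.fhr) != len(self.uc):
            raise ParameterError(
                f"fhr and uc lengths differ ({len(self.fhr)} vs {len(self.uc)})"
            )
        if len(self.fhr) == 0:
            raise ParameterError("a CTG record must contain at least one sample")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.fhr)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.fhr.shape:
                raise ParameterError("missing_mask must match the sample count")
        # loss sentinel: 0 bpm is not a physiological heart rate
        self.missing_mask |= ~np.isfinite(self.fhr) | (self.fhr == 0.0)
        self.fhr = np.where(self.missing_mask, np.nan, self.fhr)
        good = self.fhr[~self.missing_mask]
        if good.size and (good.min() < 30.0 or good.max() > 250.0):
            raise ParameterError(
                "non-missing FHR samples must lie in [30, 250] beats/min"
            )
        finite_uc = self.uc[np.isfinite(self.uc)]
        if finite_uc.size and finite_uc.min() < 0.0:
            raise ParameterError("UC samples must be non-negative")

    def __len__(self) -> int:
        return len(self.fhr)

    @property
    def duration_s(self) -> float:
        return len(self.fhr) / SAMPLE_RATE_HZ

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def copy(self) -> "CTGRecord":
        return replace(
            self,
            fhr=self.fhr.copy(),
            uc=self.uc.copy(),
            missing_mask=self.missing_mask.copy(),
        )


@dataclass(frozen=True)
class SmoothingConfig:
    """Centered moving-average smoother.

    The window is ``window_seconds`` at 4 Hz, rounded to the nearest odd
    sample count so the window is symmetric.  The default 4 s window
    (17 samples) suppresses beat-level jitter while leaving 15 s events —
    the shortest the taxonomy recognises — essentially intact.
    """

    window_seconds: float = 4.0
    mode: str = "centered_moving_average"

    def __post_init__(self) -> None:
        if self.window_seconds <= 0:
            raise ParameterError("window_seconds must be positive")
        if self.mode != "centered_moving_average":
            raise ParameterError(f"unknown smoothing mode {self.mode!r}")

    @property
    def window_samples(self) -> int:
        n = max(1, round(self.window_seconds * SAMPLE_RATE_HZ))
        return n if n % 2 == 1 else n + 1


def read_ctg(path: str | Path, dialect: str = "two_column_csv") -> CTGRecord:
    """Read a CTG recording from CSV.

    ``two_column_csv`` expects header ``fhr,uc`` (a leading ``time_s``
    column is tolerated and ignored); ``annotated_csv`` is identical but
    requires the metadata comment lines to be present.  FHR readings of 0
    or empty cells are flagged as signal loss.
    """
    path = Path(path)
    if dialect not in ("two_column_csv", "annotated_csv"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    meta: dict[str, str] = {}
    header: list[str] | None = None
    fhr_vals: list[float] = []
    uc_vals: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line[1:].partition("=")
                    meta[key.strip()] = val.strip()
                continue
            cells = [c.strip() for c in line.split(",")]
            if header is None:
                header = [c.lower() for c in cells]
                if "fhr" not in header or "uc" not in header:
                    raise ParseError(
                        f"{path} line {lineno}: header must name 'fhr' and 'uc' columns"
                    )
                i_fhr, i_uc = header.index("fhr"), header.index("uc")
                continue
            if len(cells) != len(header):
                raise ParseError(
                    f"{path} line {lineno}: expected {len(header)} columns, got {len(cells)}"
                )
            try:
                f = float(cells[i_fhr]) if cells[i_fhr] else np.nan
                u = float(cells[i_uc]) if cells[i_uc] else 0.0
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from None
            fhr_vals.append(f)
            uc_vals.append(u)
    if header is None:
        raise ParseError(f"{path}: no header row found")
    if not fhr_vals:
        raise ParseError(f"{path}: file contains a header but no samples")
    ph = float(meta["ph"]) if "ph" in meta else None
    record_id = meta.get("id", path.stem)
    return CTGRecord(
        record_id=record_id,
        fhr=np.array(fhr_vals),
        uc=np.array(uc_vals),
        ph=ph,
    )


def write_ctg(record: CTGRecord, path: str | Path) -> None:
    """Write a record as CSV; ``read_ctg`` reproduces it sample-for-sample."""
    path = Path(path)
    lines = [f"#id={record.record_id}"]
    if record.ph is not None:
        lines.append(f"#ph={float(record.ph)!r}")
    lines.append("time_s,fhr,uc")
    fhr_out = np.where(record.missing_mask, 0.0, record.fhr)
    for i in range(len(record)):
        lines.append(
            f"{i / SAMPLE_RATE_HZ!r},{float(fhr_out[i])!r},{float(record.uc[i])!r}"
        )
    path.write_text("\n".join(lines) + "\n")


def smooth(series: np.ndarray, cfg: SmoothingConfig | None = None) -> np.ndarray:
    """Centered moving average; edges use a shrinking (still centered) window.

    NaN samples are ignored inside each window, so signal-loss gaps do not
    bleed into their neighbourhood; a window that is entirely NaN stays NaN.
    """
    cfg = cfg or SmoothingConfig()
    x = np.asarray(series, dtype=float)
    w = cfg.window_samples
    if len(x) < w:
        raise ParameterError(
            f"series length {len(x)} shorter than smoothing window {w}"
        )
    s = pd.Series(x)
    out = s.rolling(window=w, center=True, min_periods=1).mean().to_numpy()
    out[~np.isfinite(x) & ~np.isfinite(out)] = np.nan
    return out


def interpolate_gaps(record: CTGRecord, max_gap_seconds: float = 15.0) -> CTGRecord:
    """Linearly fill signal-loss gaps no longer than ``max_gap_seconds``.

    Longer gaps stay masked, so downstream feature computation can exclude
    them.  The 15 s default equals the minimum event duration: a repaired
    gap can therefore never fabricate a qualifying event on its own.
    Leading/trailing gaps are extended with the nearest valid sample.
    """
    if max_gap_seconds <= 0:
        raise ParameterError("max_gap_seconds must be positive")
    rec = record.copy()
    mask = rec.missing_mask
    if mask.all():
        raise UnrecoverableSignalError(
            f"record {rec.record_id!r}: every sample is missing"
        )
    if not mask.any():
        return rec
    max_run = int(round(max_gap_seconds * SAMPLE_RATE_HZ))
    filled = (
        pd.Series(rec.fhr).interpolate(method="linear").ffill().bfill().to_numpy()
    )
    # identify runs of missing samples
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for start, stop in zip(idx[0::2], idx[1::2]):
        if stop - start <= max_run:
            rec.fhr[start:stop] = filled[start:stop]
            rec.missing_mask[start:stop] = False
    return rec


def standardize(series: np.ndarray, mean: float, std: float) -> np.ndarray:
    """Z-score a series against the given moments: ``(x - mean) / std``."""
    if std <= 0:
        raise ParameterError("std must be positive")
    return (np.asarray(series, dtype=float) - mean) / std


def destandardize(series: np.ndarray, mean: float, std: float) -> np.ndarray:
    """Exact inverse of :func:`standardize`."""
    if std <= 0:
        raise ParameterError("std must be positive")
    return np.asarray(series, dtype=float) * std + mean
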