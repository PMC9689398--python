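"""FIGO-style feature extraction from CTG recordings.

The pipeline mirrors standard computerized CTG analysis:

1. *Baseline* — an iterative fixed point.  Start from the mean of the
   whole FHR trace (M); detect accelerations/decelerations against M;
   recompute the mean over event-free samples (N); if ``|N - M| > 0.5``
   bpm, set ``M <- N`` and repeat.
2. *Events* — maximal excursions of the smoothed FHR away from the
   baseline.  An excursion qualifies if its peak deviation is at least
   15 bpm and it lasts at least 15 s.
3. *Typing* — duration bands and contraction-relative timing:
   15 s–2 min below baseline is a deceleration, 2–5 min prolonged, over
   5 min severe; a deceleration whose onset falls strictly after a
   uterine contraction's peak and before its endpoint (and lasting more
   than 15 s) is *late*; otherwise an abrupt drop (nadir reached within
   30 s of onset) is *variable*; anything else below baseline is
   *light*.  Above baseline: 15 s–2 min is an acceleration, longer is a
   prolonged acceleration.
4. *Contractions* — excursions of the UC signal more than 10 units above
   resting tone lasting 20–240 s.
5. *Histogram / variability* — distributional summaries of the FHR and
   the mean absolute successive difference over event-free samples.

The output is an 18-element feature vector per recording, plus the
cord-pH class label (pH < 7.2 is acidotic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import (
    SAMPLE_RATE_HZ,
    CTGRecord,
    ParameterError,
    SmoothingConfig,
    UnrecoverableSignalError,
    interpolate_gaps,
    smooth,
)

# Clinical thresholds (FIGO-style), in signal units and seconds.
EVENT_PEAK_BPM = 15.0  # minimum |deviation| at the event peak
EVENT_MIN_S = 15.0  # minimum event duration
PROLONGED_MIN_S = 120.0  # 2 min: accel/decel -> prolonged
SEVERE_MIN_S = 300.0  # 5 min: prolonged decel -> severe
VARIABLE_NADIR_S = 30.0  # abrupt onset: nadir reached within 30 s
CONTRACTION_AMP = 10.0  # units above resting tone
CONTRACTION_MIN_S = 20.0
CONTRACTION_MAX_S = 240.0
# Dead band around the estimated baseline: a sample within this margin is
# "at baseline" for the purpose of delimiting excursions.  Equal to the
# baseline-convergence tolerance, so it never hides a qualifying event.
BASELINE_DEADBAND_BPM = 0.5

ACCEL_TYPES = ("acceleration", "prolonged_acceleration")
DECEL_TYPES = (
    "light_deceleration",
    "variable_deceleration",
    "late_deceleration",
    "prolonged_deceleration",
    "severe_deceleration",
    "deceleration_unspecified",
)

#: Count-valued columns of the feature table (integer by construction).
COUNT_FEATURES = (
    "n_accelerations",
    "n_decelerations",
    "n_contractions",
    "n_variable_decel",
    "n_severe_decel",
    "n_late_decel",
    "n_prolonged_decel",
    "n_prolonged_accel",
    "n_light_decel",
    "hist_n_peaks",
)

FEATURE_NAMES = (
    "baseline_bpm",
    "n_accelerations",
    "n_decelerations",
    "n_contractions",
    "n_variable_decel",
    "n_severe_decel",
    "n_late_decel",
    "n_prolonged_decel",
    "n_prolonged_accel",
    "n_light_decel",
    "hist_width_bpm",
    "hist_min_bpm",
    "hist_max_bpm",
    "hist_n_peaks",
    "hist_mean",
    "hist_median",
    "hist_mode",
    "variability_bpm",
)


@dataclass
class EventAnnotation:
    """A typed excursion on the FHR axis, half-open in samples."""

    type: str
    onset: int
    offset: int
    peak_deviation_bpm: float
    paired_contraction: int | None = None

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ParameterError("event offset must exceed onset")

    @property
    def duration_s(self) -> float:
        return (self.offset - self.onset) / SAMPLE_RATE_HZ

    @property
    def is_acceleration(self) -> bool:
        return self.peak_deviation_bpm > 0


@dataclass
class Contraction:
    """A uterine contraction: onset/peak/offset samples and amplitude."""

    onset: int
    peak: int
    offset: int
    amplitude_above_tone: float

    def __post_init__(self) -> None:
        if not (self.onset <= self.peak < self.offset):
            raise ParameterError("contraction must satisfy onset <= peak < offset")

    @property
    def duration_s(self) -> float:
        return (self.offset - self.onset) / SAMPLE_RATE_HZ


@dataclass
class BaselineResult:
    """Outcome of the iterative baseline estimation."""

    M: float
    N: float
    iterations: int
    converged: bool
    event_free_mask: np.ndarray


@dataclass(frozen=True)
class LabelingConfig:
    """Cord-pH thresholding; pH below the cut is acidotic (class 1)."""

    ph_threshold: float = 7.2

    def __post_init__(self) -> None:
        if not (6.5 < self.ph_threshold < 7.6):
            raise ParameterError("ph_threshold must lie in (6.5, 7.6)")


@dataclass
class FeatureVector:
    """The 18 per-recording features used for acidosis classification."""

    baseline_bpm: float
    n_accelerations: int
    n_decelerations: int
    n_contractions: int
    n_variable_decel: int
    n_severe_decel: int
    n_late_decel: int
    n_prolonged_decel: int
    n_prolonged_accel: int
    n_light_decel: int
    hist_width_bpm: float
    hist_min_bpm: float
    hist_max_bpm: float
    hist_n_peaks: int
    hist_mean: float
    hist_median: float
    hist_mode: float
    variability_bpm: float
    events: list[EventAnnotation] = field(default_factory=list, repr=False)
    contractions: list[Contraction] = field(default_factory=list, repr=False)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


# ---------------------------------------------------------------------------
# excursions and baseline
# ---------------------------------------------------------------------------


def _excursion_intervals(
    dev: np.ndarray, deadband: float = BASELINE_DEADBAND_BPM
) -> list[tuple[int, int, int]]:
    """Maximal one-sided excursions of ``dev`` outside the dead band.

    Returns (onset, offset, sign) triples, half-open in samples.  NaN
    samples count as "at baseline" and always terminate an excursion.
    """
    with np.errstate(invalid="ignore"):
        state = np.zeros(len(dev), dtype=np.int8)
        state[dev > deadband] = 1
        state[dev < -deadband] = -1
    out: list[tuple[int, int, int]] = []
    start = 0
    for i in range(1, len(state) + 1):
        if i == len(state) or state[i] != state[start]:
            if state[start] != 0:
                out.append((start, i, int(state[start])))
            start = i
    return out


def detect_events(
    fhr: np.ndarray, baseline: float, deadband: float = BASELINE_DEADBAND_BPM
) -> list[EventAnnotation]:
    """Detect qualifying accelerations/decelerations against a baseline.

    Each returned event is a maximal excursion of the (already smoothed)
    FHR away from ``baseline`` whose peak deviation is at least 15 bpm in
    magnitude and whose duration is at least 15 s.  Typing is left to
    :func:`classify_events`; returned events carry placeholder types
    ``acceleration`` / ``deceleration_unspecified``.
    """
    x = np.asarray(fhr, dtype=float)
    if not np.isfinite(baseline):
        raise ParameterError("baseline must be finite")
    dev = x - baseline
    min_len = int(EVENT_MIN_S * SAMPLE_RATE_HZ)
    events: list[EventAnnotation] = []
    for onset, offset, sign in _excursion_intervals(dev, deadband):
        if offset - onset < min_len:
            continue
        seg = dev[onset:offset]
        peak = np.nanmax(seg) if sign > 0 else np.nanmin(seg)
        if abs(peak) < EVENT_PEAK_BPM:
            continue
        events.append(
            EventAnnotation(
                type="acceleration" if sign > 0 else "deceleration_unspecified",
                onset=onset,
                offset=offset,
                peak_deviation_bpm=float(peak),
            )
        )
    return events


def estimate_baseline(
    fhr: np.ndarray,
    tol: float = 0.5,
    max_iter: int = 50,
) -> BaselineResult:
    """Iteratively estimate the FHR baseline by removing events.

    ``M`` starts as the mean of all non-missing samples.  Each iteration
    detects events against the current ``M``, recomputes the mean ``N``
    over event-free samples, and loops with ``M <- N`` while the two
    differ by more than ``tol`` (0.5 bpm).  Non-convergence after
    ``max_iter`` iterations is reported, not raised.
    """
    x = np.asarray(fhr, dtype=float)
    valid = np.isfinite(x)
    if valid.sum() < 2 * 60 * SAMPLE_RATE_HZ:
        raise UnrecoverableSignalError(
            "baseline estimation needs at least 2 min of non-missing signal"
        )
    M = float(np.mean(x[valid]))
    N = M
    event_free = valid.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        events = detect_events(x, M)
        event_free = valid.copy()
        for ev in events:
            event_free[ev.onset : ev.offset] = False
        if not event_free.any():
            # pathological: everything inside events; fall back to all samples
            event_free = valid.copy()
        N = float(np.mean(x[event_free]))
        if abs(N - M) <= tol:
            converged = True
            M = N
            break
        M = N
    return BaselineResult(
        M=M, N=N, iterations=iterations, converged=converged,
        event_free_mask=event_free,
    )


# ---------------------------------------------------------------------------
# contractions
# ---------------------------------------------------------------------------


def estimate_tone(uc: np.ndarray, window_s: float = 600.0, q: float = 10.0) -> np.ndarray:
    """Resting uterine tone: rolling 10th percentile over a 10-min window.

    Computed on a 1 Hz decimated copy and re-expanded, which keeps the
    filter inexpensive on long recordings without visibly changing the
    estimate (tone varies over minutes, not seconds).
    """
    x = np.asarray(uc, dtype=float)
    step = int(SAMPLE_RATE_HZ)  # 4:1 decimation -> 1 Hz
    coarse = pd.Series(x[::step])
    w = max(3, int(window_s))  # samples at 1 Hz
    tone_coarse = coarse.rolling(w, center=True, min_periods=1).quantile(q / 100.0)
    idx_coarse = np.arange(len(coarse)) * step
    return np.interp(np.arange(len(x)), idx_coarse, tone_coarse.to_numpy())


def detect_contractions(uc: np.ndarray) -> list[Contraction]:
    """Detect uterine contractions in a smoothed UC series.

    A contraction is a maximal interval where the UC signal exceeds the
    resting tone by more than 10 units, lasting 20-240 s; its peak is the
    sample of maximal elevation.
    """
    x = np.asarray(uc, dtype=float)
    elev = x - estimate_tone(x)
    above = elev > CONTRACTION_AMP
    min_len = int(CONTRACTION_MIN_S * SAMPLE_RATE_HZ)
    max_len = int(CONTRACTION_MAX_S * SAMPLE_RATE_HZ)
    out: list[Contraction] = []
    idx = np.flatnonzero(
        np.diff(np.concatenate(([0], above.view(np.int8), [0])))
    )
    for start, stop in zip(idx[0::2], idx[1::2]):
        if not (min_len <= stop - start <= max_len):
            continue
        peak = start + int(np.argmax(elev[start:stop]))
        out.append(
            Contraction(
                onset=int(start),
                peak=peak,
                offset=int(stop),
                amplitude_above_tone=float(elev[peak]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# typing
# ---------------------------------------------------------------------------


def _pair_contraction(
    event: EventAnnotation, contractions: Sequence[Contraction]
) -> int | None:
    """Index of the contraction overlapping the event the most, if any."""
    best, best_overlap = None, 0
    for k, c in enumerate(contractions):
        overlap = min(event.offset, c.offset) - max(event.onset, c.onset)
        if overlap > best_overlap:
            best, best_overlap = k, overlap
    return best


def classify_events(
    events: Iterable[EventAnnotation],
    contractions: Sequence[Contraction],
    fhr: np.ndarray | None = None,
) -> list[EventAnnotation]:
    """Assign each detected excursion its clinical subtype.

    Decelerations: duration > 5 min is severe; 2-5 min prolonged; else
    late if the onset lies strictly inside (paired contraction's peak,
    its offset) and the event lasts more than 15 s; else variable if the
    nadir is reached within 30 s of onset; else light.  Accelerations:
    2 min and over is prolonged.  The precedence makes the partition
    deterministic and exhaustive.

    ``fhr`` (the same smoothed series events were detected on) is needed
    to locate the nadir for the variable-deceleration rule; without it
    the nadir is assumed at the interval midpoint.
    """
    typed: list[EventAnnotation] = []
    for ev in events:
        dur = ev.duration_s
        if ev.peak_deviation_bpm > 0:
            kind = "acceleration" if dur < PROLONGED_MIN_S else "prolonged_acceleration"
            typed.append(
                EventAnnotation(kind, ev.onset, ev.offset, ev.peak_deviation_bpm)
            )
            continue
        pair = _pair_contraction(ev, contractions)
        if dur > SEVERE_MIN_S:
            kind = "severe_deceleration"
        elif dur >= PROLONGED_MIN_S:
            kind = "prolonged_deceleration"
        elif (
            pair is not None
            and contractions[pair].peak < ev.onset < contractions[pair].offset
            and dur > EVENT_MIN_S
        ):
            kind = "late_deceleration"
        else:
            if fhr is not None:
                seg = np.asarray(fhr, dtype=float)[ev.onset : ev.offset]
                nadir_s = float(np.nanargmin(seg)) / SAMPLE_RATE_HZ
            else:
                nadir_s = dur / 2.0
            kind = (
                "variable_deceleration"
                if nadir_s <= VARIABLE_NADIR_S
                else "light_deceleration"
            )
        typed.append(
            EventAnnotation(
                kind, ev.onset, ev.offset, ev.peak_deviation_bpm,
                paired_contraction=pair if kind == "late_deceleration" else None,
            )
        )
    return typed


# ---------------------------------------------------------------------------
# histogram and variability
# ---------------------------------------------------------------------------


def histogram_features(
    fhr: np.ndarray, peak_mass_frac: float = 0.05
) -> tuple[float, float, float, int, float, float, float]:
    """Distributional summary of the FHR: (width, min, max, n_peaks, mean,
    median, mode).

    The histogram uses 1 bpm bins (matching FHR quantization); the mode is
    the center of the most populated bin; peaks are local maxima of the
    3-bin-smoothed histogram holding at least ``peak_mass_frac`` of the
    total mass.
    """
    x = np.asarray(fhr, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise UnrecoverableSignalError("histogram of an all-missing series")
    lo, hi = float(np.min(x)), float(np.max(x))
    mean, median = float(np.mean(x)), float(np.median(x))
    if hi - lo < 1.0:
        return hi - lo, lo, hi, 1, mean, median, float(np.mean([lo, hi]))
    edges = np.arange(np.floor(lo), np.ceil(hi) + 1.0)
    counts, edges = np.histogram(x, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    mode = float(centers[np.argmax(counts)])
    sm = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    floor = peak_mass_frac * counts.sum()
    n_peaks = 0
    for i in range(len(sm)):
        left = sm[i - 1] if i > 0 else -np.inf
        right = sm[i + 1] if i < len(sm) - 1 else -np.inf
        if sm[i] >= floor and sm[i] > left and sm[i] >= right:
            n_peaks += 1
    return hi - lo, lo, hi, max(1, n_peaks), mean, median, mode


def variability(fhr: np.ndarray, baseline_result: BaselineResult) -> float:
    """Mean absolute successive difference over event-free samples.

    A short-term-variability style statistic: differences are taken only
    between consecutive samples that are both event-free and non-missing,
    so excursions do not inflate it.
    """
    x = np.asarray(fhr, dtype=float)
    keep = baseline_result.event_free_mask & np.isfinite(x)
    pair_ok = keep[:-1] & keep[1:]
    if not pair_ok.any():
        raise UnrecoverableSignalError("no event-free samples to compute variability")
    d = np.diff(x)[pair_ok]
    return float(np.mean(np.abs(d)))


# ---------------------------------------------------------------------------
# labels, full pipeline, tables
# ---------------------------------------------------------------------------


def label_from_ph(ph: float, cfg: LabelingConfig | None = None) -> int:
    """1 (acidotic) if pH is strictly below the threshold, else 0."""
    cfg = cfg or LabelingConfig()
    if ph is None or not np.isfinite(ph):
        raise ParameterError("pH must be a finite number")
    return 1 if ph < cfg.ph_threshold else 0


def extract_features(
    record: CTGRecord,
    smoothing: SmoothingConfig | None = None,
    max_gap_seconds: float = 15.0,
) -> FeatureVector:
    """Run the full extraction pipeline on one recording.

    Steps: repair short signal-loss gaps, smooth both channels, estimate
    the baseline, detect and type FHR events and uterine contractions,
    and summarise the histogram and variability.
    """
    if record.duration_s < 120.0:
        raise UnrecoverableSignalError(
            f"record {record.record_id!r} is shorter than 2 min"
        )
    rec = interpolate_gaps(record, max_gap_seconds=max_gap_seconds)
    cfg = smoothing or SmoothingConfig()
    fhr_s = smooth(rec.fhr, cfg)
    uc_s = smooth(rec.uc, cfg)
    base = estimate_baseline(fhr_s)
    contractions = detect_contractions(uc_s)
    raw_events = detect_events(fhr_s, base.M)
    events = classify_events(raw_events, contractions, fhr=fhr_s)
    width, lo, hi, n_peaks, mean, median, mode = histogram_features(fhr_s)
    var = variability(fhr_s, base)
    counts = {t: 0 for t in ACCEL_TYPES + DECEL_TYPES}
    for ev in events:
        counts[ev.type] += 1
    n_decel = sum(counts[t] for t in DECEL_TYPES)
    return FeatureVector(
        baseline_bpm=base.M,
        n_accelerations=counts["acceleration"],
        n_decelerations=n_decel,
        n_contractions=len(contractions),
        n_variable_decel=counts["variable_deceleration"],
        n_severe_decel=counts["severe_deceleration"],
        n_late_decel=counts["late_deceleration"],
        n_prolonged_decel=counts["prolonged_deceleration"],
        n_prolonged_accel=counts["prolonged_acceleration"],
        n_light_decel=counts["light_deceleration"],
        hist_width_bpm=width,
        hist_min_bpm=lo,
        hist_max_bpm=hi,
        hist_n_peaks=n_peaks,
        hist_mean=mean,
        hist_median=median,
        hist_mode=mode,
        variability_bpm=var,
        events=events,
        contractions=contractions,
    )


def feature_table(
    records: Iterable[CTGRecord],
    labeling: LabelingConfig | None = None,
) -> pd.DataFrame:
    """Extract features for a cohort into one row per recording."""
    rows = []
    for rec in records:
        fv = extract_features(rec)
        row: dict[str, object] = {"record_id": rec.record_id}
        row.update(fv.as_dict())
        row["ph"] = rec.ph
        row["label"] = label_from_ph(rec.ph, labeling) if rec.ph is not None else None
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation of the numeric feature columns.

    Returns the matrix and the list of constant columns, whose
    correlations are undefined (NaN in the matrix) rather than zero.
    """
    num = table.select_dtypes(include=[np.number])
    if len(num) < 2:
        raise ParameterError("correlation needs at least 2 rows")
    constant = [c for c in num.columns if num[c].nunique(dropna=True) <= 1]
    corr = num.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    corr.loc[constant, :] = np.nan
    corr.loc[:, constant] = np.nan
    return corr, constant


def prune_rare_features(
    table: pd.DataFrame,
    labels: Sequence[int] | None = None,
    min_support: int = 3,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop count features nonzero in fewer than ``min_support`` rows.

    Features that fire in only a couple of recordings cannot influence
    the classifier; dropping them simplifies the table.  Returns the
    reduced table and the names of the dropped columns.
    """
    dropped = [
        c
        for c in COUNT_FEATURES
        if c in table.columns and int((table[c] != 0).sum()) < min_support
    ]
    return table.drop(columns=dropped), dropped
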