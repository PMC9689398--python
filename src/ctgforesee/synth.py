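"""Synthetic CTG generator with ground-truth annotations.

Real intrapartum CTG with cord-pH outcomes is hospital data and not
redistributable, so every downstream stage here is exercised on simulated
recordings that reproduce the *statistical shape* of such data: a
piecewise-stable FHR baseline in the normal range, planted accelerations
and decelerations of each recognised subtype, quasi-periodic uterine
contractions on a low resting tone, late decelerations time-locked after
contraction peaks, band-limited baseline variability, Gaussian sensor
noise, signal-loss gaps, and a cord pH drawn from class-dependent normal
distributions thresholded at 7.2.

Planted events respect the clinical detection thresholds *with margin*
(peaks at least 10 bpm above the 15 bpm floor, durations at least 10 s
inside their band), so with the noise turned off the feature-extraction
detectors must recover the planted annotation set exactly — the
generator and the detectors close over each other, which is what makes
the extraction algorithm testable without real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .features import Contraction, EventAnnotation, label_from_ph
from .io import SAMPLE_RATE_HZ, CTGRecord, ParameterError

__all__ = [
    "SynthParams",
    "GroundTruth",
    "generate_record",
    "generate_cohort",
    "non_acidotic_regime",
    "acidotic_regime",
]


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the generator; defaults describe a healthy recording.

    Rates are per hour of recording; amplitudes in beats/min (FHR) or
    monitor units (UC).  ``variability_bpm`` is the target mean absolute
    successive difference of the *unsmoothed* baseline wander.
    """

    duration_s: float = 1800.0
    baseline_bpm: float = 140.0
    baseline_drift_sd: float = 1.5
    accel_rate_per_hr: float = 12.0
    decel_rate_per_hr: float = 2.0
    decel_type_mix: dict[str, float] = field(
        default_factory=lambda: {
            "light": 0.6, "variable": 0.2, "late": 0.1,
            "prolonged": 0.1, "severe": 0.0,
        }
    )
    contraction_period_s: float = 180.0
    contraction_period_jitter_s: float = 20.0
    contraction_amp: float = 30.0
    contraction_tone: float = 8.0
    noise_sd_bpm: float = 1.0
    dropout_rate_per_hr: float = 2.0
    dropout_mean_s: float = 5.0
    variability_bpm: float = 10.0
    ph_mean: float = 7.30
    ph_sd: float = 0.06
    class_label: str = "non_acidotic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")
        if not (100.0 <= self.baseline_bpm <= 170.0):
            raise ParameterError("baseline_bpm must lie in [100, 170]")
        total = sum(self.decel_type_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError("decel_type_mix must sum to 1")
        for name, value in (
            ("accel_rate_per_hr", self.accel_rate_per_hr),
            ("decel_rate_per_hr", self.decel_rate_per_hr),
            ("noise_sd_bpm", self.noise_sd_bpm),
            ("dropout_rate_per_hr", self.dropout_rate_per_hr),
            ("variability_bpm", self.variability_bpm),
        ):
            if value < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.contraction_amp <= 10.0:
            raise ParameterError("contraction_amp must exceed 10 units")
        if self.class_label not in ("acidotic", "non_acidotic"):
            raise ParameterError("class_label must be 'acidotic' or 'non_acidotic'")


@dataclass
class GroundTruth:
    """What was planted: typed FHR events, contractions, and the pH."""

    events: list[EventAnnotation]
    contractions: list[Contraction]
    ph: float


def non_acidotic_regime(**overrides) -> SynthParams:
    """Healthy regime: reactive trace, few decelerations, pH ~ 7.30."""
    return replace(SynthParams(), **overrides)


def acidotic_regime(**overrides) -> SynthParams:
    """Compromised regime: reduced variability and accelerations, frequent
    late/variable decelerations, pH ~ 7.10."""
    base = SynthParams(
        baseline_bpm=135.0,
        accel_rate_per_hr=2.0,
        decel_rate_per_hr=8.0,
        decel_type_mix={
            "light": 0.15, "variable": 0.35, "late": 0.40,
            "prolonged": 0.08, "severe": 0.02,
        },
        variability_bpm=4.0,
        ph_mean=7.10,
        ph_sd=0.06,
        class_label="acidotic",
    )
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def _raised_cosine(n: int) -> np.ndarray:
    """Smooth 0->1->0 hump over n samples (onset/offset at exactly 0)."""
    t = np.arange(n)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * (t + 0.5) / n))


def _variable_shape(n: int) -> np.ndarray:
    """Abrupt-onset dip: linear drop to nadir in the first quarter
    (capped at 20 s), slower linear recovery."""
    drop = min(int(20 * SAMPLE_RATE_HZ), max(2, n // 4))
    shape = np.empty(n)
    shape[:drop] = np.linspace(0.0, 1.0, drop, endpoint=False)
    shape[drop:] = np.linspace(1.0, 0.0, n - drop)
    return shape


def _band_limited_wander(rng: np.random.Generator, n: int,
                         bandwidth_bpm: float, corr_s: float = 5.0) -> np.ndarray:
    """Zero-mean smooth wander emulating FHR variability.

    Gaussian noise convolved with a ~5 s Hann kernel, rescaled so its
    peak-to-peak bandwidth (~4 sd) equals ``bandwidth_bpm``.  The wander
    crosses zero every few seconds, which keeps excursion bookkeeping
    well behaved, and survives the 4 s analysis smoother far better than
    white noise would.  Clipped to ±8 bpm so it can never mask a planted
    event's 15 bpm peak margin nor fabricate one.
    """
    if bandwidth_bpm <= 0 or n < 8:
        return np.zeros(n)
    kernel = np.hanning(max(3, int(corr_s * SAMPLE_RATE_HZ)))
    kernel /= kernel.sum()
    raw = rng.standard_normal(n + len(kernel))
    sm = np.convolve(raw, kernel, mode="same")[: n]
    sm -= sm.mean()
    sd = sm.std() or 1.0
    out = sm * (bandwidth_bpm / 4.0 / sd)
    return np.clip(out, -8.0, 8.0)


def _place_intervals(
    rng: np.random.Generator,
    durations: np.ndarray,
    n_samples: int,
    forbidden: Sequence[tuple[int, int]],
    min_gap: int,
) -> list[tuple[int, int] | None]:
    """Sample non-overlapping intervals avoiding forbidden spans.

    Rejection sampling; returns one span per requested duration, in the
    same order, with ``None`` where no placement was found after the
    retry budget (the caller drops that event from the plan).
    """
    placed: list[tuple[int, int]] = []
    out: list[tuple[int, int] | None] = []
    for dur in durations:
        span = None
        hi = n_samples - int(dur) - min_gap
        if hi > min_gap:
            for _ in range(200):
                onset = int(rng.integers(min_gap, hi))
                cand = (onset, onset + int(dur))
                if all(
                    cand[1] + min_gap <= s or cand[0] >= e + min_gap
                    for s, e in placed + list(forbidden)
                ):
                    placed.append(cand)
                    span = cand
                    break
        out.append(span)
    return out


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

_DECEL_KIND = {
    "light": "light_deceleration",
    "variable": "variable_deceleration",
    "late": "late_deceleration",
    "prolonged": "prolonged_deceleration",
    "severe": "severe_deceleration",
}

# planted duration bands (s) keep >=10 s margin from classification edges
_DUR_BANDS = {
    "accel": (30.0, 90.0),
    "light": (75.0, 108.0),       # nadir (midpoint) > 30 s with margin
    "variable": (30.0, 80.0),     # nadir reached in <= 20 s by shape
    "late": (35.0, 80.0),
    "prolonged": (140.0, 280.0),
    "severe": (320.0, 420.0),
}


def generate_record(params: SynthParams) -> tuple[CTGRecord, GroundTruth]:
    """Synthesise one CTG recording plus its ground-truth annotations.

    Deterministic given ``params.seed``.  Events are planted with margin
    over the detection thresholds and never overlap on a channel; late
    decelerations onset strictly after their paired contraction's peak
    and before its offset.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * SAMPLE_RATE_HZ))
    hours = params.duration_s / 3600.0

    # --- uterine activity: tone + quasi-periodic raised-cosine bumps
    uc = np.full(n, params.contraction_tone, dtype=float)
    contractions: list[Contraction] = []
    t = rng.uniform(20.0, params.contraction_period_s)
    while True:
        dur_s = rng.uniform(50.0, 90.0)
        onset = int(t * SAMPLE_RATE_HZ)
        length = int(dur_s * SAMPLE_RATE_HZ)
        if onset + length >= n - int(10 * SAMPLE_RATE_HZ):
            break
        amp = params.contraction_amp * rng.uniform(0.9, 1.25)
        shape = _raised_cosine(length)
        uc[onset : onset + length] += amp * shape
        peak = onset + int(np.argmax(shape))
        contractions.append(
            Contraction(onset=onset, peak=peak, offset=onset + length,
                        amplitude_above_tone=float(amp))
        )
        t += max(60.0, rng.normal(params.contraction_period_s,
                                  params.contraction_period_jitter_s))

    # --- FHR: baseline + slow drift + wander + planted events
    fhr = np.full(n, params.baseline_bpm, dtype=float)
    if params.baseline_drift_sd > 0 and n > 16:
        # one very slow sinusoidal drift cycle, bounded by the drift sd
        phase = rng.uniform(0, 2 * np.pi)
        fhr += params.baseline_drift_sd * np.sin(
            2 * np.pi * np.arange(n) / n + phase
        )
    fhr += _band_limited_wander(rng, n, params.variability_bpm)

    n_accel = rng.poisson(params.accel_rate_per_hr * hours)
    n_decel = rng.poisson(params.decel_rate_per_hr * hours)
    kinds = list(params.decel_type_mix)
    probs = np.array([params.decel_type_mix[k] for k in kinds])
    decel_kinds = [kinds[i] for i in rng.choice(len(kinds), size=n_decel, p=probs)]

    min_gap = int(45 * SAMPLE_RATE_HZ)
    events: list[EventAnnotation] = []
    placed: list[tuple[int, int]] = []

    def plant(kind: str, span: tuple[int, int], sign: float) -> None:
        onset, offset = span
        length = offset - onset
        amp = rng.uniform(25.0, 35.0)
        shape = (
            _variable_shape(length) if kind == "variable" else _raised_cosine(length)
        )
        fhr[onset:offset] += sign * amp * shape
        ev_type = "acceleration" if sign > 0 else _DECEL_KIND[kind]
        if sign > 0 and length / SAMPLE_RATE_HZ >= 120.0:
            ev_type = "prolonged_acceleration"
        events.append(
            EventAnnotation(ev_type, onset, offset, float(sign * amp))
        )
        placed.append(span)

    # late decelerations: locked strictly after a contraction peak
    n_late = decel_kinds.count("late")
    late_max = int(_DUR_BANDS["late"][1] * SAMPLE_RATE_HZ)
    usable = [c for c in contractions if c.offset + late_max + min_gap < n]
    if n_late > len(usable):
        raise ParameterError(
            f"duration {params.duration_s:.0f} s hosts only {len(usable)} "
            f"contractions for {n_late} requested late decelerations"
        )
    for c in list(rng.permutation(len(usable))[:n_late]):
        c = usable[int(c)]
        lo_s, hi_s = _DUR_BANDS["late"]
        dur = int(rng.uniform(lo_s, hi_s) * SAMPLE_RATE_HZ)
        # onset strictly inside (peak, offset), at least 10 s after the peak
        onset = min(c.peak + int(10 * SAMPLE_RATE_HZ), c.offset - int(2 * SAMPLE_RATE_HZ))
        span = (onset, onset + dur)
        if not all(span[1] + min_gap <= s or span[0] >= e + min_gap for s, e in placed):
            continue  # region already occupied; drop this late deceleration
        plant("late", span, -1.0)

    # non-late events must avoid the (peak, offset] windows of contractions
    # so that planted variable/light decelerations are not typed late,
    # and keep clear of placed events
    late_zones = [
        (c.peak, c.offset + int(5 * SAMPLE_RATE_HZ)) for c in contractions
    ]
    other = ["accel"] * n_accel + [k for k in decel_kinds if k != "late"]
    durations = np.array(
        [int(rng.uniform(*_DUR_BANDS[k]) * SAMPLE_RATE_HZ) for k in other],
        dtype=int,
    )
    # an infeasible plan is rejected up front rather than silently thinned
    demand = int(durations.sum())
    if demand > 0.9 * n:
        raise ParameterError(
            f"duration {params.duration_s:.0f} s too short to host "
            f"{len(other)} requested events"
        )
    order = np.argsort(-durations)  # place long events first
    spans = _place_intervals(
        rng,
        durations[order],
        n,
        forbidden=list(placed) + late_zones,
        min_gap=min_gap,
    )
    for kind, span in zip([other[i] for i in order], spans):
        if span is not None:  # rare unlucky placement: drop the event
            plant(kind, span, 1.0 if kind == "accel" else -1.0)

    if params.noise_sd_bpm > 0:
        fhr += rng.normal(0.0, params.noise_sd_bpm, size=n)
        uc += rng.normal(0.0, params.noise_sd_bpm * 0.5, size=n)
    uc = np.clip(uc, 0.0, None)
    fhr = np.clip(fhr, 60.0, 220.0)

    # --- signal loss
    mask = np.zeros(n, dtype=bool)
    n_drop = rng.poisson(params.dropout_rate_per_hr * hours)
    for _ in range(n_drop):
        start = int(rng.integers(0, n))
        length = max(1, int(rng.exponential(params.dropout_mean_s) * SAMPLE_RATE_HZ))
        mask[start : start + length] = True

    # --- pH, truncated to keep the label consistent with the regime
    if params.class_label == "acidotic":
        lo, hi = 6.80, 7.1999
    else:
        lo, hi = 7.20, 7.50
    ph = float(np.clip(rng.normal(params.ph_mean, params.ph_sd), lo, hi))

    record = CTGRecord(
        record_id=f"synth-{params.class_label}-{params.seed}",
        fhr=np.where(mask, np.nan, fhr),
        uc=uc,
        ph=ph,
        missing_mask=mask,
    )
    truth = GroundTruth(events=sorted(events, key=lambda e: e.onset),
                        contractions=contractions, ph=ph)
    assert (label_from_ph(ph) == 1) == (params.class_label == "acidotic")
    return record, truth


def generate_cohort(
    n: int,
    acidotic_fraction: float = 0.5,
    regimes: tuple[SynthParams, SynthParams] | None = None,
    seed: int = 0,
) -> list[tuple[CTGRecord, GroundTruth]]:
    """Generate a labeled cohort of synthetic recordings.

    ``round(n * acidotic_fraction)`` records use the acidotic regime, the
    rest the non-acidotic one.  Per-record seeds are derived from the
    root seed and the record index, so the cohort is reproducible and
    insensitive to generation order.
    """
    if n < 2:
        raise ParameterError("a cohort needs at least 2 records")
    if not (0.0 <= acidotic_fraction <= 1.0):
        raise ParameterError("acidotic_fraction must lie in [0, 1]")
    if regimes is None:
        regimes = (acidotic_regime(), non_acidotic_regime())
    acid_template, normal_template = regimes
    n_acid = int(round(n * acidotic_fraction))
    out = []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
    for i in range(n):
        template = acid_template if i < n_acid else normal_template
        params = replace(template, seed=child_seeds[i])
        rec, truth = generate_record(params)
        rec.record_id = f"synth-{i:03d}-{template.class_label}"
        out.append((rec, truth))
    return out
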