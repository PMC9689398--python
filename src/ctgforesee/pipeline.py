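"""Predictive monitoring: forecast the signals, classify the future.

The headline capability: given a CTG recording, roll the per-channel
LSTM forecasters 2 or 4 minutes ahead (480 or 960 samples at 4 Hz),
append the forecasts to the observed series, re-extract the clinical
features on the extended recording, and let the abstaining ensemble
vote on the *future* fetal state — 0 (non-acidosis), 1 (acidosis) or
"unsure" when the members disagree.

``run_experiment`` reproduces the full desk-scale study from one seed:
simulate a balanced cohort, extract and prune features, train and
combine the four learners, compute the coverage/accuracy Pareto front,
train forecasters on one showcase recording per class, and emit the
future-state table.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import (
    AcidosisEnsemble,
    EnsembleResults,
    ensemble_predict,
    UNSURE,
)
from .features import (
    FEATURE_NAMES,
    FeatureVector,
    extract_features,
    feature_table,
    prune_rare_features,
)
from .forecast import ForecastModelSpec, LSTMForecaster, fast_spec
from .io import CTGRecord, ParameterError
from .synth import acidotic_regime, generate_cohort, non_acidotic_regime

__all__ = [
    "FutureStateResult",
    "predict_future_state",
    "ExperimentConfig",
    "run_experiment",
]


@dataclass
class FutureStateResult:
    """Outcome of one future-state prediction, with full provenance."""

    horizon_steps: int
    per_learner: dict[str, int]
    consensus: int | str
    feature_vector_used: FeatureVector
    forecast_fhr: np.ndarray
    forecast_uc: np.ndarray

    @property
    def horizon_seconds(self) -> float:
        return self.horizon_steps / 4.0


def predict_future_state(
    record: CTGRecord,
    fhr_model,
    uc_model,
    ensemble_models: Mapping[str, object],
    horizon_steps: int,
    feature_columns: Sequence[str] = FEATURE_NAMES,
    window: str = "full",
) -> FutureStateResult:
    """Forecast both channels and classify the extended recording.

    ``fhr_model`` / ``uc_model`` must expose ``forecast(horizon,
    history)`` returning samples in original units (a fitted
    :class:`~ctgforesee.forecast.ForecastResults` does).  ``window``
    selects whether features are extracted on the full extended series
    (default — a forecast window alone cannot host multi-minute events)
    or on the forecast segment only.  ``horizon_steps=0`` skips
    forecasting and classifies the observed recording as-is.
    """
    if horizon_steps < 0:
        raise ParameterError("horizon_steps must be non-negative")
    if window not in ("full", "forecast-only"):
        raise ParameterError("window must be 'full' or 'forecast-only'")
    if not ensemble_models:
        raise ParameterError("no ensemble models configured")

    if horizon_steps > 0:
        if fhr_model is None or uc_model is None:
            raise ParameterError("both channel forecasters are required")
        fhr_fc = np.clip(
            np.asarray(fhr_model.forecast(horizon_steps, record.fhr)), 30.0, 250.0
        )
        uc_fc = np.clip(
            np.asarray(uc_model.forecast(horizon_steps, record.uc)), 0.0, None
        )
    else:
        fhr_fc = np.empty(0)
        uc_fc = np.empty(0)

    if window == "forecast-only" and horizon_steps > 0:
        ext = CTGRecord(
            record_id=f"{record.record_id}+fc{horizon_steps}",
            fhr=fhr_fc,
            uc=uc_fc,
            ph=record.ph,
        )
    else:
        ext = CTGRecord(
            record_id=f"{record.record_id}+fc{horizon_steps}",
            fhr=np.concatenate([record.fhr, fhr_fc]),
            uc=np.concatenate([record.uc, uc_fc]),
            ph=record.ph,
            missing_mask=np.concatenate(
                [record.missing_mask, np.zeros(horizon_steps, dtype=bool)]
            ),
        )
    fv = extract_features(ext)
    x = np.array([fv.as_dict()[c] for c in feature_columns], dtype=float)
    decision = ensemble_predict(ensemble_models, x)
    return FutureStateResult(
        horizon_steps=horizon_steps,
        per_learner=decision.per_learner,
        consensus=decision.consensus,
        feature_vector_used=fv,
        forecast_fhr=fhr_fc,
        forecast_uc=uc_fc,
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """One reproducible desk-scale study."""

    n: int = 94
    acidotic_fraction: float = 0.5
    duration_s: float = 1800.0
    test_size: int = 24
    seed: int = 0
    horizons: tuple[int, ...] = (480, 960)
    ensemble_members: tuple[str, ...] = ("RF", "NN")
    forecaster: ForecastModelSpec = field(default_factory=fast_spec)
    min_support: int = 3

    def __post_init__(self) -> None:
        if self.test_size >= self.n:
            raise ParameterError("test_size must be smaller than the cohort")


def run_experiment(
    config: ExperimentConfig | None = None, out_dir: str | Path | None = None
) -> dict:
    """Run the full study; returns (and optionally writes) the report.

    Stages: simulate cohort -> extract features -> prune rare counts ->
    train/evaluate the learners and every ensemble combination ->
    Pareto front -> train FHR/UC forecasters on one showcase recording
    per class -> future-state table for each horizon.  Deterministic
    given ``config.seed``; a repeated run yields byte-identical JSON.
    """
    config = config or ExperimentConfig()

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(
                        f"experiment stage {name!r} failed (seed {config.seed}): {exc}"
                    ) from exc

        return _Ctx()

    with stage("simulate"):
        regimes = (
            acidotic_regime(duration_s=config.duration_s),
            non_acidotic_regime(duration_s=config.duration_s),
        )
        cohort = generate_cohort(
            config.n, config.acidotic_fraction, regimes=regimes, seed=config.seed
        )

    with stage("extract"):
        table = feature_table([rec for rec, _ in cohort])
        labels = table["label"].to_numpy(dtype=int)
        feats = table[list(FEATURE_NAMES)]
        pruned, dropped = prune_rare_features(feats, labels, config.min_support)

    with stage("classify"):
        model = AcidosisEnsemble(
            pruned, labels, test_size=config.test_size, seed=config.seed
        )
        results: EnsembleResults = model.fit()

    with stage("forecast"):
        showcase: dict[str, dict] = {}
        members = {m: results.models[m] for m in config.ensemble_members}
        for cls_name, want in (("non_acidosis", 0), ("acidosis", 1)):
            idx = next(
                i for i, (_, truth) in enumerate(cohort)
                if (truth.ph < 7.2) == (want == 1)
            )
            rec, _ = cohort[idx]
            fc_spec = config.forecaster
            fhr_res = LSTMForecaster(
                np.nan_to_num(rec.fhr, nan=float(np.nanmean(rec.fhr))),
                fc_spec,
            ).fit()
            uc_res = LSTMForecaster(rec.uc, fc_spec).fit()
            entry: dict = {
                "record_id": rec.record_id,
                "ph": rec.ph,
                "true_label": want,
                "fhr_report": fhr_res.report.as_dict(),
                "uc_report": uc_res.report.as_dict(),
                "horizons": {},
            }
            for horizon in config.horizons:
                fs = predict_future_state(
                    rec, fhr_res, uc_res, members, horizon,
                    feature_columns=list(pruned.columns),
                )
                entry["horizons"][str(horizon)] = {
                    "per_learner": fs.per_learner,
                    "consensus": fs.consensus,
                }
            showcase[cls_name] = entry

    future_state_table = {
        cls_name: {
            h: {
                **entry["horizons"][h]["per_learner"],
                "Ensemble output": entry["horizons"][h]["consensus"],
            }
            for h in entry["horizons"]
        }
        for cls_name, entry in showcase.items()
    }

    report = {
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "forecaster"},
            "forecaster": asdict(config.forecaster),
        },
        "dropped_features": dropped,
        "cv_metrics": {k: v.as_dict() for k, v in results.cv_metrics.items()},
        "test_metrics": {k: v.as_dict() for k, v in results.test_metrics.items()},
        "selected_hyperparameters": {
            k: {kk: (vv if vv is None or isinstance(vv, (int, float, str)) else str(vv))
                for kk, vv in v.items()}
            for k, v in results.selected_hyperparameters.items()
        },
        "combinations": [
            {
                "combo": e.name,
                "n_classified": e.n_classified,
                "accuracy_on_classified": e.accuracy_on_classified,
            }
            for e in results.combo_evaluations
        ],
        "pareto_front": [e.name for e in results.pareto],
        "showcase": showcase,
        "future_state_table": future_state_table,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, allow_nan=True) + "\n"
        )
    return report
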