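"""End-to-end orchestration: simulate -> preprocess -> features -> model.

``extract_features`` turns one recording into the 34-column qEEG feature
row used throughout: spike burden (swi, swf), whole-brain absolute and
relative band power (abs_/rel_ x 4 bands), global phase-synchrony coupling
(plv_/pli_/wpli_ x 4 bands), and sparsity-AUC graph metrics
(cpl_/cc_/sigma_ x 4 bands).  ``run_pipeline`` executes a configured run on
a synthetic cohort (or a directory of EDF files), assembles the feature
table, fits the screened backward-stepwise logistic model, and writes all
artifacts (feature table, ground truth, model JSON, validation JSON,
plot-ready CSVs) plus the verbatim configuration for reproducibility.

Per-subject failures are isolated: a failing recording yields a row of
missing features and an entry in the failure manifest; the run continues.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate
from .connectivity import (AnalyticCache, connectivity_matrices, global_value,
                           plv_fft)
from .core import BANDS, EEGRecording
from .netmetrics import SPARSITIES, metric_curves
from .predict import (LogisticModel, apply_model, bootstrap_validate, calibration,
                      compare_groups, decision_curve, default_model_pipeline,
                      nomogram_scale, roc_auc, univariable_screen, vif)
from .preprocess import csd_transform, preprocess_recording
from .spikes import compute_swi, compute_swf, swi_gate
from .spectral import band_powers, welch_psd

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "FEATURE_COLUMNS", "extract_features", "build_feature_table",
           "run_pipeline", "load_config"]

_BAND_NAMES = tuple(BANDS)

#: The 34 qEEG feature columns, in canonical order.
FEATURE_COLUMNS: tuple[str, ...] = (
    ("swi", "swf")
    + tuple(f"abs_{b}" for b in _BAND_NAMES)
    + tuple(f"rel_{b}" for b in _BAND_NAMES)
    + tuple(f"plv_{b}" for b in _BAND_NAMES)
    + tuple(f"pli_{b}" for b in _BAND_NAMES)
    + tuple(f"wpli_{b}" for b in _BAND_NAMES)
    + tuple(f"cpl_{b}" for b in _BAND_NAMES)
    + tuple(f"cc_{b}" for b in _BAND_NAMES)
    + tuple(f"sigma_{b}" for b in _BAND_NAMES)
)


@dataclass(frozen=True)
class RunConfig:
    """Every knob of a pipeline run; defaults are explicit after loading."""

    # input: either a synthetic cohort spec or a directory of EDF files
    n_per_group: tuple[int, int] = (64, 42)
    duration_s: float = 300.0
    fs: float = 500.0
    effect_scale: float = 1.0
    edf_dir: str | None = None

    # preprocessing
    low_hz: float = 1.0
    high_hz: float = 40.0
    target_fs: float = 500.0
    epoch_length_s: float = 2.0
    total_s: float | None = None          # None: full recording, capped at 300 s
    reject_peak_uv: float = 200.0

    # features
    n_null: int = 100                      # Sigma null-network count
    edge_fraction: float = 0.1
    swi_exclusion_percent: float = 50.0

    # model
    keep_threshold: float = 0.20
    removal_p: float = 0.10
    categorize: tuple[str, ...] = ("rel_alpha", "wpli_delta")
    n_bootstrap: int = 1000

    out_dir: str = "qeegpred_run"
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are a hard error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("n_per_group", "categorize"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def extract_features(rec: EEGRecording, cfg: RunConfig = RunConfig(),
                     seed=None) -> dict:
    """One 34-feature qEEG row for a recording.

    ``seed`` drives the Sigma null-network ensemble only; everything else
    is deterministic given the recording.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total_s = cfg.total_s
    if total_s is None:
        total_s = min(300.0, int(rec.duration / cfg.epoch_length_s) * cfg.epoch_length_s)
    window = (0.0, float(int(total_s)))

    row: dict = {"subject_id": rec.subject_id}
    row["swi"] = compute_swi(rec.events, window)
    row["swf"] = compute_swf(rec.events, window)

    es = preprocess_recording(
        rec, cfg.low_hz, cfg.high_hz, cfg.target_fs,
        cfg.epoch_length_s, total_s, cfg.reject_peak_uv, csd=False,
    )
    psd = band_powers(welch_psd(es, window_s=cfg.epoch_length_s))
    for b in _BAND_NAMES:
        row[f"abs_{b}"] = psd.whole_brain_abs[b]
        row[f"rel_{b}"] = psd.whole_brain_rel[b]

    es_csd = csd_transform(es)
    cache = AnalyticCache(es_csd)
    for b in _BAND_NAMES:
        mats = connectivity_matrices(es_csd, b, ("PLV", "PLI", "wPLI"),
                                     cfg.edge_fraction, cache=cache)
        for m, cm in mats.items():
            row[f"{m.lower()}_{b}"] = global_value(cm).value
        edges = plv_fft(es_csd, b)
        curves = metric_curves(edges.values, b, SPARSITIES,
                               n_null=cfg.n_null, seed=rng)
        row[f"cpl_{b}"] = curves["CPL"].auc_value
        row[f"cc_{b}"] = curves["CC"].auc_value
        row[f"sigma_{b}"] = curves["Sigma"].auc_value
    return row


def build_feature_table(recs: list[EEGRecording], cfg: RunConfig = RunConfig(),
                        seed: int | None = None) -> tuple[pd.DataFrame, list[dict]]:
    """Feature rows for a cohort, with per-subject failure isolation."""
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    children = root.spawn(len(recs))
    rows, failures = [], []
    for rec, ss in zip(recs, children):
        t0 = time.perf_counter()
        try:
            row = extract_features(rec, cfg, seed=np.random.default_rng(ss))
        except Exception as exc:  # noqa: BLE001 - isolate per-subject failures
            logger.error("feature extraction failed for %s: %s", rec.subject_id, exc)
            failures.append({"subject_id": rec.subject_id, "error": repr(exc)})
            row = {"subject_id": rec.subject_id,
                   **{c: np.nan for c in FEATURE_COLUMNS}}
        row["group_label"] = rec.meta.get("group", "")
        logger.debug("features for %s in %.2f s", rec.subject_id,
                     time.perf_counter() - t0)
        rows.append(row)
    ft = pd.DataFrame(rows)
    ft["group"] = (ft["group_label"] == "EE-SWAS").astype(int)
    return ft, failures


def _model_to_dict(model: LogisticModel) -> dict:
    return {
        "predictors": model.predictors,
        "coefficients": model.coefficients,
        "standardized_coefficients": model.standardized_coefficients,
        "intercept": model.intercept,
        "encodings": {k: list(map(float, v)) for k, v in model.encodings.items()},
        "column_ranges": {k: list(v) for k, v in model.column_ranges.items()},
        "converged": model.converged,
        "n_obs": model.n_obs,
        "outcome": model.outcome,
    }


def model_from_dict(d: dict) -> LogisticModel:
    return LogisticModel(
        predictors=list(d["predictors"]),
        coefficients={k: float(v) for k, v in d["coefficients"].items()},
        intercept=float(d["intercept"]),
        encodings={k: np.asarray(v, dtype=float) for k, v in d["encodings"].items()},
        column_ranges={k: tuple(v) for k, v in d["column_ranges"].items()},
        converged=bool(d.get("converged", True)),
        n_obs=int(d.get("n_obs", 0)),
        outcome=d.get("outcome", "group"),
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute a full configured run and write all artifacts to cfg.out_dir.

    Returns a summary dict with the feature table, fitted model, and
    validation report.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)
    )

    if cfg.edf_dir is not None:
        from .io import read_edf

        paths = sorted(Path(cfg.edf_dir).glob("*.edf"))
        recs = [read_edf(p) for p in paths]
        truth = pd.DataFrame()
    else:
        spec = simulate.study_cohort_spec(
            cfg.n_per_group, cfg.duration_s, cfg.fs,
            seed=cfg.seed, effect_scale=cfg.effect_scale,
        )
        recs, truth = simulate.generate_cohort(spec)
        truth.to_csv(out / "ground_truth.csv", index=False)

    ft, failures = build_feature_table(recs, cfg)
    # screening gate: subjects already showing the sleep-activated pattern
    ft["swi_excluded"] = ~ft["swi"].apply(
        lambda s: swi_gate(s, cfg.swi_exclusion_percent) if np.isfinite(s) else False
    )
    ft.to_csv(out / "features.csv", index=False)
    if failures:
        pd.DataFrame(failures).to_csv(out / "failures.csv", index=False)

    usable = ft[~ft["swi_excluded"] & ft[list(FEATURE_COLUMNS)].notna().all(axis=1)]
    comparisons = compare_groups(usable, "group", list(FEATURE_COLUMNS))
    comparisons.to_csv(out / "group_comparisons.csv", index=False)

    pipe = default_model_pipeline(list(FEATURE_COLUMNS), list(cfg.categorize),
                                  cfg.keep_threshold, cfg.removal_p)
    selected, screen_tab = univariable_screen(usable, "group",
                                              list(FEATURE_COLUMNS),
                                              cfg.keep_threshold)
    screen_tab.to_csv(out / "univariable_screen.csv", index=False)
    model = pipe(usable, "group")

    report: dict = {"n_subjects": len(ft), "n_usable": len(usable),
                    "n_failures": len(failures),
                    "screened": selected, "predictors": model.predictors}
    y = usable["group"].to_numpy(dtype=float)
    if model.predictors:
        probs = apply_model(model, usable)
        auc, ci = roc_auc(probs, y)
        # separation on small cohorts can hit the open-interval bound
        probs_cal = np.clip(probs, 1e-10, 1 - 1e-10)
        bins, hl, hl_p, hl_df = calibration(probs_cal, y)
        bins.to_csv(out / "calibration_bins.csv", index=False)
        dca = decision_curve(probs, y)
        dca.to_csv(out / "dca_curves.csv", index=False)
        roc_pts = _roc_points(probs, y)
        roc_pts.to_csv(out / "roc_points.csv", index=False)
        boot = bootstrap_validate(usable, pipe, "group",
                                  B=cfg.n_bootstrap, seed=cfg.seed)
        report.update(
            auc_apparent=auc, auc_ci=list(ci),
            auc_optimism_corrected=boot["auc_corrected"],
            hl_statistic=hl, hl_p=hl_p, hl_df=hl_df,
        )
        if len(model.predictors) >= 2:
            report["vif"] = vif(usable, model.predictors, model.encodings)
        scale = nomogram_scale(model)
        (out / "nomogram_scale.json").write_text(json.dumps({
            "log_odds_per_point": scale.log_odds_per_point,
            "base_log_odds": scale.base_log_odds,
            "column_base": scale.column_base,
            "coefficients": scale.coefficients,
            "column_ranges": {k: list(v) for k, v in scale.column_ranges.items()},
        }, indent=1))
    (out / "model.json").write_text(json.dumps(_model_to_dict(model), indent=1))
    (out / "validation.json").write_text(json.dumps(report, indent=1, default=float))
    return {"features": ft, "truth": truth, "model": model, "report": report}


#: Features given a true group contrast by the synthetic cohort generator.
TRUE_CONTRAST_FEATURES: tuple[str, ...] = ("swf", "rel_alpha", "wpli_delta",
                                           "cpl_delta")


def synthetic_validation_replicate(seed: int,
                                   n_train: tuple[int, int] = (60, 40),
                                   n_heldout: tuple[int, int] = (12, 8),
                                   duration_s: float = 16.0,
                                   n_null: int = 5,
                                   effect_scale: float = 1.0) -> dict:
    """One seeded end-to-end validation replicate on synthetic cohorts.

    Generates a training cohort with the engineered group contrasts plus an
    independent held-out cohort from the same process, runs the full
    screen + backward-stepwise pipeline on the training features, and
    scores the fitted model on the held-out subjects.  Returns the held-out
    AUC, the selected predictors, and which generator-contrast features
    ("true" features) the final model retained.
    """
    from .predict import apply_model, roc_auc

    cfg = RunConfig(duration_s=duration_s, n_null=n_null, seed=seed)
    spec = simulate.study_cohort_spec(n_train, duration_s, cfg.fs,
                                      seed=seed, effect_scale=effect_scale)
    recs, _ = simulate.generate_cohort(spec)
    ft, _ = build_feature_table(recs, cfg, seed=seed)
    spec_h = simulate.study_cohort_spec(n_heldout, duration_s, cfg.fs,
                                        seed=seed + 1_000_000,
                                        effect_scale=effect_scale)
    recs_h, _ = simulate.generate_cohort(spec_h)
    ft_h, _ = build_feature_table(recs_h, cfg, seed=seed + 1_000_000)

    cols = list(FEATURE_COLUMNS)
    train = ft.dropna(subset=cols)
    test = ft_h.dropna(subset=cols)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        screened, _ = univariable_screen(train, "group", cols,
                                         cfg.keep_threshold)
    pipe = default_model_pipeline(cols, list(cfg.categorize),
                                  cfg.keep_threshold, cfg.removal_p)
    model = pipe(train, "group")
    if model.predictors and test["group"].nunique() == 2:
        auc, _ = roc_auc(apply_model(model, test),
                         test["group"].to_numpy(float))
    else:
        auc = 0.5
    return {
        "heldout_auc": float(auc),
        "predictors": list(model.predictors),
        "screened": list(screened),
        "true_features_screened": sorted(set(screened)
                                         & set(TRUE_CONTRAST_FEATURES)),
        "true_features_retained": sorted(set(model.predictors)
                                         & set(TRUE_CONTRAST_FEATURES)),
        "n_train": len(train),
        "n_heldout": len(test),
    }


def _roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
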