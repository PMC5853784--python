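"""End-to-end flows: preprocess -> split -> train + CV -> validate, and
frozen-model surveys of unseen material.

Every record entering a flow is accounted for in the outputs: it appears in
the predictions/validation tables or in the audit list of removed records
with the removal reason.  Flows are deterministic given the config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, plsr, preprocess
from .spectra import SpectralRecord, TraitTable


@dataclass
class TrainingConfig:
    """Single configuration object for the training flow; defaults follow
    the reference analysis (junctions per instrument, 0.35-0.6 filter at
    800 nm, 400-2400 nm window, ~55% of records in training, up to 30
    components chosen by RMSEP-CV)."""

    traits: list[str] = field(default_factory=lambda: ["Narea", "LMA", "SPAD", "Vcmax25"])
    junctions: tuple[int, ...] | None = None     # None: use each record's own
    jump_method: str = "additive"
    average_replicates: bool = True
    outlier_bounds: tuple[float, float] = preprocess.OUTLIER_RANGE
    trim: tuple[int, int] = preprocess.TRIM_RANGE_NM
    band: tuple[int, int] | None = None          # e.g. (400, 900); None: full window
    split_seed: int = 0
    train_fraction_target: float = 0.55
    max_components: int = 30
    cv_folds: int = 10
    cv_seed: int = 0
    cv_group_by_genotype: bool = True
    one_se_rule: bool = False


@dataclass
class FlowResult:
    models: dict[str, plsr.PLSRModel]
    reports: dict[str, evaluation.ValidationReport]
    split: evaluation.SplitPlan
    removed: list[preprocess.RemovedRecord]
    audit: pd.DataFrame  # one row per input record: stage outcome + reason


def _audit_frame(records, kept, removed, split=None) -> pd.DataFrame:
    kept_ids = {r.record_id for r in kept}
    removed_map = {rr.record.record_id: rr.reason for rr in removed}
    rows = []
    for rec in records:
        rid = rec.record_id
        mean_rid = "|".join(str(k) for k in (rec.genotype, rec.experiment, rec.repetition, "mean"))
        if rid in removed_map or mean_rid in removed_map:
            status, reason = "removed", removed_map.get(rid, removed_map.get(mean_rid, ""))
            side = ""
        elif rid in kept_ids or mean_rid in kept_ids:
            status, reason = "kept", "" if rid in kept_ids else "merged into replicate mean"
            side = split.assignment.get(rid, split.assignment.get(mean_rid, "")) if split else ""
        else:
            status, reason, side = "dropped", "not matched to a preprocessed record", ""
        rows.append({"record_id": rid, "status": status, "reason": reason, "split": side})
    return pd.DataFrame(rows)


def run_training_flow(
    records: list[SpectralRecord],
    traits: TraitTable,
    config: TrainingConfig | None = None,
) -> FlowResult:
    """Train one PLSR model per configured trait with CV component selection
    and genotype-preserving validation.

    Trait values are matched to preprocessed records by
    ``(genotype, experiment, repetition)`` (leaf replicates share the trait
    measurement); records lacking a trait value are skipped for that trait
    only.
    """
    cfg = config or TrainingConfig()
    processed, removed = preprocess.preprocess_records(
        records,
        junctions=cfg.junctions,
        jump_method=cfg.jump_method,
        average=cfg.average_replicates,
        outlier_bounds=cfg.outlier_bounds,
        trim=cfg.trim,
    )
    if not processed:
        raise evaluation.EvaluationError("no records survived preprocessing")
    split = evaluation.make_split(processed, seed=cfg.split_seed, train_fraction_target=cfg.train_fraction_target)

    grid = processed[0].spectrum.wavelengths_nm
    X = plsr.reflectance_matrix(processed, grid)
    if cfg.band is not None:
        X, grid = plsr.restrict_band(X, grid, *cfg.band)

    # trait lookup keyed by (genotype, experiment, repetition)
    trait_key = {}
    for rid in traits.data.index:
        from .spectra import record_id_parts
        p = record_id_parts(str(rid))
        trait_key[(p["genotype"], p["experiment"], p["repetition"])] = rid

    rec_trait_rid = [
        trait_key.get((r.genotype, r.experiment, r.repetition)) for r in processed
    ]
    sides = np.array([split.assignment[r.record_id] for r in processed])
    genotypes = np.array([r.genotype for r in processed])
    experiments = [r.experiment for r in processed]

    models: dict[str, plsr.PLSRModel] = {}
    reports: dict[str, evaluation.ValidationReport] = {}
    recipe = {
        "junctions": list(cfg.junctions) if cfg.junctions else "per-record",
        "jump_method": cfg.jump_method,
        "outlier_band_nm": preprocess.OUTLIER_BAND_NM,
        "outlier_bounds": list(cfg.outlier_bounds),
        "trim_nm": list(cfg.trim),
        "band_nm": list(cfg.band) if cfg.band else list(cfg.trim),
    }
    for trait in cfg.traits:
        y_all = traits.values_for(trait, [rid if rid is not None else "?" for rid in rec_trait_rid])
        have = np.isfinite(y_all.to_numpy(dtype=float))
        tr = (sides == "train") & have
        va = (sides == "test") & have
        if tr.sum() < 5 or va.sum() < 3:
            raise evaluation.EvaluationError(f"trait {trait!r}: too few records with values")
        y = y_all.to_numpy(dtype=float)
        cv = plsr.cross_validate(
            X[tr], y[tr],
            max_k=cfg.max_components, folds=cfg.cv_folds, seed=cfg.cv_seed,
            groups=genotypes[tr] if cfg.cv_group_by_genotype else None,
        )
        k = plsr.select_ncomp(cv, one_se_rule=cfg.one_se_rule)
        model = plsr.fit_plsr(X[tr], y[tr], k, wavelength_grid=grid, trait_name=trait, preprocessing=recipe)
        model.training_summary.update(
            {
                "rmsep_cv": cv.rmsep_cv.tolist(),
                "press": cv.press.tolist(),
                "components": cv.components.tolist(),
                "folds": cv.fold_description,
            }
        )
        y_pred = model.predict(X[va])
        reports[trait] = evaluation.build_report(
            trait, y[va], y_pred,
            n_train=int(tr.sum()), n_components=k,
            r2_train=model.training_summary["r2_train"],
            record_ids=[processed[i].record_id for i in np.where(va)[0]],
            experiments=[experiments[i] for i in np.where(va)[0]],
        )
        models[trait] = model

    audit = _audit_frame(records, processed, removed, split)
    return FlowResult(models=models, reports=reports, split=split, removed=removed, audit=audit)


def run_survey_flow(
    models: dict[str, plsr.PLSRModel],
    records: list[SpectralRecord],
    traits: TraitTable | None = None,
    config: TrainingConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Apply frozen models to new (possibly unseen-genotype) spectra.

    Returns the per-record predictions table and, when observed traits are
    supplied, an assessment dict per trait (R^2, REP%, bias%) on the new
    material.  Records removed by preprocessing appear in the table with
    their removal reason and NaN predictions.  An empty model dict is a
    warned no-op.
    """
    if not models:
        import warnings

        warnings.warn("survey called with no models; nothing to predict", stacklevel=2)
        return pd.DataFrame(), {}
    cfg = config or TrainingConfig()
    processed, removed = preprocess.preprocess_records(
        records,
        junctions=cfg.junctions,
        jump_method=cfg.jump_method,
        average=cfg.average_replicates,
        outlier_bounds=cfg.outlier_bounds,
        trim=cfg.trim,
    )
    rows = []
    for rec in processed:
        row = {"record_id": rec.record_id, "status": "ok", "reason": ""}
        for trait, model in models.items():
            row[f"pred_{trait}"] = float(model.predict_records([rec])[0])
        rows.append(row)
    for rr in removed:
        row = {"record_id": rr.record.record_id, "status": "removed", "reason": rr.reason}
        for trait in models:
            row[f"pred_{trait}"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)

    assessment: dict[str, dict] = {}
    if traits is not None:
        from .spectra import record_id_parts

        trait_key = {}
        for rid in traits.data.index:
            p = record_id_parts(str(rid))
            trait_key[(p["genotype"], p["experiment"], p["repetition"])] = rid
        for trait, model in models.items():
            obs, pred = [], []
            for rec in processed:
                rid = trait_key.get((rec.genotype, rec.experiment, rec.repetition))
                if rid is None or trait not in traits.data.columns:
                    continue
                val = traits.data.loc[rid, trait]
                if pd.isna(val):
                    continue
                obs.append(float(val))
                pred.append(float(model.predict_records([rec])[0]))
            if len(obs) >= 3:
                obs_a, pred_a = np.array(obs), np.array(pred)
                assessment[trait] = {
                    "n": len(obs),
                    "r2": evaluation.r_squared(obs_a, pred_a),
                    "rep_percent": evaluation.rep_percent(obs_a, pred_a),
                    "bias_percent": evaluation.bias_percent(obs_a, pred_a),
                }
    return table, assessment


def save_flow_result(result: FlowResult, outdir: str | Path) -> Path:
    """Serialize models (JSON), reports (JSON + residual CSVs) and the audit
    log under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for trait, model in result.models.items():
        model.to_json(outdir / f"model_{trait}.json")
    summary = {t: r.to_dict() for t, r in result.reports.items()}
    (outdir / "validation_summary.json").write_text(json.dumps(summary, indent=2))
    for trait, rep in result.reports.items():
        rep.residuals.to_csv(outdir / f"residuals_{trait}.csv", index=False)
    result.audit.to_csv(outdir / "audit.csv", index=False)
    return outdir
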