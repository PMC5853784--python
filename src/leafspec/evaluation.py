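"""Validation machinery: genotype-preserving train/test splits, the bias and
relative-error-of-prediction percentages, R^2 variants, residual-trend
diagnostics, and the direct-vs-ratio comparison for ratio traits.

The split design assigns whole experimental repetitions of each genotype to
one side, so that every multi-repetition genotype appears in both training
and validation (about 55% of records in training by default).  Validation
statistics::

    bias (%) = 100 * (mean(y_pred) - mean(y_obs)) / mean(y_obs)
    REP  (%) = 100 * sqrt(mean((y_obs - y_pred)^2)) / mean(y_obs)

Both are unit-free (invariant to a common positive rescaling).  R^2 defaults
to the squared Pearson correlation of observed vs predicted; the
1 - SSres/SStot form is also computed and both are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plsr import cross_validate, fit_plsr, select_ncomp


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _check_pair(y_obs, y_pred):
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.size != y_pred.size or y_obs.size < 1:
        raise EvaluationError("observed and predicted vectors must have equal length >= 1")
    return y_obs, y_pred


def bias_percent(y_obs, y_pred) -> float:
    """Percentage difference between mean predicted and mean observed."""
    y_obs, y_pred = _check_pair(y_obs, y_pred)
    ybar = y_obs.mean()
    if ybar == 0:
        raise EvaluationError("bias undefined: observed mean is zero")
    return 100.0 * (y_pred.mean() - ybar) / ybar


def rep_percent(y_obs, y_pred) -> float:
    """Relative error of prediction: RMSE as a percentage of the observed
    mean."""
    y_obs, y_pred = _check_pair(y_obs, y_pred)
    ybar = y_obs.mean()
    if ybar == 0:
        raise EvaluationError("REP undefined: observed mean is zero")
    return 100.0 * float(np.sqrt(np.mean((y_obs - y_pred) ** 2))) / ybar


def r_squared(y_obs, y_pred, mode: str = "pearson_sq") -> float:
    """Coefficient of determination.

    ``mode="pearson_sq"`` (default): squared Pearson correlation of observed
    vs predicted.  ``mode="one_minus_ss"``: 1 - SSres/SStot.  The two agree
    for an unbiased perfect-slope predictor and diverge otherwise.
    """
    y_obs, y_pred = _check_pair(y_obs, y_pred)
    if y_obs.size < 3:
        raise EvaluationError("R^2 needs at least 3 points")
    if np.ptp(y_obs) == 0:
        raise EvaluationError("R^2 undefined: observed values have zero variance")
    if mode == "pearson_sq":
        if np.ptp(y_pred) == 0:
            return 0.0
        return float(np.corrcoef(y_obs, y_pred)[0, 1] ** 2)
    if mode == "one_minus_ss":
        ss_res = float(np.sum((y_obs - y_pred) ** 2))
        ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
        return 1.0 - ss_res / ss_tot
    raise ValueError(f"unknown R^2 mode {mode!r}")


# ---------------------------------------------------------------------------
# Split design
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Assignment of records to train/test by whole repetitions.

    ``assignment`` maps record_id -> "train" | "test"; the per-genotype
    presence table records how many repetitions landed on each side.
    """

    assignment: dict[str, str]
    train_fraction: float
    genotype_table: pd.DataFrame
    seed: int

    def side(self, record_id: str) -> str:
        return self.assignment[record_id]

    @property
    def train_ids(self) -> list[str]:
        return [r for r, s in self.assignment.items() if s == "train"]

    @property
    def test_ids(self) -> list[str]:
        return [r for r, s in self.assignment.items() if s == "test"]


def make_split(records, seed: int = 0, train_fraction_target: float = 0.55) -> SplitPlan:
    """Split records so every multi-repetition genotype is present on both
    sides, randomising at the repetition level (never the record level).

    Per genotype with R distinct repetitions, round(target * R) repetitions
    (clipped to [1, R-1]) are drawn for training.  A genotype with a single
    repetition goes to training with a warning.  Reproducible by seed.
    """
    rng = np.random.default_rng(seed)
    by_geno: dict[str, dict] = {}
    for rec in records:
        by_geno.setdefault(rec.genotype, {}).setdefault(rec.repetition, []).append(rec)
    assignment: dict[str, str] = {}
    rows = []
    for geno in sorted(by_geno):
        reps = sorted(by_geno[geno], key=str)
        if len(reps) == 1:
            warnings.warn(
                f"genotype {geno!r} has a single repetition; assigned to train "
                "(cannot appear on both sides)",
                stacklevel=2,
            )
            train_reps = set(reps)
        else:
            n_train = int(np.clip(round(train_fraction_target * len(reps)), 1, len(reps) - 1))
            train_reps = set(rng.choice(len(reps), size=n_train, replace=False))
            train_reps = {reps[i] for i in train_reps}
        for rep in reps:
            side = "train" if rep in train_reps else "test"
            for rec in by_geno[geno][rep]:
                assignment[rec.record_id] = side
        rows.append(
            {
                "genotype": geno,
                "n_repetitions": len(reps),
                "n_train_reps": len(train_reps),
                "n_test_reps": len(reps) - len(train_reps),
            }
        )
    n_train = sum(1 for s in assignment.values() if s == "train")
    return SplitPlan(
        assignment=assignment,
        train_fraction=n_train / max(len(assignment), 1),
        genotype_table=pd.DataFrame(rows),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Reports and diagnostics
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Validation-set performance of one trait model."""

    trait_name: str
    n_train: int
    n_val: int
    n_components: int
    r2_train: float
    r2_val: float
    r2_val_ss: float
    rep_val: float
    bias_val: float
    residuals: pd.DataFrame = field(default_factory=pd.DataFrame)
    # residuals columns: record_id, experiment, observed, predicted, residual

    def to_dict(self) -> dict:
        return {
            "trait": self.trait_name,
            "n_train": self.n_train,
            "n_val": self.n_val,
            "n_components": self.n_components,
            "r2_train": self.r2_train,
            "r2_val": self.r2_val,
            "r2_val_one_minus_ss": self.r2_val_ss,
            "rep_val_percent": self.rep_val,
            "bias_val_percent": self.bias_val,
        }


def build_report(
    trait_name, y_obs, y_pred, n_train, n_components, r2_train,
    record_ids=None, experiments=None,
) -> ValidationReport:
    y_obs, y_pred = _check_pair(y_obs, y_pred)
    res = pd.DataFrame(
        {
            "record_id": record_ids if record_ids is not None else np.arange(y_obs.size),
            "experiment": experiments if experiments is not None else "all",
            "observed": y_obs,
            "predicted": y_pred,
            "residual": y_obs - y_pred,
        }
    )
    return ValidationReport(
        trait_name=trait_name,
        n_train=int(n_train),
        n_val=int(y_obs.size),
        n_components=int(n_components),
        r2_train=float(r2_train),
        r2_val=r_squared(y_obs, y_pred, "pearson_sq"),
        r2_val_ss=r_squared(y_obs, y_pred, "one_minus_ss"),
        rep_val=rep_percent(y_obs, y_pred),
        bias_val=bias_percent(y_obs, y_pred),
        residuals=res,
    )


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx = np.var(x)
    if vx == 0:
        return 0.0
    return float(np.cov(x, y, bias=True)[0, 1] / vx)


def residual_diagnostics(report: ValidationReport) -> pd.DataFrame:
    """Per-experiment OLS slopes of residual on predicted and on observed.

    An underfitting (variance-shrinking) model shows slope ~ 0 against
    predicted but a positive slope against observed -- the classic trend in
    residual-vs-observed panels.
    """
    if report.residuals.empty:
        raise EvaluationError("report carries no residuals")
    rows = []
    for exp, grp in report.residuals.groupby("experiment"):
        rows.append(
            {
                "experiment": exp,
                "n": len(grp),
                "slope_vs_predicted": _ols_slope(grp["predicted"], grp["residual"]),
                "slope_vs_observed": _ols_slope(grp["observed"], grp["residual"]),
            }
        )
    return pd.DataFrame(rows)


def ratio_trait_comparison(
    X_train, y_num_train, y_den_train, X_val, y_num_val, y_den_val,
    max_k: int = 30, folds: int = 10, seed: int = 0,
) -> dict:
    """Predict a ratio trait two ways and compare validation R^2.

    (a) ``direct``: one PLSR model trained on y_num/y_den itself;
    (b) ``from_components``: separate models for numerator and denominator,
    predictions divided.  Component counts are chosen by CV per model.
    Returns validation R^2 (squared Pearson) for both routes.
    """
    y_den_train = np.asarray(y_den_train, float)
    y_den_val = np.asarray(y_den_val, float)
    if np.any(y_den_train <= 0) or np.any(y_den_val <= 0):
        raise EvaluationError("ratio denominator must be positive")
    y_num_train = np.asarray(y_num_train, float)
    y_num_val = np.asarray(y_num_val, float)
    ratio_train = y_num_train / y_den_train
    ratio_val = y_num_val / y_den_val

    def _train_predict(ytr):
        cv = cross_validate(X_train, ytr, max_k=max_k, folds=folds, seed=seed)
        k = select_ncomp(cv)
        model = fit_plsr(X_train, ytr, k)
        return model.predict(X_val), k

    pred_direct, k_direct = _train_predict(ratio_train)
    pred_num, k_num = _train_predict(y_num_train)
    pred_den, k_den = _train_predict(y_den_train)
    pred_den = np.where(np.abs(pred_den) > 1e-12, pred_den, np.nan)
    pred_ratio = pred_num / pred_den
    ok = np.isfinite(pred_ratio)
    return {
        "r2_direct": r_squared(ratio_val, pred_direct),
        "r2_from_components": r_squared(ratio_val[ok], pred_ratio[ok]),
        "k_direct": k_direct,
        "k_num": k_num,
        "k_den": k_den,
    }
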