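"""Partial least squares regression (PLS1) for trait-on-reflectance models.

The estimator is the classic NIPALS bilinear decomposition for a univariate
response: X and y are mean-centered (no unit-variance scaling -- the
chemometric convention for reflectance spectra), components are extracted
sequentially, and the k-component model is collapsed into one regression
coefficient per wavelength plus an intercept.  The coefficient form and the
score form give identical predictions.

Component count is chosen by cross-validation: RMSEP-CV(k) assembled from
out-of-fold predictions, with PRESS(k) = n * RMSEP-CV(k)^2 when the folds
partition the sample.  The selection rule is the argmin of RMSEP-CV, ties
broken toward fewer components; a one-standard-error parsimony rule is
available behind a flag.

Models serialize to JSON (including centering vectors and the preprocessing
recipe, so frozen models are self-describing) and to a two-column
wavelength/coefficient CSV for interoperability with published coefficient
tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class PLSRError(ValueError):
    pass


@dataclass
class PLSRModel:
    """A fitted univariate PLSR model in coefficient form.

    ``predict(x) = intercept + coefficients @ x`` for a reflectance row on
    ``wavelength_grid``.  Loadings/weights/scores are retained for
    diagnostics and for score-form prediction.
    """

    trait_name: str
    wavelength_grid: np.ndarray
    coefficients: np.ndarray
    intercept: float
    n_components: int
    x_center: np.ndarray
    y_center: float
    x_weights: np.ndarray | None = None  # p x k, orthonormal NIPALS weights
    x_loadings: np.ndarray | None = None  # p x k
    y_loadings: np.ndarray | None = None  # k
    scores: np.ndarray | None = None  # n x k training scores
    training_summary: dict = field(default_factory=dict)
    preprocessing: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelength_grid = np.asarray(self.wavelength_grid, dtype=np.int64)
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        self.x_center = np.asarray(self.x_center, dtype=np.float64)
        if self.coefficients.size != self.wavelength_grid.size:
            raise PLSRError("coefficient vector length must equal wavelength grid length")
        if self.n_components < 1:
            raise PLSRError("n_components must be >= 1")

    # -- prediction ---------------------------------------------------------
    def predict(self, X: np.ndarray) -> np.ndarray:
        """Coefficient-form prediction for rows of reflectance on the model
        grid; the training-mean spectrum maps to the training-mean trait."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.wavelength_grid.size:
            raise PLSRError(
                f"input has {X.shape[1]} wavelengths, model expects {self.wavelength_grid.size}"
            )
        return self.intercept + X @ self.coefficients

    def predict_scores_form(self, X: np.ndarray) -> np.ndarray:
        """Score-form prediction via the latent decomposition; agrees with
        :meth:`predict` to ~1e-12 (regression-form equivalence)."""
        if self.x_weights is None or self.x_loadings is None or self.y_loadings is None:
            raise PLSRError("model was loaded without loadings; score form unavailable")
        Xc = np.atleast_2d(np.asarray(X, dtype=float)) - self.x_center
        W, P, q = self.x_weights, self.x_loadings, self.y_loadings
        T = Xc @ W @ np.linalg.inv(P.T @ W)  # rotated scores
        return self.y_center + T @ q

    def predict_records(self, records) -> np.ndarray:
        """Predict for SpectralRecords, matching the model grid by exact
        wavelength; missing wavelengths raise with the offending list."""
        X = reflectance_matrix(records, self.wavelength_grid)
        return self.predict(X)

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "trait": self.trait_name,
            "wavelengths": self.wavelength_grid.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "n_components": self.n_components,
            "x_center": self.x_center.tolist(),
            "y_center": self.y_center,
            "preprocessing": self.preprocessing,
            "training_summary": self.training_summary,
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSRModel":
        d = json.loads(Path(path).read_text())
        return cls(
            trait_name=d["trait"],
            wavelength_grid=np.array(d["wavelengths"], dtype=np.int64),
            coefficients=np.array(d["coefficients"]),
            intercept=float(d["intercept"]),
            n_components=int(d["n_components"]),
            x_center=np.array(d["x_center"]),
            y_center=float(d["y_center"]),
            preprocessing=d.get("preprocessing", {}),
            training_summary=d.get("training_summary", {}),
        )

    def to_coefficient_csv(self, path: str | Path) -> Path:
        """Two-column (wavelength, coefficient) CSV with the intercept on a
        leading comment header line -- the format of published coefficient
        tables."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# trait={self.trait_name} intercept={self.intercept:.17g} "
                     f"n_components={self.n_components}\n")
            fh.write("wavelength_nm,coefficient\n")
            for w, c in zip(self.wavelength_grid, self.coefficients):
                fh.write(f"{int(w)},{c:.17g}\n")
        return path

    @classmethod
    def from_coefficient_csv(cls, path: str | Path, trait_name: str | None = None) -> "PLSRModel":
        """Import an external coefficient table (possibly sparse in
        wavelength, e.g. a published 22-wavelength model).  The centering is
        folded into the intercept, so ``x_center`` is zero."""
        path = Path(path)
        intercept = 0.0
        trait = trait_name or path.stem
        ncomp = 1
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                k, _, v = tok.partition("=")
                if k == "intercept":
                    intercept = float(v)
                elif k == "trait" and trait_name is None:
                    trait = v
                elif k == "n_components":
                    ncomp = int(v)
            df = pd.read_csv(path, skiprows=1)
        else:
            df = pd.read_csv(path)
        wl = df.iloc[:, 0].to_numpy(dtype=np.int64)
        coef = df.iloc[:, 1].to_numpy(dtype=np.float64)
        return cls(
            trait_name=trait,
            wavelength_grid=wl,
            coefficients=coef,
            intercept=intercept,
            n_components=ncomp,
            x_center=np.zeros_like(coef),
            y_center=0.0,
        )


def reflectance_matrix(records: Sequence, grid: np.ndarray) -> np.ndarray:
    """Stack record reflectances onto ``grid`` (exact wavelength match);
    raises listing the missing wavelengths on a grid mismatch."""
    grid = np.asarray(grid, dtype=np.int64)
    rows = []
    for rec in records:
        w = rec.spectrum.wavelengths_nm
        w0, w1 = int(w[0]), int(w[-1])
        missing = [int(g) for g in (grid[0], grid[-1]) if not (w0 <= g <= w1)]
        if missing:
            raise PLSRError(
                f"record {rec.record_id}: spectrum [{w0}, {w1}] nm does not cover model "
                f"wavelengths {missing}"
            )
        idx = grid - w0
        rows.append(rec.spectrum.reflectance[idx])
    return np.asarray(rows, dtype=float)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, k: int, strict: bool = True):
    """Sequential PLS1 extraction on centered data.

    Per component: weight w = X'y normalised, score t = Xw, X-loading
    p = X't/t't, y-loading q = y't/t't, then deflate X (and y) by the
    rank-one fits.  For a univariate response no inner iteration is needed.
    Returns (W, P, q, T); with ``strict=False`` extraction stops early when
    the residual covariance vanishes (rank exhausted, e.g. noise-free
    low-rank data) and fewer than k columns come back.
    """
    n, p = Xc.shape
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    q = np.zeros(k)
    T = np.zeros((n, k))
    X = Xc.copy()
    y = yc.copy()
    scale = max(float(np.linalg.norm(Xc.T @ yc)), 1.0)
    achieved = 0
    for a in range(k):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-12 * scale:
            if strict:
                raise PLSRError(
                    f"component {a + 1}: residual covariance vanished (rank of X or y exhausted)"
                )
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-14:
            if strict:
                raise PLSRError(f"component {a + 1}: degenerate score vector")
            break
        pvec = X.T @ t / tt
        qa = float(y @ t) / tt
        X = X - np.outer(t, pvec)
        y = y - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t
        achieved = a + 1
    return W[:, :achieved], P[:, :achieved], q[:achieved], T[:, :achieved]


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    wavelength_grid: np.ndarray | None = None,
    trait_name: str = "trait",
    preprocessing: dict | None = None,
) -> PLSRModel:
    """Fit a k-component PLS1 model of trait ``y`` on reflectance ``X``.

    Mean-centers both, runs NIPALS, and collapses the latent model into the
    coefficient vector  b = W (P'W)^-1 q  with intercept
    ybar - xbar.b.  Requires n >= k + 2 and a non-constant y.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise PLSRError("X and y sample counts differ")
    if np.isnan(X).any() or np.isnan(y).any():
        raise PLSRError("missing values are not supported")
    if k >= n:
        raise PLSRError(f"k={k} components require more than k samples (n={n})")
    if np.ptp(y) == 0:
        raise PLSRError("constant trait vector: degenerate target")
    xbar = X.mean(axis=0)
    ybar = float(y.mean())
    W, P, q, T = _nipals_pls1(X - xbar, y - ybar, k)
    beta = W @ np.linalg.solve(P.T @ W, q)
    model = PLSRModel(
        trait_name=trait_name,
        wavelength_grid=wavelength_grid if wavelength_grid is not None else np.arange(p),
        coefficients=beta,
        intercept=ybar - float(xbar @ beta),
        n_components=k,
        x_center=xbar,
        y_center=ybar,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        preprocessing=preprocessing or {},
    )
    yhat = model.predict(X)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - ybar) ** 2))
    model.training_summary = {"n": int(n), "r2_train": 1.0 - ss_res / ss_tot}
    return model


# ---------------------------------------------------------------------------
# Cross-validation and component selection
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-component-count cross-validation error curve."""

    components: np.ndarray  # candidate k values, ascending
    rmsep_cv: np.ndarray
    press: np.ndarray
    n: int
    fold_description: str = ""
    rmsep_se: np.ndarray | None = None  # SE of per-fold RMSEP, for the 1-SE rule

    @property
    def chosen_k(self) -> int:
        return select_ncomp(self)


def _make_folds(n: int, folds: int, seed: int, groups: Sequence | None) -> list[np.ndarray]:
    """Seeded fold assignment; with groups, whole groups share a fold."""
    rng = np.random.default_rng(seed)
    if groups is None:
        idx = rng.permutation(n)
        return [idx[f::folds] for f in range(folds)]
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    order = rng.permutation(len(uniq))
    fold_of_group = {uniq[g]: f % folds for f, g in enumerate(order)}
    assign = np.array([fold_of_group[g] for g in groups])
    return [np.where(assign == f)[0] for f in range(folds) if np.any(assign == f)]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    max_k: int = 30,
    folds: int = 10,
    seed: int = 0,
    groups: Sequence | None = None,
) -> CVResult:
    """RMSEP-CV and PRESS for every component count 1..max_k.

    Out-of-fold predictions are assembled over all folds (each sample is
    predicted exactly once), so PRESS(k) = n * RMSEP-CV(k)^2 holds as an
    identity.  With ``groups`` (e.g. genotype labels) whole groups share a
    fold, preventing leakage between repetitions of one genotype.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if folds < 2:
        raise PLSRError("need at least 2 folds")
    fold_idx = _make_folds(n, folds, seed, groups)
    smallest_train = min(n - fi.size for fi in fold_idx)
    max_k = min(max_k, smallest_train - 2)
    if max_k < 1:
        raise PLSRError("folds leave too few training samples for even 1 component")
    for fi in fold_idx:
        if n - fi.size < 2:
            raise PLSRError("a fold leaves fewer than 2 training records")

    ks = np.arange(1, max_k + 1)
    oof = np.full((n, max_k), np.nan)
    per_fold_rmse = np.full((len(fold_idx), max_k), np.nan)
    for f, test in enumerate(fold_idx):
        train = np.setdiff1d(np.arange(n), test)
        Xtr, ytr = X[train], y[train]
        xbar, ybar = Xtr.mean(axis=0), float(ytr.mean())
        W, P, q, _ = _nipals_pls1(Xtr - xbar, ytr - ybar, max_k, strict=False)
        achieved = q.size  # may be < max_k on rank-deficient folds
        # cumulative coefficient vectors: reuse one decomposition for all k
        PtW = P.T @ W
        for k in ks:
            kk = min(int(k), achieved)
            beta = W[:, :kk] @ np.linalg.solve(PtW[:kk, :kk], q[:kk])
            pred = ybar + (X[test] - xbar) @ beta
            oof[test, k - 1] = pred
            per_fold_rmse[f, k - 1] = float(np.sqrt(np.mean((y[test] - pred) ** 2)))
    press = np.nansum((y[:, None] - oof) ** 2, axis=0)
    rmsep = np.sqrt(press / n)
    se = np.nanstd(per_fold_rmse, axis=0, ddof=1) / np.sqrt(len(fold_idx))
    desc = f"{len(fold_idx)}-fold, seed={seed}, " + ("grouped" if groups is not None else "record-level")
    return CVResult(components=ks, rmsep_cv=rmsep, press=press, n=n, fold_description=desc, rmsep_se=se)


def select_ncomp(cv: CVResult, one_se_rule: bool = False) -> int:
    """Smallest-RMSEP-CV rule: the argmin of the error curve, ties broken
    toward fewer components.  With ``one_se_rule``, the smallest k whose
    RMSEP is within one standard error of the minimum."""
    if cv.components.size == 0:
        raise PLSRError("empty CV result")
    i_min = int(np.argmin(cv.rmsep_cv))  # argmin returns the first minimum -> smaller k on ties
    if not one_se_rule:
        return int(cv.components[i_min])
    se = cv.rmsep_se if cv.rmsep_se is not None else np.zeros_like(cv.rmsep_cv)
    threshold = cv.rmsep_cv[i_min] + se[i_min]
    ok = np.where(cv.rmsep_cv <= threshold)[0]
    return int(cv.components[ok[0]])


def restrict_band(
    X: np.ndarray, grid: np.ndarray, low_nm: int = 400, high_nm: int = 900
) -> tuple[np.ndarray, np.ndarray]:
    """Keep only the wavelength columns inside [low_nm, high_nm] (e.g. the
    visible/NIR-only 400-900 nm scenario); downstream fitting is unchanged."""
    grid = np.asarray(grid, dtype=np.int64)
    mask = (grid >= low_nm) & (grid <= high_nm)
    if not mask.any():
        raise PLSRError(f"band [{low_nm}, {high_nm}] nm contains no grid wavelengths")
    return np.asarray(X, dtype=float)[:, mask], grid[mask]
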