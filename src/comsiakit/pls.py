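"""Partial least squares (NIPALS), exact leave-one-out CV and field scans.

Grid field blocks have far more columns than compounds and the columns are
strongly collinear, which is the textbook PLS setting: latent components are
extracted sequentially (NIPALS) and regression runs on those.  Internal
quality is the leave-one-out cross-validated q²; the whole preprocessing
pipeline (column filtering, centering) is refit inside every fold so q²
carries no leakage.  The exact LOO loop is used rather than any covariance
shortcut — exactness is what the oracle tests check.

The field scan fits one model per non-empty subset of the available property
fields (31 models for all five) and ranks them by q², reproducing the
sequential model-search table of similarity-field QSAR studies.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fields import FIELD_KINDS, FieldBlock, column_filter

logger = logging.getLogger(__name__)

_EPS = 1e-12


class PLSError(ValueError):
    pass


def _nipals_coefs(Xc: np.ndarray, yc: np.ndarray, n_components: int) -> list[np.ndarray]:
    """Sequential PLS1 coefficient vectors B_1..B_A on centered data.

    Stops early when the residual X carries no more covariance with y; the
    returned list length is the effective number of components.
    """
    X = Xc.copy()
    scale = max(float(np.abs(Xc).max(initial=0.0)) * float(np.abs(yc).max(initial=0.0)), _EPS)
    W, P, Q = [], [], []
    coefs: list[np.ndarray] = []
    for _ in range(n_components):
        w = X.T @ yc
        nw = np.linalg.norm(w)
        if nw <= 1e-10 * scale:
            break
        w = w / nw
        t = X @ w
        tt = float(t @ t)
        if tt <= _EPS:
            break
        p = X.T @ t / tt
        q = float(yc @ t) / tt
        X = X - np.outer(t, p)
        W.append(w)
        P.append(p)
        Q.append(q)
        Wm = np.column_stack(W)
        Pm = np.column_stack(P)
        # B = W (PᵀW)⁻¹ q maps loadings back to the original columns
        B = Wm @ np.linalg.solve(Pm.T @ Wm, np.asarray(Q))
        coefs.append(B)
    return coefs


@dataclass
class PLSModel:
    """Fitted latent-variable model on (filtered) field columns.

    ``coef`` acts on centered columns: yhat = (X − x_mean)·coef + y_mean.
    ``column_field``/``column_grid_index`` (set by the field scan) record,
    for every kept column, which property field it came from and its index
    in that field's full grid — the contour module needs both.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    coef: np.ndarray
    n_train: int
    r2: float
    see: float
    f_stat: float
    fitted: np.ndarray
    x_sigma: np.ndarray
    column_field: np.ndarray | None = None
    column_grid_index: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coef + self.y_mean


def regression_summary(y: np.ndarray, y_fit: np.ndarray, n_terms: int):
    """(r², SEE, F) for a fitted model with ``n_terms`` effective predictors.

    SEE = sqrt(RSS/(n − k − 1)); F = (r²·(n − k − 1))/((1 − r²)·k).  An exact
    fit yields F = inf.
    """
    y = np.asarray(y, float)
    y_fit = np.asarray(y_fit, float)
    n = len(y)
    dof = n - n_terms - 1
    if dof <= 0:
        raise PLSError(f"no residual degrees of freedom (n={n}, terms={n_terms})")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        raise PLSError("constant response: r^2 undefined")
    rss = float(np.sum((y - y_fit) ** 2))
    r2 = 1.0 - rss / ss_tot
    see = float(np.sqrt(rss / dof))
    if rss <= _EPS * ss_tot:
        f_stat = float("inf")
    else:
        f_stat = (r2 * dof) / ((1.0 - r2) * n_terms)
    return r2, see, f_stat


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit PLS with ``n_components`` latent variables (capped at the data rank).

    At full rank the fit coincides with ordinary least squares on the same
    columns, which is the oracle property the tests exercise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3:
        raise PLSError("PLS needs at least 3 training rows")
    if n_components < 1:
        raise PLSError("n_components must be >= 1")
    cap = min(n - 1, p)
    if n_components > cap:
        warnings.warn(f"n_components={n_components} exceeds rank bound {cap}; capped",
                      stacklevel=2)
        n_components = cap
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    coefs = _nipals_coefs(X - x_mean, y - y_mean, n_components)
    if not coefs:
        raise PLSError("no extractable PLS component (X carries no covariance with y)")
    if len(coefs) < n_components:
        logger.debug("NIPALS stopped at %d of %d requested components", len(coefs), n_components)
    n_eff = len(coefs)
    coef = coefs[-1]
    fitted = (X - x_mean) @ coef + y_mean
    r2, see, f_stat = regression_summary(y, fitted, n_eff)
    return PLSModel(n_components=n_eff, x_mean=x_mean, y_mean=y_mean, coef=coef,
                    n_train=n, r2=r2, see=see, f_stat=f_stat, fitted=fitted,
                    x_sigma=X.std(axis=0))


@dataclass(frozen=True)
class LOOResult:
    """Leave-one-out summary: per-N q², SEP, PRESS, and the chosen N."""

    q2: np.ndarray        # index a-1 holds q² at N=a
    sep: np.ndarray
    press: np.ndarray
    n_opt: int
    y_loo: np.ndarray     # (n, N_max) LOO predictions per component count

    @property
    def q2_opt(self) -> float:
        return float(self.q2[self.n_opt - 1])

    @property
    def sep_opt(self) -> float:
        return float(self.sep[self.n_opt - 1])


def _block_scales(Xf: np.ndarray, col_field: np.ndarray) -> np.ndarray:
    """Per-column divisor standardising each field block by its overall σ."""
    scales = np.ones(Xf.shape[1])
    for k in np.unique(col_field):
        sel = col_field == k
        s = float(Xf[:, sel].std())
        if s > 0:
            scales[sel] = s
    return scales


def loo_q2(X: np.ndarray, y: np.ndarray, n_max: int,
           filter_threshold: float | None = None,
           filter_mode: str = "range",
           column_field: np.ndarray | None = None,
           block_scale: bool = False) -> LOOResult:
    """Exact leave-one-out cross-validation of the full pipeline.

    For every left-out compound the column filter (if requested) and the
    centering statistics are recomputed on the remaining n−1 rows and PLS is
    refit from scratch.  q²(N) = 1 − PRESS(N)/SS, with SS the squared
    deviations of each held-out activity from its fold-complement mean.
    Ties in q² resolve toward fewer components.  SEP(N) =
    sqrt(PRESS/(n − N − 1)) where defined, NaN otherwise.

    ``block_scale`` standardises each property-field block (grouped by
    ``column_field``) by its overall standard deviation after filtering,
    recomputed inside every fold; it equalises the leverage of fields whose
    atom weights live on very different scales (e.g. cubed radii vs binary
    flags).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 4:
        raise PLSError("LOO cross-validation needs at least 4 rows")
    n_max = min(n_max, n - 2, p)
    if n_max < 1:
        raise PLSError("no admissible component count")
    if block_scale and column_field is None:
        raise PLSError("block_scale requires column_field labels")

    y_loo = np.empty((n, n_max))
    ss_tot = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        Xtr, ytr = X[keep], y[keep]
        fold_mean = float(ytr.mean())
        ss_tot += (y[i] - fold_mean) ** 2
        if filter_threshold is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mask = column_filter(Xtr, filter_threshold, filter_mode)
        else:
            mask = np.ones(p, dtype=bool)
        if not mask.any():
            y_loo[i, :] = fold_mean
            continue
        Xf = Xtr[:, mask]
        xi = X[i, mask]
        if block_scale:
            scales = _block_scales(Xf, column_field[mask])
            Xf = Xf / scales
            xi = xi / scales
        xm = Xf.mean(axis=0)
        coefs = _nipals_coefs(Xf - xm, ytr - fold_mean, n_max)
        xi = xi - xm
        for a in range(n_max):
            B = coefs[min(a, len(coefs) - 1)] if coefs else None
            y_loo[i, a] = fold_mean if B is None else float(xi @ B) + fold_mean

    press = np.sum((y[:, None] - y_loo) ** 2, axis=0)
    q2 = 1.0 - press / ss_tot
    n_comp = np.arange(1, n_max + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sep = np.where(n - n_comp - 1 > 0,
                       np.sqrt(press / np.maximum(n - n_comp - 1, 1)), np.nan)
    # argmax with ties broken toward the smallest N
    n_opt = int(np.argmax(np.round(q2, 12))) + 1
    return LOOResult(q2=q2, sep=sep, press=press, n_opt=n_opt, y_loo=y_loo)


def field_contributions(coef: np.ndarray, sigma: np.ndarray,
                        column_field: np.ndarray) -> dict[str, float]:
    """Fractional contribution per field: Σ|coef_j|·σ_j within the field,
    normalised across fields to sum to 1."""
    coef = np.asarray(coef, float)
    sigma = np.asarray(sigma, float)
    column_field = np.asarray(column_field)
    kinds = [k for k in FIELD_KINDS if k in set(column_field.tolist())]
    mass = {k: float(np.sum(np.abs(coef[column_field == k]) * sigma[column_field == k]))
            for k in kinds}
    total = sum(mass.values())
    if total <= 0:
        warnings.warn("zero coefficient mass; reporting uniform field contributions",
                      stacklevel=2)
        return {k: 1.0 / len(kinds) for k in kinds}
    return {k: v / total for k, v in mass.items()}


def _combo_blocks(blocks: Mapping[str, FieldBlock | np.ndarray], combo: Sequence[str]):
    """Concatenate blocks for a combo; returns (X, column_field, column_index)."""
    parts, labels, indices = [], [], []
    for k in combo:
        b = blocks[k]
        Xb = b.X if isinstance(b, FieldBlock) else np.asarray(b, float)
        parts.append(Xb)
        labels.append(np.full(Xb.shape[1], k, dtype=object))
        indices.append(np.arange(Xb.shape[1]))
    return np.hstack(parts), np.concatenate(labels), np.concatenate(indices)


def fit_combo(blocks: Mapping[str, FieldBlock | np.ndarray], y: np.ndarray,
              combo: Sequence[str], n_max: int = 10,
              filter_threshold: float = 2.0, filter_mode: str = "range",
              block_scale: bool = False):
    """LOO-select N and fit the final model for one field combination.

    Returns ``(row_dict, model)``; the row carries the scan-table statistics,
    the model the per-column metadata the contour module consumes.  When the
    column filter removes every column the row holds NaNs and model is None.
    The returned model always acts on original (unscaled) columns, whatever
    ``block_scale`` says.
    """
    y = np.asarray(y, dtype=float)
    X, col_field, col_index = _combo_blocks(blocks, combo)
    name = "".join(combo)
    loo = loo_q2(X, y, n_max=n_max, filter_threshold=filter_threshold,
                 filter_mode=filter_mode, column_field=col_field,
                 block_scale=block_scale)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mask = column_filter(X, filter_threshold, filter_mode)
    row = {"model": name, "q2": loo.q2_opt, "N": loo.n_opt, "SEP": loo.sep_opt,
           "SEE": np.nan, "r2": np.nan, "F": np.nan}
    row.update({f"contrib_{k}": np.nan for k in FIELD_KINDS})
    if not mask.any():
        logger.warning("combo %s: column filter removed every column", name)
        row.update({"q2": np.nan, "N": 0, "SEP": np.nan})
        return row, None
    Xm = X[:, mask]
    scales = _block_scales(Xm, col_field[mask]) if block_scale else np.ones(Xm.shape[1])
    model = pls_fit(Xm / scales, y, loo.n_opt)
    # fold the scaling into the model so it predicts from raw columns
    model.coef = model.coef / scales
    model.x_mean = model.x_mean * scales
    model.x_sigma = model.x_sigma * scales
    model.column_field = col_field[mask]
    model.column_grid_index = col_index[mask]
    row["N"] = model.n_components
    row["SEE"], row["r2"], row["F"] = model.see, model.r2, model.f_stat
    for k, frac in field_contributions(model.coef, model.x_sigma, model.column_field).items():
        row[f"contrib_{k}"] = frac
    return row, model


def field_scan(blocks: Mapping[str, FieldBlock | np.ndarray], y: np.ndarray,
               n_max: int = 10, filter_threshold: float = 2.0,
               filter_mode: str = "range", block_scale: bool = False):
    """Exhaustive scan over all non-empty field combinations.

    With all five fields available this is the 2⁵−1 = 31-model sequential
    search; rows are ranked by q² descending (NaN last).  Returns
    ``(scan_table, models)`` with models keyed by combo string.
    """
    kinds = [k for k in FIELD_KINDS if k in blocks]
    if not kinds:
        raise PLSError("field_scan needs at least one field block")
    rows, models = [], {}
    for r in range(1, len(kinds) + 1):
        for combo in itertools.combinations(kinds, r):
            row, model = fit_combo(blocks, y, combo, n_max=n_max,
                                   filter_threshold=filter_threshold,
                                   filter_mode=filter_mode,
                                   block_scale=block_scale)
            rows.append(row)
            models[row["model"]] = model
    table = pd.DataFrame(rows)
    table = table.sort_values("q2", ascending=False, na_position="last",
                              kind="mergesort").reset_index(drop=True)
    return table, models
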