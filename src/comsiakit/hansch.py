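"""Classical 2D-QSAR: Hansch/Free-Wilson multilinear regression.

Activity is regressed on physicochemical substituent descriptors: calculated
molar refractivity (CMR), a binary Free-Wilson indicator S for the presence
of the left-hand-side sulfonamide fragment, and hydrophobic substituent
constants πx (substituent at position 7 of the indole ring) and πy
(substituent on the LHS benzene ring).  Squared monomials are built here
from the base descriptors so callers can never supply inconsistent
CMR/CMR² pairs.

The published best equation for the beta3-agonist series,

    pEC50 = 0.057·CMR² − 1.65·CMR + 2.37·S + 0.072·πx² + 0.098·πy² + 18.56,

ships as a frozen model object: its descriptor table was never published, so
the equation is evaluable but deliberately not refittable.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASE_DESCRIPTORS = ("CMR", "S", "pi_x", "pi_y")

#: monomial name -> (base column, power)
TERM_DEFS: dict[str, tuple[str, int]] = {
    "CMR": ("CMR", 1),
    "CMR^2": ("CMR", 2),
    "S": ("S", 1),
    "pi_x": ("pi_x", 1),
    "pi_x^2": ("pi_x", 2),
    "pi_y": ("pi_y", 1),
    "pi_y^2": ("pi_y", 2),
}


class HanschError(ValueError):
    pass


def build_design(descriptors: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    """Design matrix (without intercept) of named monomials from base columns."""
    cols = []
    for t in terms:
        if t not in TERM_DEFS:
            raise HanschError(f"unknown term {t!r}; known: {sorted(TERM_DEFS)}")
        base, power = TERM_DEFS[t]
        if base not in descriptors.columns:
            raise HanschError(f"descriptor table lacks column {base!r}")
        cols.append(descriptors[base].to_numpy(dtype=float) ** power)
    X = np.column_stack(cols) if cols else np.empty((len(descriptors), 0))
    if not np.all(np.isfinite(X)):
        raise HanschError("non-finite descriptor values")
    return X


@dataclass(frozen=True)
class HanschModel:
    """Fitted (or frozen) multilinear descriptor model.

    ``coef`` is ordered like ``terms``; ``intercept`` is separate.  Fit
    statistics are None on frozen models that were never fit to data here.
    """

    terms: tuple[str, ...]
    coef: np.ndarray
    intercept: float
    coef_se: np.ndarray | None = None
    intercept_se: float | None = None
    n: int | None = None
    r2: float | None = None
    f_stat: float | None = None
    s: float | None = None
    q2: float | None = None
    sep: float | None = None

    def predict(self, descriptors: pd.DataFrame) -> np.ndarray:
        X = build_design(descriptors, self.terms)
        return X @ self.coef + self.intercept

    def summary(self) -> str:
        parts = [f"{c:+.3g}*{t}" for c, t in zip(self.coef, self.terms)]
        eq = " ".join(parts) + f" {self.intercept:+.4g}"
        stats = ""
        if self.r2 is not None:
            stats = (f"\nn={self.n}, r2={self.r2:.4f}, F={self.f_stat:.2f}, "
                     f"s={self.s:.3f}, q2={self.q2:.4f}, SEP={self.sep:.3f}")
        return f"pEC50 = {eq}{stats}"


#: frozen published equation: coefficient (standard error) per monomial
EQ1_TERMS = ("CMR^2", "CMR", "S", "pi_x^2", "pi_y^2")
EQ1 = HanschModel(
    terms=EQ1_TERMS,
    coef=np.array([0.057, -1.65, 2.37, 0.072, 0.098]),
    intercept=18.56,
    coef_se=np.array([0.013, 0.38, 0.25, 0.049, 0.024]),
)


def eq1_predict(descriptors) -> np.ndarray | float:
    """Evaluate the frozen published equation.

    Accepts a DataFrame with columns CMR, S, pi_x, pi_y, or a mapping of
    scalars; returns predicted pEC50 (scalar for scalar input).
    """
    if isinstance(descriptors, Mapping):
        df = pd.DataFrame([descriptors])
        return float(EQ1.predict(df)[0])
    return EQ1.predict(descriptors)


def _check_singular(X1: np.ndarray, terms: Sequence[str]) -> None:
    # name the offending monomials from the smallest right-singular vector
    _, s, vt = np.linalg.svd(X1, full_matrices=False)
    if s[-1] <= 1e-10 * s[0]:
        null = np.abs(vt[-1])
        names = ["intercept"] + list(terms)
        bad = [names[i] for i in np.where(null > 0.1 * null.max())[0]]
        raise HanschError(f"singular design: collinear terms {bad}")


def mlr_fit(descriptors: pd.DataFrame, y, terms: Sequence[str]) -> HanschModel:
    """Ordinary least squares with intercept on named monomials.

    Reports r², F, residual standard error s, per-coefficient standard
    errors, and exact leave-one-out q²/SEP (each fold refit from scratch).
    """
    y = np.asarray(y, dtype=float)
    X = build_design(descriptors, terms)
    n, k = X.shape
    if n <= k + 1:
        raise HanschError(f"n={n} rows cannot support {k} terms plus intercept")
    X1 = np.column_stack([np.ones(n), X])
    _check_singular(X1, terms)
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    fitted = X1 @ beta
    resid = y - fitted
    dof = n - k - 1
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    rss = float(resid @ resid)
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else 0.0
    s = float(np.sqrt(rss / dof))
    f_stat = float("inf") if rss <= 1e-12 * max(ss_tot, 1.0) else \
        (r2 * dof) / ((1.0 - r2) * k) if k > 0 else float("nan")
    cov = np.linalg.inv(X1.T @ X1) * (rss / dof)
    se = np.sqrt(np.diag(cov))

    # exact LOO
    press = 0.0
    y_loo = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        b, *_ = np.linalg.lstsq(X1[keep], y[keep], rcond=None)
        y_loo[i] = X1[i] @ b
    press = float(np.sum((y - y_loo) ** 2))
    q2 = 1.0 - press / ss_tot if ss_tot > 0 else float("nan")
    sep = float(np.sqrt(press / dof))
    return HanschModel(terms=tuple(terms), coef=beta[1:], intercept=float(beta[0]),
                       coef_se=se[1:], intercept_se=float(se[0]), n=n, r2=r2,
                       f_stat=f_stat, s=s, q2=q2, sep=sep)


def exhaustive_subset_search(descriptors: pd.DataFrame, y, pool: Sequence[str],
                             max_terms: int | None = None) -> list[HanschModel]:
    """Fit every descriptor subset of size ≤ max_terms; rank by q², then size.

    A pool larger than 20 terms is refused (2²⁰ fits is past the desk-scale
    guard).  Models with fewer than 5 observations per term draw an
    overfitting warning, following the usual rule of thumb.
    """
    pool = list(pool)
    if len(pool) > 20:
        raise HanschError(
            f"candidate pool of {len(pool)} terms is too large for exhaustive "
            "search; prune it below 21 terms or search hierarchically")
    if max_terms is None:
        max_terms = len(pool)
    y = np.asarray(y, dtype=float)
    models: list[HanschModel] = []
    for r in range(1, max_terms + 1):
        for combo in itertools.combinations(pool, r):
            try:
                models.append(mlr_fit(descriptors, y, combo))
            except HanschError:
                logger.debug("subset %s skipped (singular or too large)", combo)
    if not models:
        raise HanschError("no fittable subset in the pool")
    models.sort(key=lambda m: (-m.q2, len(m.terms)))
    best = models[0]
    if best.n / max(len(best.terms), 1) < 5:
        warnings.warn(
            f"best model uses {len(best.terms)} terms for {best.n} compounds "
            "(< 5 observations per term): overfitting risk", stacklevel=2)
    return models


def search_table(models: Sequence[HanschModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {"terms": ["+".join(m.terms) for m in models],
         "n_terms": [len(m.terms) for m in models],
         "q2": [m.q2 for m in models],
         "r2": [m.r2 for m in models],
         "s": [m.s for m in models],
         "F": [m.f_stat for m in models]})


def prediction_report(ids: Sequence[str], y_actual, y_pred) -> pd.DataFrame:
    """Per-compound actual/predicted/residual table (report layout)."""
    y_actual = np.asarray(y_actual, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return pd.DataFrame({"id": list(ids), "actual": y_actual,
                         "predicted": y_pred, "residual": y_actual - y_pred})
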