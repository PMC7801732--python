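"""Stability, Bootstrap P values, the combined model, threshold and error rates.

A bootstrap coefficient matrix (from one method, or several methods stacked
row-wise into the *combined model*) is summarised per covariate:

* selection stability — the percentage of rows in which the covariate has a
  nonzero coefficient;
* Bootstrap P value — among the nonzero coefficient values only, the smaller
  of the two sign-side proportions (0 = perfectly sign-consistent, 0.5 =
  direction a coin flip; undefined when never selected);
* coefficient distribution — median and 2.5/97.5 empirical percentiles of
  the nonzero values.

Covariates are ranked by descending stability and a change point in the
ranked profile (the scree-plot elbow) is detected from a rolling mean of the
consecutive stability drops: the covariates above the point where the
smoothed drop rate falls back to <= 1 percentage point per rank are deemed
important.  When the ground-truth support is known the selection is scored
with false positive / false negative error rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap import BootstrapMatrix
from .selectors import ZERO_TOL

__all__ = [
    "CombinedMatrix",
    "StabilityReport",
    "ErrorRates",
    "selection_stability",
    "bootstrap_p",
    "combine_matrices",
    "coefficient_summary",
    "stability_change_threshold",
    "error_rates",
    "make_report",
]


@dataclass
class CombinedMatrix:
    """Row-wise stack of equal-B bootstrap matrices from several methods."""

    coefficients: np.ndarray
    method_of_row: np.ndarray
    covariate_names: list[str]
    method = "combined"

    @property
    def B(self) -> int:
        return self.coefficients.shape[0]

    @property
    def p(self) -> int:
        return self.coefficients.shape[1]


def _coef_array(m) -> np.ndarray:
    if isinstance(m, (BootstrapMatrix, CombinedMatrix)):
        return m.coefficients
    return np.atleast_2d(np.asarray(m, dtype=float))


def combine_matrices(ms: list[BootstrapMatrix]) -> CombinedMatrix:
    """Stack matrices row-wise; refuses unequal B or misaligned covariates.

    Equal replicate counts give every method equal weight in all combined
    statistics; misalignment is an error, never silently reweighted.
    """
    if len(ms) < 2:
        raise ValueError("need at least two matrices to combine")
    B = ms[0].B
    names = list(ms[0].covariate_names)
    for m in ms[1:]:
        if m.B != B:
            raise ValueError(f"unequal replicate counts: {m.B} != {B}")
        if list(m.covariate_names) != names:
            raise ValueError("covariate names/order differ between matrices")
    coef = np.vstack([m.coefficients for m in ms])
    labels = np.concatenate([np.repeat(m.method, m.B) for m in ms])
    return CombinedMatrix(coefficients=coef, method_of_row=labels, covariate_names=names)


def selection_stability(m) -> np.ndarray:
    """Per-covariate selection percentage: 100 x (nonzero rows) / rows."""
    coef = _coef_array(m)
    return 100.0 * (np.abs(coef) > ZERO_TOL).mean(axis=0)


def bootstrap_p(m) -> np.ndarray:
    """Smallest sign-side proportion among nonzero values; NaN when never selected."""
    coef = _coef_array(m)
    nonzero = np.abs(coef) > ZERO_TOL
    n_nonzero = nonzero.sum(axis=0)
    n_pos = ((coef > 0) & nonzero).sum(axis=0)
    n_neg = n_nonzero - n_pos
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.minimum(n_pos, n_neg) / n_nonzero
    return np.where(n_nonzero > 0, p, np.nan)


def coefficient_summary(m, level: float = 0.95) -> pd.DataFrame:
    """Median and percentile interval of the nonzero values, per covariate."""
    coef = _coef_array(m)
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    masked = np.where(np.abs(coef) > ZERO_TOL, coef, np.nan)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        med = np.nanmedian(masked, axis=0)
        lo = np.nanpercentile(masked, lo_q, axis=0)
        hi = np.nanpercentile(masked, hi_q, axis=0)
    names = getattr(m, "covariate_names", None) or [f"V{j+1}" for j in range(coef.shape[1])]
    return pd.DataFrame(
        {"median": med, "lo": lo, "hi": hi}, index=pd.Index(names, name="covariate")
    )


def stability_change_threshold(stability, window: int = 15) -> int | None:
    """Change-point rank in the descending stability profile.

    The stabilities are sorted descending; the drop between consecutive
    ranks, d_r = s_(r) - s_(r+1) (percentage points per rank), is smoothed
    with a rolling mean over ``window`` consecutive values looking down the
    ranking from rank r.  Once the smoothed rate has exceeded 1 and then
    falls back to <= 1, the ranks before that point are deemed important.

    Returns the rank of the last important covariate (so ranks
    1..threshold are selected), or None when the smoothed rate never
    exceeds 1 (flat profile: no demarcation, select nothing).
    """
    s = np.sort(np.asarray(stability, dtype=float))[::-1]
    p = s.size
    if p <= window:
        raise ValueError(f"need more covariates than the window ({p} <= {window})")
    d = s[:-1] - s[1:]
    # means[r-1] = mean(d_r .. d_{r+window-1}), full windows only
    kernel = np.ones(window) / window
    means = np.convolve(d, kernel, mode="valid")
    above = means > 1.0
    if not above.any():
        return None
    r0 = int(np.argmax(above))
    after = np.flatnonzero(~above[r0:])
    if after.size == 0:
        return None
    return int(r0 + after[0])  # 1-based rank of last important covariate


@dataclass
class ErrorRates:
    """Selection errors against a known true support."""

    fp_count: int
    fn_count: int
    fper: float
    fner: float | None

    def to_dict(self) -> dict:
        return {
            "fp_count": self.fp_count,
            "fn_count": self.fn_count,
            "fper": self.fper,
            "fner": self.fner,
        }


def error_rates(selected, true_support, p: int) -> ErrorRates:
    """FPER = FP / (true negatives in data); FNER = FN / (true positives)."""
    selected = set(int(i) for i in np.asarray(selected, dtype=int).ravel())
    truth = set(int(i) for i in np.asarray(true_support, dtype=int).ravel())
    if any(i < 0 or i >= p for i in selected | truth):
        raise ValueError("indices out of range")
    fp = len(selected - truth)
    fn = len(truth - selected)
    n_neg = p - len(truth)
    fper = fp / n_neg if n_neg else 0.0
    fner = fn / len(truth) if truth else None
    return ErrorRates(fp_count=fp, fn_count=fn, fper=fper, fner=fner)


@dataclass
class StabilityReport:
    """Per-covariate stability statistics plus the threshold-based selection.

    ``ranking`` is a permutation of covariate indices by descending
    stability (ties broken by ascending Bootstrap P, descending absolute
    median coefficient, then name, so rankings are deterministic);
    ``threshold_rank`` the rank of the last covariate deemed important
    (None when no demarcation); ``selected`` the covariate indices at ranks
    above the change point.
    """

    covariate_names: list[str]
    stability: np.ndarray
    bootstrap_p: np.ndarray
    coef_median: np.ndarray
    coef_lo95: np.ndarray
    coef_hi95: np.ndarray
    ranking: np.ndarray
    threshold_rank: int | None
    selected: np.ndarray
    method: str = "combined"
    window: int = 15
    errors: ErrorRates | None = None

    @property
    def p(self) -> int:
        return len(self.covariate_names)

    def to_frame(self) -> pd.DataFrame:
        rank = np.empty(self.p, dtype=int)
        rank[self.ranking] = np.arange(1, self.p + 1)
        sel = np.zeros(self.p, dtype=bool)
        sel[self.selected] = True
        return pd.DataFrame(
            {
                "covariate": self.covariate_names,
                "stability": self.stability,
                "bootstrap_p": self.bootstrap_p,
                "median": self.coef_median,
                "lo95": self.coef_lo95,
                "hi95": self.coef_hi95,
                "rank": rank,
                "selected": sel,
            }
        ).set_index("covariate")

    def summary(self) -> dict:
        out = {
            "method": self.method,
            "window": self.window,
            "threshold_rank": self.threshold_rank,
            "n_selected": int(self.selected.size),
            "selected": [self.covariate_names[i] for i in self.selected],
            "max_stability": float(self.stability.max()) if self.p else None,
        }
        if self.errors is not None:
            out["errors"] = self.errors.to_dict()
        return out

    def save(self, csv_path, json_path=None) -> None:
        self.to_frame().to_csv(csv_path)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.summary(), indent=1))


def _rank_covariates(stability, bp, median, names) -> np.ndarray:
    """Deterministic ranking: stability desc, bootstrap_p asc, |median| desc, name."""
    bp_key = np.where(np.isnan(bp), np.inf, bp)
    med_key = np.where(np.isnan(median), 0.0, np.abs(median))
    order = sorted(
        range(len(names)),
        key=lambda j: (-stability[j], bp_key[j], -med_key[j], names[j]),
    )
    return np.asarray(order, dtype=int)


def make_report(
    m,
    window: int = 15,
    true_support=None,
    level: float = 0.95,
) -> StabilityReport:
    """Full per-covariate report for one bootstrap (or combined) matrix."""
    names = list(getattr(m, "covariate_names", [])) or [
        f"V{j+1}" for j in range(_coef_array(m).shape[1])
    ]
    stab = selection_stability(m)
    bp = bootstrap_p(m)
    summ = coefficient_summary(m, level=level)
    ranking = _rank_covariates(stab, bp, summ["median"].to_numpy(), names)
    thr = stability_change_threshold(stab, window=window)
    selected = ranking[:thr] if thr else np.array([], dtype=int)
    errors = None
    if true_support is not None:
        errors = error_rates(selected, true_support, p=len(names))
    return StabilityReport(
        covariate_names=names,
        stability=stab,
        bootstrap_p=bp,
        coef_median=summ["median"].to_numpy(),
        coef_lo95=summ["lo"].to_numpy(),
        coef_hi95=summ["hi"].to_numpy(),
        ranking=ranking,
        threshold_rank=thr,
        selected=selected,
        method=getattr(m, "method", "matrix"),
        window=window,
        errors=errors,
    )
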