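"""Nonparametric bootstrap of any selector.

Each replicate resamples the n observations with replacement (rows of X and
y kept paired), refits the selection method — by default re-tuning its
hyperparameters inside the replicate — and stores the resulting full-length
coefficient vector as one row of a B x p matrix.  Replicate sub-seeds are
derived from (master seed, method label, replicate index) with a counter
-based scheme, so rows are independent of execution order and worker count.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .selectors import CvSpec, fit_selector

__all__ = ["BootstrapMatrix", "draw_bootstrap_sample", "run_bootstrap", "replicate_seed"]

logger = logging.getLogger(__name__)


@dataclass
class BootstrapMatrix:
    """B x p coefficient matrix for one method (zeros where unselected)."""

    coefficients: np.ndarray
    method: str
    covariate_names: list[str]
    seed: int | None = None

    def __post_init__(self):
        self.coefficients = np.atleast_2d(np.asarray(self.coefficients, dtype=float))
        if self.coefficients.shape[1] != len(self.covariate_names):
            raise ValueError("coefficient columns and covariate_names disagree")

    @property
    def B(self) -> int:
        return self.coefficients.shape[0]

    @property
    def p(self) -> int:
        return self.coefficients.shape[1]

    def save(self, path) -> None:
        """Delimited text (one row per replicate) plus a JSON metadata sidecar."""
        path = Path(path)
        pd.DataFrame(self.coefficients, columns=self.covariate_names).to_csv(path, index=False)
        meta = {"method": self.method, "B": self.B, "seed": self.seed}
        path.with_name(path.stem + ".meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "BootstrapMatrix":
        path = Path(path)
        df = pd.read_csv(path)
        metafile = path.with_name(path.stem + ".meta.json")
        meta = json.loads(metafile.read_text()) if metafile.exists() else {}
        return cls(
            coefficients=df.to_numpy(dtype=float),
            method=meta.get("method", path.stem),
            covariate_names=list(df.columns),
            seed=meta.get("seed"),
        )


def draw_bootstrap_sample(X, y, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample n rows with replacement; X and y rows stay paired.

    Returns (X_boot, y_boot, indices)."""
    X = np.asarray(X)
    y = np.asarray(y)
    if X.shape[0] < 1:
        raise ValueError("need at least one observation")
    rng = np.random.default_rng(rng)
    idx = rng.integers(0, X.shape[0], size=X.shape[0])
    return X[idx], y[idx], idx


def replicate_seed(seed: int, method: str, b: int, attempt: int = 0) -> np.random.SeedSequence:
    """Splittable counter-based sub-seed for replicate b of one method."""
    return np.random.SeedSequence(
        entropy=(int(seed), zlib.crc32(method.encode()), int(b), int(attempt))
    )


def _one_replicate(method, X, y, seed, b, cv, retune, fixed_hyperparams, max_retries):
    for attempt in range(max_retries + 1):
        ss = replicate_seed(seed, method, b, attempt)
        rng = np.random.default_rng(ss)
        Xb, yb, _ = draw_bootstrap_sample(X, y, rng)
        cv_b = cv
        if cv is not None:
            sub = int(rng.integers(2**31))
            if retune:
                cv_b = dataclasses.replace(cv, seed=sub)
            else:
                grids = dict(cv.grids or {})
                grids.update(fixed_hyperparams or {})
                cv_b = dataclasses.replace(cv, seed=sub, grids=grids)
        try:
            res = fit_selector(method, Xb, yb, cv_b)
            return res.coefficients
        except Exception:  # noqa: BLE001 - any selector failure triggers a retry
            logger.warning("replicate %d of %s failed (attempt %d)", b, method, attempt, exc_info=True)
    logger.warning("replicate %d of %s failed after retries; recording an all-zero row", b, method)
    return np.zeros(X.shape[1])


def run_bootstrap(
    method: str,
    X,
    y,
    B: int,
    seed: int = 0,
    cv: CvSpec | None = None,
    covariate_names: list[str] | None = None,
    fixed_hyperparams: dict | None = None,
    n_jobs: int = 1,
    max_retries: int = 2,
) -> BootstrapMatrix:
    """Bootstrap one selector B times and stack the coefficient vectors.

    By default hyperparameters are re-tuned by CV inside every replicate so
    stability reflects the whole selection pipeline; pass
    ``fixed_hyperparams`` (e.g. ``{"lambdas": [0.3], "alpha": [0.5]}``) to
    pin the grids instead.  A replicate whose fit raises is retried with a
    fresh sub-seed up to ``max_retries`` times, then recorded as an all-zero
    row with a logged warning — never silently dropped.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    retune = fixed_hyperparams is None
    rows = Parallel(n_jobs=n_jobs)(
        delayed(_one_replicate)(
            method, X, y, seed, b, cv, retune, fixed_hyperparams, max_retries
        )
        for b in range(B)
    )
    names = covariate_names or [f"V{j + 1}" for j in range(X.shape[1])]
    return BootstrapMatrix(
        coefficients=np.vstack(rows), method=method, covariate_names=list(names), seed=seed
    )
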