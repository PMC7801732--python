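"""Simulated high-dimensional regression datasets with a known sparse signal.

The generator reproduces a family of benchmark datasets used to compare
variable-selection methods: a continuous outcome driven by ten "true"
standardized covariates (five of them mutually correlated, five independent)
buried among hundreds to thousands of standardized noise covariates, part of
which are organised in correlated blocks to mimic the correlation structure
of real epidemiological data.  Null variants draw the outcome independently
of every covariate.

All covariates are simulated with population mean 0 and SD 1, i.e. they are
standardized by construction and are used as simulated (no empirical
re-standardization).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "TrueModelSpec",
    "CorrelatedGroup",
    "NoiseBlockSpec",
    "SimulatedDataset",
    "TrueModelFit",
    "DATASET12_NOISE",
    "DATASET34_NOISE",
    "simulate_true_block",
    "simulate_outcome",
    "simulate_noise_block",
    "build_dataset",
    "fit_true_model",
    "dataset_names",
]

# The true block always holds 4 + 1 correlated and 5 independent covariates.
N_CORR_MAJOR = 4
N_CORR_MINOR = 1
N_UNCORR = 5
N_TRUE = N_CORR_MAJOR + N_CORR_MINOR + N_UNCORR


@dataclass(frozen=True)
class TrueModelSpec:
    """Generating model for the outcome.

    y_i = intercept + coef_correlated_major * (x1 + x2 + x3 + x4)
          + coef_correlated_minor * x5
          + coef_uncorrelated * (x6 + ... + x10) + v_i,   v_i ~ N(0, noise_sd^2)

    where x1..x5 are multivariate normal with unit variances and exchangeable
    pairwise correlation ``true_corr`` and x6..x10 are iid standard normal.
    noise_sd = 15, 6.5 and 23 give the weak-, strong- and very-weak-signal
    benchmark variants respectively.
    """

    intercept: float = 1.0
    coef_correlated_major: float = 2.5
    coef_correlated_minor: float = 1.0
    coef_uncorrelated: float = 2.5
    noise_sd: float = 15.0
    true_corr: float = 0.6

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not (0.0 <= self.true_corr < 1.0):
            raise ValueError(f"true_corr must be in [0, 1), got {self.true_corr}")

    @property
    def coefficients(self) -> np.ndarray:
        """Length-10 generating coefficient vector (2.5 x4, 1, 2.5 x5 at defaults)."""
        return np.array(
            [self.coef_correlated_major] * N_CORR_MAJOR
            + [self.coef_correlated_minor] * N_CORR_MINOR
            + [self.coef_uncorrelated] * N_UNCORR
        )

    def correlation_matrix(self) -> np.ndarray:
        """10 x 10 population correlation matrix of the true block."""
        sigma = np.eye(N_TRUE)
        k = N_CORR_MAJOR + N_CORR_MINOR
        sigma[:k, :k] = _exchangeable(k, self.true_corr)
        return sigma

    def signal_variance(self) -> float:
        """Analytic variance c' Sigma c of the linear predictor (no noise)."""
        c = self.coefficients
        return float(c @ self.correlation_matrix() @ c)

    def r_squared(self) -> float:
        """Analytic population R^2 of the generating model."""
        s = self.signal_variance()
        return s / (s + self.noise_sd**2)


@dataclass(frozen=True)
class CorrelatedGroup:
    """A group of mutually independent MVN blocks sharing one within-block correlation."""

    n_blocks: int
    block_size: int
    within_corr: float

    def __post_init__(self) -> None:
        if self.n_blocks < 0 or self.block_size <= 0:
            raise ValueError("n_blocks must be >= 0 and block_size > 0")
        if not (0.0 <= self.within_corr < 1.0):
            raise ValueError(f"within_corr must be in [0, 1), got {self.within_corr}")

    @property
    def n_total(self) -> int:
        return self.n_blocks * self.block_size


@dataclass(frozen=True)
class NoiseBlockSpec:
    """Structure of the noise covariates: correlated blocks plus an iid remainder."""

    groups: tuple[CorrelatedGroup, ...] = ()
    n_iid: int = 0

    def __post_init__(self) -> None:
        if self.n_iid < 0:
            raise ValueError("n_iid must be >= 0")
        if self.n_total <= 0:
            raise ValueError("noise spec describes zero covariates")

    @property
    def n_total(self) -> int:
        return sum(g.n_total for g in self.groups) + self.n_iid


#: 4 blocks of 50 at 0.7, 4 blocks of 50 at 0.8, 500 iid -> 900 noise covariates.
DATASET12_NOISE = NoiseBlockSpec(
    (CorrelatedGroup(4, 50, 0.7), CorrelatedGroup(4, 50, 0.8)), 500
)
#: 40 blocks of 50 at 0.7, 40 blocks of 50 at 0.8, 6000 iid -> 10,000 noise covariates.
DATASET34_NOISE = NoiseBlockSpec(
    (CorrelatedGroup(40, 50, 0.7), CorrelatedGroup(40, 50, 0.8)), 6000
)


def _exchangeable(size: int, rho: float) -> np.ndarray:
    return np.full((size, size), rho) + (1.0 - rho) * np.eye(size)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _mvn_block(rng: np.random.Generator, n: int, size: int, rho: float) -> np.ndarray:
    """n x size draw from MVN(0, exchangeable corr) via Cholesky."""
    z = rng.standard_normal((n, size))
    if rho == 0.0 or size == 1:
        return z
    chol = np.linalg.cholesky(_exchangeable(size, rho))
    return z @ chol.T


def simulate_true_block(n: int, spec: TrueModelSpec | None = None, seed=0) -> np.ndarray:
    """Draw the n x 10 matrix of true covariates.

    Columns 1-5 are MVN with unit variances and pairwise correlation
    ``spec.true_corr``; columns 6-10 are iid standard normal.  Deterministic
    given ``seed`` (an int or :class:`numpy.random.SeedSequence`).
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    spec = spec or TrueModelSpec()
    rng = _rng(seed)
    k = N_CORR_MAJOR + N_CORR_MINOR
    corr = _mvn_block(rng, n, k, spec.true_corr)
    indep = rng.standard_normal((n, N_UNCORR))
    return np.hstack([corr, indep])


def simulate_outcome(true_block: np.ndarray, spec: TrueModelSpec | None = None, seed=0) -> np.ndarray:
    """Compute y = intercept + X c + v with v ~ N(0, noise_sd^2), seeded."""
    spec = spec or TrueModelSpec()
    true_block = np.asarray(true_block, dtype=float)
    if true_block.ndim != 2 or true_block.shape[1] != N_TRUE:
        raise ValueError(
            f"true_block must have exactly {N_TRUE} columns, got shape {true_block.shape}"
        )
    rng = _rng(seed)
    signal = spec.intercept + true_block @ spec.coefficients
    if spec.noise_sd == 0:
        return signal
    return signal + rng.normal(0.0, spec.noise_sd, size=true_block.shape[0])


def simulate_noise_block(n: int, spec: NoiseBlockSpec, seed=0) -> np.ndarray:
    """Draw the n x m noise matrix: correlated blocks then iid columns.

    Blocks are mutually independent; nothing depends on any outcome.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    rng = _rng(seed)
    parts = []
    for group in spec.groups:
        for _ in range(group.n_blocks):
            parts.append(_mvn_block(rng, n, group.block_size, group.within_corr))
    if spec.n_iid:
        parts.append(rng.standard_normal((n, spec.n_iid)))
    return np.hstack(parts)


@dataclass
class SimulatedDataset:
    """A simulated design matrix, outcome, and the generating ground truth."""

    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    true_support: np.ndarray  # integer column indices; empty for null datasets
    spec: TrueModelSpec | None
    noise_spec: NoiseBlockSpec | None
    seed: int | None
    name: str | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Outcome in the first column (``y_out``), covariates after it."""
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, "y_out", self.y)
        return df

    def to_csv(self, path) -> None:
        """Write the data as delimited text plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {
            "name": self.name,
            "seed": self.seed,
            "true_support": [int(i) for i in self.true_support],
            "spec": dataclasses.asdict(self.spec) if self.spec else None,
            "noise_spec": dataclasses.asdict(self.noise_spec) if self.noise_spec else None,
        }
        sidecar(path).write_text(json.dumps(meta, indent=1))

    @classmethod
    def read_csv(cls, path) -> "SimulatedDataset":
        path = Path(path)
        df = pd.read_csv(path)
        meta = {}
        if sidecar(path).exists():
            meta = json.loads(sidecar(path).read_text())
        spec = TrueModelSpec(**meta["spec"]) if meta.get("spec") else None
        noise = None
        if meta.get("noise_spec"):
            ns = meta["noise_spec"]
            noise = NoiseBlockSpec(
                tuple(CorrelatedGroup(**g) for g in ns["groups"]), ns["n_iid"]
            )
        return cls(
            X=df.iloc[:, 1:].to_numpy(dtype=float),
            y=df.iloc[:, 0].to_numpy(dtype=float),
            columns=list(df.columns[1:]),
            true_support=np.array(meta.get("true_support", []), dtype=int),
            spec=spec,
            noise_spec=noise,
            seed=meta.get("seed"),
            name=meta.get("name"),
        )


def sidecar(path) -> Path:
    """Path of the JSON metadata file accompanying a dataset CSV."""
    path = Path(path)
    return path.with_name(path.stem + ".meta.json")


def _noise_names(m: int) -> list[str]:
    width = len(str(m))
    return [f"N{i + 1:0{width}d}" for i in range(m)]


#: Preset (n, noise structure, generating spec, null?) per benchmark dataset.
_PRESETS: dict[int, dict] = {
    1: dict(n=1000, noise=DATASET12_NOISE, spec=TrueModelSpec(noise_sd=15.0), null=False),
    2: dict(n=1000, noise=DATASET12_NOISE, spec=TrueModelSpec(noise_sd=6.5), null=False),
    3: dict(n=200, noise=DATASET34_NOISE, spec=TrueModelSpec(noise_sd=6.5), null=False),
    4: dict(n=200, noise=DATASET34_NOISE, spec=TrueModelSpec(noise_sd=23.0), null=False),
    5: dict(n=1000, noise=DATASET12_NOISE, spec=TrueModelSpec(noise_sd=15.0), null=True),
    6: dict(n=200, noise=DATASET34_NOISE, spec=TrueModelSpec(noise_sd=23.0), null=True),
}


def dataset_names() -> list[int]:
    return sorted(_PRESETS)


def build_dataset(
    name: int | None = None,
    seed: int = 0,
    *,
    n: int | None = None,
    spec: TrueModelSpec | None = None,
    noise_spec: NoiseBlockSpec | None = None,
    null: bool | None = None,
) -> SimulatedDataset:
    """Assemble a full simulated dataset.

    ``name`` selects one of the six presets (1-4 signal, 5-6 null); any of
    ``n``/``spec``/``noise_spec``/``null`` overrides the preset (or defines a
    fully custom dataset when ``name`` is omitted).  For null datasets the
    covariate matrix keeps the same structure (including the would-be true
    block) but y is drawn iid standard normal, independent of X, and the true
    support is empty.

    The master seed is split into independent sub-seeds for the true block,
    the noise block and the outcome, so each component is reproducible on its
    own.
    """
    if name is not None:
        if name not in _PRESETS:
            raise ValueError(f"unknown dataset name {name!r}; known: {dataset_names()}")
        preset = _PRESETS[name]
        n = preset["n"] if n is None else n
        spec = preset["spec"] if spec is None else spec
        noise_spec = preset["noise"] if noise_spec is None else noise_spec
        null = preset["null"] if null is None else null
    else:
        if n is None or noise_spec is None:
            raise ValueError("custom datasets require at least n and noise_spec")
        spec = spec or TrueModelSpec()
        null = bool(null)

    ss = np.random.SeedSequence(seed)
    s_true, s_noise, s_out = ss.spawn(3)
    true_block = simulate_true_block(n, spec, s_true)
    noise = simulate_noise_block(n, noise_spec, s_noise)
    X = np.hstack([true_block, noise])
    if null:
        y = _rng(s_out).standard_normal(n)
        support = np.array([], dtype=int)
    else:
        y = simulate_outcome(true_block, spec, s_out)
        support = np.arange(N_TRUE)
    columns = [f"X{i + 1}" for i in range(N_TRUE)] + _noise_names(noise.shape[1])
    return SimulatedDataset(
        X=X,
        y=y,
        columns=columns,
        true_support=support,
        spec=spec,
        noise_spec=noise_spec,
        seed=seed,
        name=f"dataset{name}" if name is not None else None,
    )


@dataclass
class TrueModelFit:
    """OLS reference fit of the outcome on the true covariates only."""

    table: pd.DataFrame  # index = covariate names; estimate, lo95, hi95
    intercept: float
    r_squared: float


def fit_true_model(ds: SimulatedDataset) -> TrueModelFit:
    """OLS of y on the true covariates: estimates, Wald 95% CIs and R^2."""
    if len(ds.true_support) == 0:
        raise ValueError("dataset has no true covariates; a true model is not applicable")
    Xt = sm.add_constant(ds.X[:, ds.true_support])
    fit = sm.OLS(ds.y, Xt).fit()
    ci = fit.conf_int(alpha=0.05)
    names = [ds.columns[i] for i in ds.true_support]
    table = pd.DataFrame(
        {
            "estimate": fit.params[1:],
            "lo95": ci[1:, 0],
            "hi95": ci[1:, 1],
        },
        index=pd.Index(names, name="covariate"),
    )
    return TrueModelFit(table=table, intercept=float(fit.params[0]), r_squared=float(fit.rsquared))
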