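"""Matrix-variate simulator with Kronecker-product covariance.

Generates N independent r x c matrices X_i = M + L_R Z_i L_C' where
L_R L_R' = Sigma_R, L_C L_C' = Sigma_C (symmetric matrix square roots) and
the entries of Z_i are iid standardized draws, so that
Cov(X_ij, X_lm) = (Sigma_R)_il (Sigma_C)_jm exactly.  Two innovation
families are available:

* ``gaussian`` — standard normal entries;
* ``scaled_gamma`` — (Gamma(a, 1) - a)/sqrt(a) entries, mean 0, variance 1,
  skewness 2/sqrt(a); used to probe robustness to non-normality.

Sigma_C is renormalized to trace c at configuration time, matching the
identifiability convention used by the estimators.  Sampling is
deterministic given the seed: subject i draws from an independent
substream keyed by (seed, i), so enlarging N extends rather than reshuffles
the sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .data import TransposableDataset

__all__ = [
    "SimulationConfig",
    "random_covariance",
    "sample_dataset",
    "gtex_like_config",
    "calibration_run",
]


def random_covariance(p: int, structure: str, seed: int | None = None, **params) -> np.ndarray:
    """Build a structured symmetric positive-definite p x p matrix.

    structure
        ``"identity"``;
        ``"ar1"`` with ``rho`` (|rho| < 1): Sigma_ij = rho^|i-j|;
        ``"cs"`` (compound symmetry) with ``rho`` in (-1/(p-1), 1): unit
        diagonal, rho off-diagonal;
        ``"diag_unequal"`` with ``lo``, ``hi`` (0 < lo <= hi): diagonal with
        entries evenly spaced from lo to hi (seed-free and deterministic).
    """
    if p < 1:
        raise ValueError("dimension must be >= 1")
    if structure == "identity":
        return np.eye(p)
    if structure == "ar1":
        rho = float(params["rho"])
        if not abs(rho) < 1:
            raise ValueError(f"ar1 requires |rho| < 1, got {rho}")
        idx = np.arange(p)
        return rho ** np.abs(idx[:, None] - idx[None, :])
    if structure == "cs":
        rho = float(params["rho"])
        lo = -1.0 / (p - 1) if p > 1 else -1.0
        if not (lo < rho < 1):
            raise ValueError(f"cs requires rho in ({lo:.4g}, 1), got {rho}")
        return np.full((p, p), rho) + (1 - rho) * np.eye(p)
    if structure == "diag_unequal":
        lo, hi = float(params["lo"]), float(params["hi"])
        if not 0 < lo <= hi:
            raise ValueError("diag_unequal requires 0 < lo <= hi")
        return np.diag(np.linspace(lo, hi, p))
    raise ValueError(f"unknown covariance structure {structure!r}")


def parse_structure(spec: str):
    """Parse CLI-style structure strings like ``ar1:0.5``, ``cs:0.2``,
    ``diag_unequal:0.5:3``, ``identity`` into a dimension -> matrix factory."""
    parts = spec.split(":")
    name = parts[0]
    if name == "identity":
        return lambda p: random_covariance(p, "identity")
    if name in ("ar1", "cs"):
        return lambda p: random_covariance(p, name, rho=float(parts[1]))
    if name == "diag_unequal":
        return lambda p: random_covariance(p, name, lo=float(parts[1]), hi=float(parts[2]))
    raise ValueError(f"unknown covariance structure spec {spec!r}")


def _spd_sqrt(sigma: np.ndarray, what: str) -> np.ndarray:
    """Symmetric square root via eigendecomposition, so that permuting
    labels commutes with generation."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError(f"{what} must be square")
    if not np.allclose(sigma, sigma.T, atol=1e-10):
        raise ValueError(f"{what} must be symmetric")
    vals, vecs = np.linalg.eigh(sigma)
    if vals.min() <= 0:
        raise ValueError(f"{what} must be positive definite (min eigenvalue {vals.min():.3g})")
    return (vecs * np.sqrt(vals)) @ vecs.T


@dataclass
class SimulationConfig:
    """Generative model for one simulated transposable dataset.

    Sigma_C is renormalized to trace c on construction.  ``family`` is
    ``"gaussian"`` or ``"scaled_gamma"`` (with ``shape`` a > 0).
    """

    mean: np.ndarray
    sigma_r: np.ndarray
    sigma_c: np.ndarray
    n_subjects: int
    family: str = "gaussian"
    shape: float = 1.0
    seed: int = 0
    _lr: np.ndarray = field(init=False, repr=False)
    _lc: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.mean = np.atleast_2d(np.asarray(self.mean, dtype=float))
        r, c = self.mean.shape
        self.sigma_r = np.asarray(self.sigma_r, dtype=float)
        self.sigma_c = np.asarray(self.sigma_c, dtype=float)
        if self.sigma_r.shape != (r, r) or self.sigma_c.shape != (c, c):
            raise ValueError(
                f"covariance shapes {self.sigma_r.shape}/{self.sigma_c.shape} do not "
                f"match mean shape {(r, c)}"
            )
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.family not in ("gaussian", "scaled_gamma"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "scaled_gamma" and self.shape <= 0:
            raise ValueError("scaled_gamma requires shape > 0")
        tr_c = np.trace(self.sigma_c)
        if tr_c <= 0:
            raise ValueError("sigma_c must have positive trace")
        self.sigma_c = self.sigma_c * (c / tr_c)  # identifiability convention
        self._lr = _spd_sqrt(self.sigma_r, "sigma_r")
        self._lc = _spd_sqrt(self.sigma_c, "sigma_c")

    @property
    def shape_rc(self) -> tuple[int, int]:
        return self.mean.shape  # type: ignore[return-value]


def _innovations(rng: np.random.Generator, size, family: str, shape: float) -> np.ndarray:
    if family == "gaussian":
        return rng.standard_normal(size)
    return (rng.gamma(shape, 1.0, size) - shape) / np.sqrt(shape)


def sample_dataset(cfg: SimulationConfig) -> TransposableDataset:
    """Draw one dataset from the configured matrix-variate model.

    Deterministic given ``cfg.seed``; subject i uses substream (seed, i).
    Labels are auto-generated ("g0001", ..., "t1", ..., "s01", ...).
    """
    r, c = cfg.shape_rc
    n = cfg.n_subjects
    x = np.empty((n, r, c))
    for i in range(n):
        rng = np.random.default_rng((int(cfg.seed), i))
        z = _innovations(rng, (r, c), cfg.family, cfg.shape)
        x[i] = cfg.mean + cfg._lr @ z @ cfg._lc.T
    width = max(4, len(str(r)))
    rows = [f"g{a + 1:0{width}d}" for a in range(r)]
    cols = [f"t{b + 1}" for b in range(c)]
    subs = [f"s{i + 1:02d}" for i in range(n)]
    return TransposableDataset(x, subs, rows, cols)


def gtex_like_config(
    r: int = 2000,
    c: int = 9,
    n_subjects: int = 11,
    seed: int = 0,
    frac_silent: float = 0.3,
    family: str = "gaussian",
    shape: float = 1.0,
) -> SimulationConfig:
    """Configuration emulating the shape class of multi-tissue RNAseq data:
    many genes, few tissues, fewer subjects (default 2000 x 9 x 11).

    A fraction of genes is "silent" (mean RPKM ~ 1e-3, tiny variance, so the
    standard 0.1 expression-sum filter removes them); expressed genes get
    log-uniform mean levels in [0.5, 50) with standard deviations
    proportional to their level (30% coefficient of variation), AR1(0.5)
    gene-gene correlation and compound-symmetric tissue correlation 0.2.
    """
    rng = np.random.default_rng((int(seed), 987654321))
    n_silent = int(round(frac_silent * r))
    level = np.empty(r)
    level[:n_silent] = 1e-3
    level[n_silent:] = np.exp(rng.uniform(np.log(0.5), np.log(50.0), r - n_silent))
    order = rng.permutation(r)
    level = level[order]
    mean = np.tile(level[:, None], (1, c))
    sd = np.maximum(0.3 * level, 1e-4)
    corr_r = random_covariance(r, "ar1", rho=0.5)
    sigma_r = corr_r * np.outer(sd, sd)
    sigma_c = random_covariance(c, "cs", rho=0.2)
    return SimulationConfig(mean, sigma_r, sigma_c, n_subjects, family=family, shape=shape, seed=seed)


# ---------------------------------------------------------------------------
# calibration harness


def _replicate_seeds(seed: int, n_reps: int) -> Iterator[int]:
    # independent per-replicate seeds kept below 2**31
    ss = np.random.SeedSequence(int(seed))
    for s in ss.generate_state(n_reps):
        yield int(s % (2**31 - 1))


def calibration_run(scenario: dict) -> pd.DataFrame:
    """Run a named size/power simulation and tabulate empirical rates.

    ``scenario`` is a mapping with keys:

    name
        free-text label echoed in the output;
    test
        one of ``mean_size``, ``mean_power``, ``sphericity_size``,
        ``sphericity_power``;
    r, c, n_subjects, n_reps, seed, level (default 0.05)
        design sizes;
    sigma_r, sigma_c
        structure strings (e.g. ``ar1:0.5``), default identity;
    family, shape
        innovation family (default gaussian);
    shift, frac_rows, shift_col
        mean_power only: mean shift added to a fraction of rows of one
        column; a list of shifts produces one output row per shift;
    rho
        sphericity_power only: equicorrelation(s) of a two-column
        Sigma_C; a list produces one output row per value.

    Returns a DataFrame with columns (scenario, test, parameter, nominal,
    estimate, mc_se, n_reps); deterministic given the seed.
    """
    from .cov_tests import all_pairs_sphericity
    from .mean_tests import ColumnGrouping, mean_conservation_test

    sc = dict(scenario)
    test = sc.get("test")
    if test not in ("mean_size", "mean_power", "sphericity_size", "sphericity_power"):
        raise ValueError(f"unknown calibration test {test!r}")
    n_reps = int(sc.get("n_reps", 0))
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    r, c, n = int(sc["r"]), int(sc["c"]), int(sc["n_subjects"])
    level = float(sc.get("level", 0.05))
    seed = int(sc.get("seed", 0))
    family = sc.get("family", "gaussian")
    shape = float(sc.get("shape", 1.0))
    make_r = parse_structure(sc.get("sigma_r", "identity"))
    make_c = parse_structure(sc.get("sigma_c", "identity"))
    sigma_r, sigma_c = make_r(r), make_c(c)

    def dataset(rep_seed: int, mean: np.ndarray, sc_mat: np.ndarray) -> TransposableDataset:
        cfg = SimulationConfig(mean, sigma_r, sc_mat, n, family=family, shape=shape, seed=rep_seed)
        return sample_dataset(cfg)

    rows = []

    def emit(parameter: str, hits: int, reps: int) -> None:
        est = hits / reps
        rows.append(
            {
                "scenario": sc.get("name", test),
                "test": test,
                "parameter": parameter,
                "nominal": level,
                "estimate": est,
                "mc_se": float(np.sqrt(est * (1 - est) / reps)),
                "n_reps": reps,
            }
        )

    if test in ("mean_size", "mean_power"):
        shifts = [0.0] if test == "mean_size" else list(np.atleast_1d(sc.get("shift", 0.5)))
        frac = float(sc.get("frac_rows", 0.1))
        col = int(sc.get("shift_col", 0))
        grouping = None
        for shift in shifts:
            hits = 0
            for rep_seed in _replicate_seeds(seed, n_reps):
                mean = np.zeros((r, c))
                if shift:
                    mean[: int(round(frac * r)), col] = shift
                ds = dataset(rep_seed, mean, sigma_c)
                if grouping is None:
                    grouping = ColumnGrouping([list(ds.col_ids)])
                res = mean_conservation_test(ds, grouping)
                hits += res.p_value < level
            emit(f"shift={shift:g}", hits, n_reps)
    else:
        rhos = [0.0] if test == "sphericity_size" else list(np.atleast_1d(sc.get("rho", 0.3)))
        for rho in rhos:
            sc_mat = random_covariance(c, "cs", rho=rho) if rho else sigma_c
            hits = 0
            n_tests = 0
            for rep_seed in _replicate_seeds(seed, n_reps):
                ds = dataset(rep_seed, np.zeros((r, c)), sc_mat)
                results, _ = all_pairs_sphericity(ds)
                hits += sum(t.p_value < level for t in results)
                n_tests += len(results)
            emit(f"rho={rho:g}", hits, n_tests)
    return pd.DataFrame(rows)
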