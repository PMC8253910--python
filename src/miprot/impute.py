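"""Left-censored imputation and the multiple-imputation ensemble.

Missing label-free intensities are assumed to be left-censored: a value
is absent because it fell below the detection limit.  For each sample
column we estimate the mean and standard deviation of the complete
(uncensored) log2 distribution from the upper order statistics of the
observed values, then replace each missing cell with an independent draw
from the fitted normal truncated above at the estimated censoring
quantile.  Repeating the draw R times yields an ensemble of completed
matrices over which downstream p-values are pooled.

Fitting is ordinary least squares of the sorted observed values against
standard-normal quantiles at the plotting positions

    p_i = f + (1 - f) * (i - 0.375) / (n_obs + 0.25),   i = 1..n_obs,

where ``f`` is the column's missing fraction (Blom positions shifted to
account for the censored left tail), restricted to an upper probability
window ``p_i >= max(f, 0.25)``.  The slope estimates sigma and the
intercept mu; the truncation point is the ``f``-quantile
``mu + sigma * Phi^-1(f)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import UserInputError
from .matrix import IntensityMatrix

MIN_OBS_FOR_FIT = 20


@dataclass(frozen=True)
class CensoredNormalFit:
    """Normal parameters of one sample column plus its censoring point."""

    mu: float
    sigma: float
    missing_fraction: float
    truncation_point: float

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "sigma": self.sigma,
            "missing_fraction": self.missing_fraction,
            "truncation_point": self.truncation_point,
        }


def fit_censored_normal(observed, missing_fraction: float) -> CensoredNormalFit:
    """Estimate (mu, sigma) of the complete distribution of one column.

    ``observed`` are the non-missing log2 values (any order);
    ``missing_fraction`` is the fraction of the column that is censored.
    """
    x = np.sort(np.asarray(observed, dtype=float))
    n = x.size
    if n < MIN_OBS_FOR_FIT:
        raise UserInputError(f"need >= {MIN_OBS_FOR_FIT} observed values, got {n}")
    if not 0 <= missing_fraction < 1:
        raise UserInputError("missing_fraction must be in [0, 1)")
    if np.ptp(x) == 0:
        raise UserInputError("cannot estimate sigma: observed values are constant")

    f = missing_fraction
    i = np.arange(1, n + 1)
    p = f + (1 - f) * (i - 0.375) / (n + 0.25)
    window = p >= max(f, 0.25)
    if window.sum() < 2:
        raise UserInputError("probability window leaves fewer than 2 points")
    z = norm.ppf(p[window])
    y = x[window]
    zbar, ybar = z.mean(), y.mean()
    denom = float(((z - zbar) ** 2).sum())
    if denom == 0:
        raise UserInputError("cannot estimate sigma: degenerate quantile window")
    sigma = float(((z - zbar) * (y - ybar)).sum() / denom)
    mu = float(ybar - sigma * zbar)
    if sigma <= 0:
        raise UserInputError("cannot estimate sigma: non-positive slope")
    trunc = mu + sigma * norm.ppf(f) if f > 0 else -np.inf
    return CensoredNormalFit(mu, sigma, f, float(trunc))


def _draw_truncated(
    fit: CensoredNormalFit, size: int, rng: np.random.Generator, tune_sigma: float
) -> np.ndarray:
    """Draws from Normal(mu, tune_sigma * sigma) truncated above at the censor point."""
    scale = tune_sigma * fit.sigma
    b = (fit.truncation_point - fit.mu) / scale
    u = rng.random(size)
    # inverse-CDF sampling of the upper-truncated normal
    return fit.mu + scale * norm.ppf(u * norm.cdf(b))


def fit_columns(matrix: IntensityMatrix) -> dict[str, CensoredNormalFit]:
    """Per-sample censored-normal fits, with a pooled-global fallback.

    Columns with fewer than ``MIN_OBS_FOR_FIT`` observed values fall back
    to a fit on all observed values of the matrix (warning emitted);
    columns with no observed values are an error.
    """
    values = matrix.values
    fits: dict[str, CensoredNormalFit] = {}
    pooled = None
    for sid in values.columns:
        col = values[sid].to_numpy()
        obs = col[~np.isnan(col)]
        f = 1 - obs.size / col.size
        if obs.size == 0:
            raise UserInputError(f"column {sid!r} has no observed values")
        if obs.size >= MIN_OBS_FOR_FIT:
            fits[sid] = fit_censored_normal(obs, f)
        else:
            warnings.warn(
                f"column {sid!r} too sparse for fitting ({obs.size} observed); "
                "falling back to a global fit",
                stacklevel=2,
            )
            if pooled is None:
                allv = values.to_numpy()
                allobs = allv[~np.isnan(allv)]
                pooled_f = 1 - allobs.size / allv.size
                pooled = fit_censored_normal(allobs, pooled_f)
            trunc = (
                pooled.mu + pooled.sigma * norm.ppf(f) if f > 0 else -np.inf
            )
            fits[sid] = CensoredNormalFit(pooled.mu, pooled.sigma, f, float(trunc))
    return fits


def impute_qrilc(
    matrix: IntensityMatrix,
    seed: int,
    tune_sigma: float = 1.0,
    fits: dict[str, CensoredNormalFit] | None = None,
) -> IntensityMatrix:
    """Complete a matrix by truncated-normal draws, column by column.

    Observed cells are untouched; a matrix with no missing values is
    returned as a copy unchanged.  Identical seeds give identical output.
    """
    if tune_sigma <= 0:
        raise UserInputError("tune_sigma must be positive")
    if fits is None:
        fits = fit_columns(matrix)
    values = matrix.values.copy()
    rng = np.random.default_rng(seed)
    for sid in values.columns:
        col = values[sid].to_numpy(copy=True)
        miss = np.isnan(col)
        if not miss.any():
            continue
        fit = fits[sid]
        if fit.missing_fraction == 0:
            raise UserInputError(f"column {sid!r}: fit has no censored mass to draw from")
        col[miss] = _draw_truncated(fit, int(miss.sum()), rng, tune_sigma)
        values[sid] = col
    return IntensityMatrix(values, matrix.design)


def replicate_seed(master_seed: int, index: int) -> int:
    """Stable per-replicate seed derived from (master seed, replicate index)."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0])


@dataclass
class ImputedEnsemble:
    """R completed matrices differing only in imputed cells."""

    replicates: list[IntensityMatrix] = field(repr=False)
    replicate_seeds: list[int]
    source: IntensityMatrix = field(repr=False)
    fits: dict[str, CensoredNormalFit]
    tune_sigma: float = 1.0

    def __post_init__(self) -> None:
        if len(self.replicates) != len(self.replicate_seeds):
            raise UserInputError("one seed per replicate required")
        src = self.source.to_numpy()
        obs = ~np.isnan(src)
        for r in self.replicates:
            arr = r.to_numpy()
            if np.isnan(arr).any():
                raise UserInputError("ensemble replicate contains missing values")
            if not np.array_equal(arr[obs], src[obs]):
                raise UserInputError("observed cells altered in a replicate")

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def save(self, directory) -> None:
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for i, rep in enumerate(self.replicates):
            rep.to_tsv(d / f"replicate_{i:04d}.tsv")
        self.source.to_tsv(d / "source.tsv")
        self.source.design.to_csv(d / "design.csv")
        manifest = {
            "n_replicates": self.n_replicates,
            "replicate_seeds": self.replicate_seeds,
            "tune_sigma": self.tune_sigma,
            "fits": {sid: f.to_dict() for sid, f in self.fits.items()},
        }
        with open(d / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, directory) -> "ImputedEnsemble":
        import json
        from pathlib import Path

        from .design import SampleDesign

        d = Path(directory)
        with open(d / "manifest.json") as fh:
            manifest = json.load(fh)
        design = SampleDesign.from_csv(d / "design.csv")
        source = IntensityMatrix.from_tsv(d / "source.tsv", design)
        reps = [
            IntensityMatrix.from_tsv(d / f"replicate_{i:04d}.tsv", design)
            for i in range(manifest["n_replicates"])
        ]
        fits = {
            sid: CensoredNormalFit(**f) for sid, f in manifest["fits"].items()
        }
        return cls(reps, manifest["replicate_seeds"], source, fits, manifest["tune_sigma"])


def build_ensemble(
    matrix: IntensityMatrix,
    n_replicates: int = 300,
    master_seed: int = 0,
    tune_sigma: float = 1.0,
) -> ImputedEnsemble:
    """Impute ``n_replicates`` times with deterministically derived seeds."""
    if n_replicates < 2:
        raise UserInputError("n_replicates must be >= 2 (pooling undefined otherwise)")
    fits = fit_columns(matrix)
    seeds = [replicate_seed(master_seed, r) for r in range(n_replicates)]
    reps = [impute_qrilc(matrix, seed=s, tune_sigma=tune_sigma, fits=fits) for s in seeds]
    return ImputedEnsemble(reps, seeds, matrix, fits, tune_sigma)
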