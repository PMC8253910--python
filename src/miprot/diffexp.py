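"""Per-replicate two-way ANOVA + Tukey HSD, FDR, and ensemble pooling.

Each completed matrix of the imputation ensemble is analysed protein by
protein with a fixed-effects two-way ANOVA (treatment x time, Type-II
sums of squares by default for the unbalanced 28-sample design) followed
by Tukey's HSD over all 15 pairwise (group, timepoint) cell contrasts.
ANOVA p-values are Benjamini-Hochberg adjusted across proteins within
each term and each replicate, and replicate-level adjusted p-values are
pooled as the geometric mean.  A protein is called differentially
expressed when its pooled interaction q-value falls below alpha; the
time point of significance and the direction (which arm is higher) are
read off the within-time between-group Tukey contrasts.

The per-protein operations are exposed individually; ``call_de`` runs
the whole ensemble through a vectorised path that shares the design
projections across proteins and replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

from .design import GROUPS, TIMEPOINTS, SampleDesign
from .errors import UserInputError
from .impute import ImputedEnsemble

P_FLOOR = 1e-300  # floor applied before log pooling

# ---------------------------------------------------------------------------
# design projections

CELLS: list[tuple[str, str]] = [(g, tp) for g in GROUPS for tp in TIMEPOINTS]


def _effect_code(labels: np.ndarray, levels: list) -> np.ndarray:
    """Sum-to-zero (deviation) coding, n x (len(levels) - 1)."""
    n = labels.shape[0]
    out = np.zeros((n, len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        out[labels == lev, j] = 1.0
    out[labels == levels[-1], :] = -1.0
    return out


@dataclass(frozen=True)
class _DesignProjections:
    """Orthonormal bases of the nested models for one factor layout."""

    q_full: np.ndarray
    q_additive: np.ndarray
    q_a_only: np.ndarray
    q_b_only: np.ndarray
    q_intercept: np.ndarray
    q_no_a: np.ndarray  # Type III: full minus treatment columns
    q_no_b: np.ndarray  # Type III: full minus time columns
    cells: tuple  # (level_a, level_b) pairs
    cell_index: np.ndarray  # sample -> index into cells
    cell_sizes: np.ndarray
    df: dict


def _q_basis(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


@lru_cache(maxsize=32)
def _make_projections(
    a_labels: tuple, b_labels: tuple, a_levels: tuple, b_levels: tuple
) -> _DesignProjections:
    ga = np.asarray(a_labels, dtype=object)
    gb = np.asarray(b_labels, dtype=object)
    n = ga.shape[0]
    a = _effect_code(ga, list(a_levels))
    b = _effect_code(gb, list(b_levels))
    ab = np.column_stack(
        [a[:, i] * b[:, j] for i in range(a.shape[1]) for j in range(b.shape[1])]
    )
    one = np.ones((n, 1))
    cells = tuple((la, lb) for la in a_levels for lb in b_levels)
    cell_index = np.array([cells.index((x, y)) for x, y in zip(ga, gb)])
    cell_sizes = np.bincount(cell_index, minlength=len(cells))
    if (cell_sizes < 2).any():
        bad = [cells[i] for i in np.where(cell_sizes < 2)[0]]
        raise UserInputError(f"two-way ANOVA needs >=2 samples per cell; short cells: {bad}")
    df = {
        "treatment": len(a_levels) - 1,
        "time": len(b_levels) - 1,
        "interaction": (len(a_levels) - 1) * (len(b_levels) - 1),
        "error": n - len(a_levels) * len(b_levels),
    }
    if df["error"] < 1:
        raise UserInputError("no residual degrees of freedom")
    return _DesignProjections(
        q_full=_q_basis(np.hstack([one, a, b, ab])),
        q_additive=_q_basis(np.hstack([one, a, b])),
        q_a_only=_q_basis(np.hstack([one, a])),
        q_b_only=_q_basis(np.hstack([one, b])),
        q_intercept=_q_basis(one),
        q_no_a=_q_basis(np.hstack([one, b, ab])),
        q_no_b=_q_basis(np.hstack([one, a, ab])),
        cells=cells,
        cell_index=cell_index,
        cell_sizes=cell_sizes,
        df=df,
    )


def _get_projections(design: SampleDesign) -> _DesignProjections:
    t = design.table
    return _make_projections(
        tuple(t["group"]), tuple(t["timepoint"]), GROUPS, TIMEPOINTS
    )


def _factor_projections(factor_a, factor_b) -> _DesignProjections:
    a = tuple(factor_a)
    b = tuple(factor_b)
    if len(a) != len(b):
        raise UserInputError("factor label vectors must have equal length")
    levels_a = tuple(dict.fromkeys(a))
    levels_b = tuple(dict.fromkeys(b))
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise UserInputError("each factor needs at least two levels")
    return _make_projections(a, b, levels_a, levels_b)


def _rss(q: np.ndarray, y: np.ndarray, total_sq: np.ndarray) -> np.ndarray:
    fitted = q.T @ y
    return total_sq - np.einsum("ij,ij->j", fitted, fitted)


def anova_terms_matrix(
    y: np.ndarray, design: SampleDesign | None = None, ss_type: str = "II",
    projections: _DesignProjections | None = None,
) -> dict:
    """Vectorised two-way ANOVA over proteins.

    ``y`` is samples x proteins, complete, rows in design order.  Returns
    arrays of sums of squares, F statistics and p-values per term.
    """
    if ss_type not in ("I", "II", "III"):
        raise UserInputError("ss_type must be 'I', 'II' or 'III'")
    proj = projections if projections is not None else _get_projections(design)
    if y.shape[0] != len(proj.cell_index):
        raise UserInputError("value rows do not match design samples")
    if np.isnan(y).any():
        raise UserInputError("ANOVA requires complete values (impute first)")
    total_sq = np.einsum("ij,ij->j", y, y)
    rss_full = _rss(proj.q_full, y, total_sq)
    rss_add = _rss(proj.q_additive, y, total_sq)
    if ss_type == "II":
        ss_a = _rss(proj.q_b_only, y, total_sq) - rss_add
        ss_b = _rss(proj.q_a_only, y, total_sq) - rss_add
    elif ss_type == "I":
        rss_a_only = _rss(proj.q_a_only, y, total_sq)
        ss_a = _rss(proj.q_intercept, y, total_sq) - rss_a_only
        ss_b = rss_a_only - rss_add
    else:  # Type III with sum-to-zero coding
        ss_a = _rss(proj.q_no_a, y, total_sq) - rss_full
        ss_b = _rss(proj.q_no_b, y, total_sq) - rss_full
    ss_ab = rss_add - rss_full
    ss_err = rss_full
    df = proj.df
    out = {"df": df, "ss": {}, "F": {}, "p": {}}
    # clip tiny negative round-off
    ss = {"treatment": ss_a, "time": ss_b, "interaction": ss_ab}
    mse = ss_err / df["error"]
    zero_var = mse <= 0
    if zero_var.any():
        warnings.warn("zero residual variance for some proteins; p set to 0/1", stacklevel=2)
    for term, s in ss.items():
        s = np.maximum(s, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fstat = (s / df[term]) / mse
        p = f_dist.sf(fstat, df[term], df["error"])
        if zero_var.any():
            fstat = np.where(zero_var & (s > 0), np.inf, fstat)
            p = np.where(zero_var, np.where(s > 0, 0.0, 1.0), p)
        out["ss"][term] = s
        out["F"][term] = fstat
        out["p"][term] = p
    out["ss"]["error"] = np.maximum(ss_err, 0.0)
    return out


@dataclass(frozen=True)
class AnovaTerms:
    """Two-way ANOVA summary for one protein."""

    p_treatment: float
    p_time: float
    p_interaction: float
    F: dict
    df: dict
    ss: dict


def _as_design_vector(values, design: SampleDesign) -> np.ndarray:
    if isinstance(values, pd.Series):
        values = values.reindex(design.sample_ids)
    arr = np.asarray(values, dtype=float)
    if arr.shape != (design.n_samples,):
        raise UserInputError(
            f"expected {design.n_samples} values in design order, got shape {arr.shape}"
        )
    return arr


def anova_two_way(
    values,
    design: SampleDesign | None = None,
    ss_type: str = "II",
    factor_a=None,
    factor_b=None,
) -> AnovaTerms:
    """Two-way ANOVA for a single protein's values.

    Either pass a :class:`SampleDesign` (treatment x time layout) or two
    explicit factor label vectors of the same length as ``values``.
    """
    if design is not None:
        y = _as_design_vector(values, design)[:, None]
        proj = _get_projections(design)
    else:
        if factor_a is None or factor_b is None:
            raise UserInputError("provide a design or both factor label vectors")
        y = np.asarray(values, dtype=float)[:, None]
        proj = _factor_projections(factor_a, factor_b)
    if np.isnan(y).any():
        raise UserInputError("ANOVA requires complete values (impute first)")
    res = anova_terms_matrix(y, ss_type=ss_type, projections=proj)
    return AnovaTerms(
        p_treatment=float(res["p"]["treatment"][0]),
        p_time=float(res["p"]["time"][0]),
        p_interaction=float(res["p"]["interaction"][0]),
        F={k: float(v[0]) for k, v in res["F"].items()},
        df=res["df"],
        ss={k: float(v[0]) for k, v in res["ss"].items()},
    )


# ---------------------------------------------------------------------------
# studentized range / Tukey

@lru_cache(maxsize=32)
def _srange_logsf_grid(k: int, df: int) -> tuple[np.ndarray, np.ndarray]:
    grid = np.concatenate([np.linspace(0.0, 20.0, 401), np.linspace(20.1, 80.0, 600)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sf = studentized_range.sf(grid, k, df)
    sf = np.clip(sf, 1e-320, 1.0)
    logsf = np.log(sf)
    # enforce monotonicity against quadrature noise
    logsf = np.minimum.accumulate(logsf)
    return grid, logsf


def srange_sf(q, k: int, df: int, fast: bool = False):
    """Upper tail of the studentized range distribution.

    ``fast=True`` evaluates a cached log-survival interpolant (built once
    per (k, df)); the default calls the exact distribution.
    """
    if not fast:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return studentized_range.sf(q, k, df)
    grid, logsf = _srange_logsf_grid(k, df)
    q = np.asarray(q, dtype=float)
    out = np.interp(q, grid, logsf)
    return np.exp(out)


@dataclass(frozen=True)
class ContrastResult:
    """One Tukey HSD pairwise cell contrast."""

    cell_pair: tuple
    mean_difference: float
    q_statistic: float
    adjusted_p: float


def tukey_from_cells(cells: list[np.ndarray], fast: bool = False) -> list[ContrastResult]:
    """Tukey(-Kramer) HSD over arbitrary cells of observations.

    The pooled within-cell mean square plays the error term; the
    studentized range family size equals the number of cells.
    """
    k = len(cells)
    if k < 2:
        raise UserInputError("need at least two cells")
    cells = [np.asarray(c, dtype=float) for c in cells]
    sizes = np.array([c.size for c in cells])
    if (sizes < 2).any():
        raise UserInputError("every cell needs >=2 observations")
    means = np.array([c.mean() for c in cells])
    ss_within = float(sum(((c - c.mean()) ** 2).sum() for c in cells))
    df = int(sizes.sum() - k)
    mse = ss_within / df
    results = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        if mse == 0:
            qstat = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            se = np.sqrt(mse / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            qstat = abs(diff) / se
            p = float(np.clip(srange_sf(qstat, k, df, fast=fast), 0.0, 1.0))
        results.append(ContrastResult((i, j), float(diff), float(qstat), p))
    return results


def tukey_hsd(values, design: SampleDesign, fast: bool = False) -> list[ContrastResult]:
    """All 15 pairwise (group, timepoint) cell contrasts for one protein."""
    y = _as_design_vector(values, design)
    if np.isnan(y).any():
        raise UserInputError("Tukey HSD requires complete values (impute first)")
    proj = _get_projections(design)
    cells = [y[proj.cell_index == c] for c in range(len(CELLS))]
    raw = tukey_from_cells(cells, fast=fast)
    return [
        ContrastResult((CELLS[i], CELLS[j]), r.mean_difference, r.q_statistic, r.adjusted_p)
        for r, (i, j) in zip(raw, [c.cell_pair for c in raw])
    ]


def _tukey_matrix(y: np.ndarray, proj: _DesignProjections) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Tukey over proteins: (15 x P mean diffs, 15 x P adjusted p)."""
    k = len(CELLS)
    n, n_prot = y.shape
    sums = np.zeros((k, n_prot))
    np.add.at(sums, proj.cell_index, y)
    means = sums / proj.cell_sizes[:, None]
    ss_within = np.einsum("ij,ij->j", y, y) - (proj.cell_sizes[:, None] * means**2).sum(axis=0)
    df = n - k
    mse = np.maximum(ss_within, 0.0) / df
    pairs = list(combinations(range(k), 2))
    diffs = np.empty((len(pairs), n_prot))
    ps = np.empty((len(pairs), n_prot))
    for idx, (i, j) in enumerate(pairs):
        diff = means[i] - means[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(mse / 2.0 * (1.0 / proj.cell_sizes[i] + 1.0 / proj.cell_sizes[j]))
            qstat = np.abs(diff) / se
        p = srange_sf(qstat, k, df, fast=True)
        p = np.where(mse == 0, np.where(diff != 0, 0.0, 1.0), p)
        diffs[idx] = diff
        ps[idx] = np.clip(p, 0.0, 1.0)
    return diffs, ps


# ---------------------------------------------------------------------------
# multiplicity and pooling

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up; output order matches input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise UserInputError("bh_adjust expects a 1-D sequence")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise UserInputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def pool_geometric(values) -> float:
    """Geometric mean of probabilities: exp(mean(log p)).

    Zeros are floored at ``P_FLOOR`` with a warning.
    """
    p = np.asarray(values, dtype=float)
    if p.size == 0:
        raise UserInputError("cannot pool an empty list")
    if (p < 0).any() or (p > 1).any():
        raise UserInputError("probabilities must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn(f"zero p-values floored at {P_FLOOR} before pooling", stacklevel=2)
        p = np.maximum(p, P_FLOOR)
    return float(np.exp(np.log(p).mean()))


# ---------------------------------------------------------------------------
# ensemble DE calling

#: within-time NEVKP-vs-SCS contrasts, as indices into the 15 Tukey pairs
_PAIRS = list(combinations(range(len(CELLS)), 2))
_WITHIN_TIME = {
    tp: _PAIRS.index(
        tuple(sorted([CELLS.index(("NEVKP", tp)), CELLS.index(("SCS", tp))]))
    )
    for tp in TIMEPOINTS
}


@dataclass
class DEResult:
    """Pooled differential-expression table plus the call parameters."""

    table: pd.DataFrame = field(repr=False)
    alpha: float
    de_term: str
    n_replicates: int

    @property
    def significant_ids(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="protein_id")


def call_de(
    ensemble: ImputedEnsemble,
    alpha: float = 0.05,
    de_term: str = "interaction",
    ss_type: str = "II",
) -> DEResult:
    """Run the per-replicate ANOVA/Tukey/BH analysis and pool the ensemble.

    ``de_term='interaction'`` keys significance to the treatment-x-time
    interaction q-value; ``de_term='main_effects'`` requires both the
    treatment and the time pooled q-values below alpha.
    """
    if de_term not in ("interaction", "main_effects"):
        raise UserInputError("de_term must be 'interaction' or 'main_effects'")
    if not 0 < alpha < 1:
        raise UserInputError("alpha must lie in (0, 1)")
    design = ensemble.source.design
    proj = _get_projections(design)
    protein_ids = ensemble.source.protein_ids
    n_prot = len(protein_ids)
    r_total = ensemble.n_replicates

    log_q = {term: np.zeros(n_prot) for term in ("treatment", "time", "interaction")}
    log_contrast = np.zeros((len(_PAIRS), n_prot))
    mean_diffs = np.zeros((len(_PAIRS), n_prot))

    for rep in ensemble.replicates:
        y = rep.to_numpy().T  # samples x proteins
        res = anova_terms_matrix(y, design, ss_type=ss_type)
        for term in log_q:
            q = bh_adjust(res["p"][term])
            log_q[term] += np.log(np.maximum(q, P_FLOOR))
        diffs, ps = _tukey_matrix(y, proj)
        log_contrast += np.log(np.maximum(ps, P_FLOOR))
        mean_diffs += diffs

    pooled_q = {term: np.exp(v / r_total) for term, v in log_q.items()}
    pooled_contrast = np.exp(log_contrast / r_total)
    mean_diffs /= r_total

    if de_term == "interaction":
        significant = pooled_q["interaction"] < alpha
    else:
        significant = (pooled_q["treatment"] < alpha) & (pooled_q["time"] < alpha)

    tp_order = list(TIMEPOINTS)
    within_p = np.vstack([pooled_contrast[_WITHIN_TIME[tp]] for tp in tp_order])  # 3 x P
    within_diff = np.vstack([mean_diffs[_WITHIN_TIME[tp]] for tp in tp_order])
    # sign convention: positive diff means the NEVKP cell mean is higher
    for row, tp in enumerate(tp_order):
        i, j = _PAIRS[_WITHIN_TIME[tp]]
        if CELLS[i][0] != "NEVKP":
            within_diff[row] = -within_diff[row]

    timepoints = np.array([""] * n_prot, dtype=object)
    directions = np.array([""] * n_prot, dtype=object)
    for p_idx in np.where(significant)[0]:
        col = within_p[:, p_idx]
        below = np.where(col < alpha)[0]
        pick = below[np.argmin(col[below])] if below.size else int(np.argmin(col))
        timepoints[p_idx] = tp_order[pick]
        directions[p_idx] = "NEVKP" if within_diff[pick, p_idx] > 0 else "SCS"

    table = pd.DataFrame(
        {
            "q_treatment": pooled_q["treatment"],
            "q_time": pooled_q["time"],
            "q_interaction": pooled_q["interaction"],
            "significant": significant,
            "timepoint_of_significance": timepoints,
            "direction": directions,
        },
        index=pd.Index(protein_ids, name="protein_id"),
    )
    for row, tp in enumerate(tp_order):
        table[f"p_within_{tp}"] = within_p[row]
        table[f"diff_within_{tp}"] = within_diff[row]
    return DEResult(table, alpha=alpha, de_term=de_term, n_replicates=r_total)
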