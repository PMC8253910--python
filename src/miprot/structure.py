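"""Unsupervised structure: PCA, hierarchical clustering, cluster profiles."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .design import GROUPS, TIMEPOINTS, SampleDesign
from .errors import UserInputError
from .matrix import IntensityMatrix


@dataclass
class PcaResult:
    """Sample scores, protein loadings and per-component variance fractions."""

    scores: pd.DataFrame = field(repr=False)
    loadings: pd.DataFrame = field(repr=False)
    explained_variance_fraction: np.ndarray

    def __post_init__(self) -> None:
        f = self.explained_variance_fraction
        if (f < -1e-12).any() or abs(f.sum() - 1.0) > 1e-8:
            raise UserInputError("variance fractions must be nonnegative and sum to 1")


def pca(matrix: IntensityMatrix | pd.DataFrame) -> PcaResult:
    """Principal components of the samples (proteins as variables).

    The proteins x samples matrix is transposed, each protein is mean
    centered, and the singular value decomposition provides scores and
    variance fractions (squared singular values over their total).
    """
    if isinstance(matrix, IntensityMatrix):
        values = matrix.values
    else:
        values = matrix
    if values.shape[1] < 2:
        raise UserInputError("PCA needs at least 2 samples")
    if values.isna().any().any():
        raise UserInputError("PCA requires a complete matrix (impute first)")
    x = values.to_numpy(dtype=float).T  # samples x proteins
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float((s**2).sum())
    if total == 0:
        raise UserInputError("matrix has zero variance")
    frac = s**2 / total
    comp = [f"PC{i + 1}" for i in range(s.size)]
    scores = pd.DataFrame(u * s, index=values.columns, columns=comp)
    loadings = pd.DataFrame(vt.T, index=values.index, columns=comp)
    return PcaResult(scores, loadings, frac)


@dataclass
class ClusterAssignment:
    """Protein cluster ids (1..k) plus dendrogram leaf orders."""

    clusters: pd.Series = field(repr=False)  # protein_id -> cluster id
    protein_order: list[str]
    sample_order: list[str]
    k: int

    def __post_init__(self) -> None:
        ids = set(self.clusters.unique())
        if ids != set(range(1, self.k + 1)):
            raise UserInputError(f"cluster ids must be contiguous 1..{self.k}, got {sorted(ids)}")

    def members(self, cluster_id: int) -> list[str]:
        return list(self.clusters.index[self.clusters == cluster_id])

    def to_tsv(self, path) -> None:
        self.clusters.rename("cluster").to_csv(path, sep="\t", index_label="protein_id")


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def cluster_heatmap(
    matrix: IntensityMatrix | pd.DataFrame,
    k: int = 8,
    metric: str = "euclidean",
    method: str = "average",
    zscore: bool = True,
) -> ClusterAssignment:
    """Agglomerative clustering of proteins and samples; cut proteins into k.

    Rows are z-scored per protein before distance computation by default
    (display-style clustering); the cut uses the protein dendrogram with
    a max-cluster criterion and ids are relabelled contiguously in
    dendrogram leaf order, making the assignment deterministic.
    """
    values = matrix.values if isinstance(matrix, IntensityMatrix) else matrix
    if values.isna().any().any():
        raise UserInputError("clustering requires a complete matrix (impute first)")
    n = values.shape[0]
    if k < 1 or k > n:
        raise UserInputError(f"k must lie in 1..{n}")
    x = values.to_numpy(dtype=float)
    if zscore:
        x = _zscore_rows(x)
    z_prot = linkage(x, method=method, metric=metric)
    z_samp = linkage(x.T, method=method, metric=metric)
    raw = fcluster(z_prot, t=k, criterion="maxclust")
    prot_leaves = leaves_list(z_prot)
    samp_leaves = leaves_list(z_samp)
    # contiguous ids in order of first appearance along the dendrogram
    relabel: dict[int, int] = {}
    for leaf in prot_leaves:
        relabel.setdefault(int(raw[leaf]), len(relabel) + 1)
    labels = np.array([relabel[int(c)] for c in raw])
    actual_k = labels.max()
    clusters = pd.Series(labels, index=values.index, name="cluster")
    return ClusterAssignment(
        clusters=clusters,
        protein_order=[values.index[i] for i in prot_leaves],
        sample_order=[values.columns[i] for i in samp_leaves],
        k=int(actual_k),
    )


def cluster_profiles(
    matrix: IntensityMatrix | pd.DataFrame,
    clusters: ClusterAssignment,
    design: SampleDesign,
) -> pd.DataFrame:
    """Median/quartile summaries per (cluster, group, timepoint) stratum.

    Quantiles use linear interpolation (numpy default).  Strata with no
    values get NaN summaries and n = 0.
    """
    values = matrix.values if isinstance(matrix, IntensityMatrix) else matrix
    unknown = set(clusters.clusters.index) - set(values.index)
    if unknown:
        raise UserInputError(f"clustered proteins absent from matrix: {sorted(unknown)[:5]}")
    rows = []
    for cid in range(1, clusters.k + 1):
        member_values = values.loc[clusters.members(cid)]
        for g in GROUPS:
            for tp in TIMEPOINTS:
                samples = design.samples(group=g, timepoint=tp)
                pool = member_values[samples].to_numpy().ravel()
                pool = pool[~np.isnan(pool)]
                if pool.size:
                    med, q1, q3 = (
                        float(np.quantile(pool, 0.5)),
                        float(np.quantile(pool, 0.25)),
                        float(np.quantile(pool, 0.75)),
                    )
                else:
                    med = q1 = q3 = np.nan
                rows.append(
                    {
                        "cluster": cid,
                        "group": g,
                        "timepoint": tp,
                        "median": med,
                        "q1": q1,
                        "q3": q3,
                        "n": int(pool.size),
                    }
                )
    return pd.DataFrame(rows)
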