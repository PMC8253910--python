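"""Cross-study signature overlap, directional concordance, and ORA.

External differential-expression signatures (gene lists with an
up/down-in-injury direction) are compared against the query DE set with
an upper-tail hypergeometric test, and the overlapping genes are
classified by whether the NEVKP-side change opposes or mirrors the
injury-side change.  The same hypergeometric machinery drives a generic
over-representation analysis over user-supplied GMT gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .diffexp import bh_adjust
from .errors import UserInputError

UP = "up_in_injury"
DOWN = "down_in_injury"

_DIRECTION_ALIASES = {
    "up": UP, "up_in_injury": UP, "increased": UP, "+": UP,
    "down": DOWN, "down_in_injury": DOWN, "decreased": DOWN, "-": DOWN,
}


@dataclass
class ExternalSignature:
    """A published injury signature: gene -> direction, with its universe size."""

    study_id: str
    entries: dict[str, str]
    universe_size: int

    def __post_init__(self) -> None:
        bad = {d for d in self.entries.values() if d not in (UP, DOWN)}
        if bad:
            raise UserInputError(f"unknown signature directions: {sorted(bad)}")
        if self.universe_size < len(self.entries):
            raise UserInputError("universe smaller than the signature")

    @property
    def genes(self) -> set[str]:
        return set(self.entries)


def read_signature(path, study_id: str, universe_size: int) -> ExternalSignature:
    """Read a two-column (gene, direction) TSV signature."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "gene" not in cols or "direction" not in cols:
        raise UserInputError("signature file needs 'gene' and 'direction' columns")
    entries = {}
    for _, row in df.iterrows():
        gene = str(row[cols["gene"]])
        raw = str(row[cols["direction"]]).strip().lower()
        if raw not in _DIRECTION_ALIASES:
            raise UserInputError(f"unparseable direction {raw!r} for gene {gene!r}")
        if gene in entries:
            raise UserInputError(f"duplicate gene in signature: {gene!r}")
        entries[gene] = _DIRECTION_ALIASES[raw]
    return ExternalSignature(study_id, entries, universe_size)


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (GMT semantics)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # dict keys are unique by construction; empty sets are suspicious
        empty = [n for n, s in self.sets.items() if not s]
        if empty:
            raise UserInputError(f"empty gene sets: {empty}")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> gene ... per line."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise UserInputError(f"malformed GMT line {lineno}: needs >= 3 fields")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise UserInputError(f"duplicate gene set name: {name!r}")
            sets[name] = set(genes)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def map_orthologs(
    query_genes, mapping: pd.DataFrame, allow_first: bool = False
) -> tuple[list[str], list[str]]:
    """Apply a two-column species mapping; report unmapped genes.

    One-to-many mappings raise unless ``allow_first`` takes the first
    listed target.  Returns (mapped targets in query order, unmapped).
    """
    if mapping.shape[1] < 2:
        raise UserInputError("mapping table needs two columns (source, target)")
    src_col, dst_col = mapping.columns[:2]
    table: dict[str, list[str]] = {}
    for _, row in mapping.iterrows():
        table.setdefault(str(row[src_col]), []).append(str(row[dst_col]))
    mapped, unmapped = [], []
    for g in query_genes:
        targets = table.get(str(g))
        if not targets:
            unmapped.append(str(g))
            continue
        if len(set(targets)) > 1 and not allow_first:
            raise UserInputError(
                f"one-to-many mapping for {g!r}: {sorted(set(targets))}; "
                "enable first-listed tie-break to accept"
            )
        mapped.append(targets[0])
    return mapped, unmapped


@dataclass
class OverlapResult:
    """Hypergeometric overlap of a query set with a signature."""

    study_id: str
    n_query: int
    n_signature: int
    n_universe: int
    n_overlap: int
    p_hypergeometric: float
    overlap_genes: list[str]
    n_opposing: int = 0
    n_concordant: int = 0

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_query, self.n_signature):
            raise UserInputError("overlap exceeds a set size")
        if self.n_opposing + self.n_concordant > self.n_overlap:
            raise UserInputError("directional tallies exceed the overlap")


def hypergeometric_upper_tail(n_universe: int, n_signature: int, n_query: int, n_overlap: int) -> float:
    """P(X >= n_overlap), X ~ Hypergeom(universe, signature, query draws)."""
    return float(hypergeom.sf(n_overlap - 1, n_universe, n_signature, n_query))


def hypergeometric_overlap(query, signature_genes, universe: int, study_id: str = "") -> OverlapResult:
    """Upper-tail hypergeometric test of the overlap of two gene sets."""
    q = set(query)
    s = set(signature_genes)
    if universe < len(q) or universe < len(s):
        raise UserInputError("universe smaller than a gene set")
    if universe < len(q | s):
        raise UserInputError("universe smaller than the union of the sets")
    overlap = sorted(q & s)
    p = hypergeometric_upper_tail(universe, len(s), len(q), len(overlap))
    return OverlapResult(
        study_id=study_id,
        n_query=len(q),
        n_signature=len(s),
        n_universe=universe,
        n_overlap=len(overlap),
        p_hypergeometric=p,
        overlap_genes=overlap,
    )


OPPOSING = "opposing"
CONCORDANT = "concordant"
UNDIRECTED = "undirected"


def classify_concordance(
    de_directions: dict[str, str] | pd.Series,
    signature: ExternalSignature,
    polarity: str = "nevkp_opposes_injury",
) -> dict[str, str]:
    """Label each query gene opposing/concordant/undirected vs a signature.

    ``de_directions`` maps gene -> arm with the higher expression
    ("NEVKP" or "SCS").  Default polarity: a gene higher in NEVKP whose
    signature direction is down-in-injury opposes the injury signature
    (NEVKP reverses injury); higher in SCS with up-in-injury likewise
    opposes, since SCS mirrors the injury.  The flipped polarity swaps
    the two labels exactly.
    """
    if polarity not in ("nevkp_opposes_injury", "flipped"):
        raise UserInputError("polarity must be 'nevkp_opposes_injury' or 'flipped'")
    if isinstance(de_directions, pd.Series):
        de_directions = de_directions.to_dict()
    labels: dict[str, str] = {}
    for gene, arm in de_directions.items():
        if arm not in ("NEVKP", "SCS"):
            raise UserInputError(f"unknown arm {arm!r} for gene {gene!r}")
        direction = signature.entries.get(gene)
        if direction is None:
            labels[gene] = UNDIRECTED
            continue
        opposes = (arm == "NEVKP" and direction == DOWN) or (arm == "SCS" and direction == UP)
        if polarity == "flipped":
            opposes = not opposes
        labels[gene] = OPPOSING if opposes else CONCORDANT
    return labels


def overlap_with_signature(
    de_directions: dict[str, str] | pd.Series,
    signature: ExternalSignature,
    universe: int | None = None,
    polarity: str = "nevkp_opposes_injury",
) -> OverlapResult:
    """Hypergeometric overlap plus directional-concordance tallies."""
    if isinstance(de_directions, pd.Series):
        de_directions = de_directions.to_dict()
    universe = signature.universe_size if universe is None else universe
    result = hypergeometric_overlap(
        de_directions.keys(), signature.genes, universe, study_id=signature.study_id
    )
    labels = classify_concordance(de_directions, signature, polarity=polarity)
    result.n_opposing = sum(
        1 for g in result.overlap_genes if labels.get(g) == OPPOSING
    )
    result.n_concordant = sum(
        1 for g in result.overlap_genes if labels.get(g) == CONCORDANT
    )
    return result


def ora(
    query, collection: GeneSetCollection, universe: int, alpha: float = 0.05
) -> pd.DataFrame:
    """Over-representation of the query in each gene set, BH across sets.

    Gene ratio is hits over query size.  Empty collections yield an
    empty frame.
    """
    q = set(query)
    if universe < len(q):
        raise UserInputError("universe smaller than the query")
    if not q:
        raise UserInputError("empty query")
    rows = []
    for name, genes in collection.sets.items():
        if universe < len(genes):
            raise UserInputError(f"universe smaller than gene set {name!r}")
        hits = sorted(q & genes)
        p = hypergeometric_upper_tail(universe, len(genes), len(q), len(hits))
        rows.append(
            {
                "set": name,
                "description": collection.descriptions.get(name, ""),
                "n_set": len(genes),
                "n_hits": len(hits),
                "gene_ratio": len(hits) / len(q),
                "p": p,
                "hits": ";".join(hits),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["set", "description", "n_set", "n_hits", "gene_ratio", "p", "q", "significant", "hits"]
        )
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] < alpha
    return df.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
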