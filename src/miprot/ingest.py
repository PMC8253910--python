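"""Reading proteinGroups-dialect tables and the quantification filter cascade.

The cascade mirrors standard label-free practice: decoy ("Reverse"),
contaminant and unannotated rows are removed first, then identifications
with posterior error probability above threshold, then the observed
intensities are log2-transformed, proteins quantified in too few samples
of every time point are dropped, and finally single-peptide
identifications are removed.  Every stage is tallied in a
:class:`FilterReport` so the funnel is auditable.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import TIMEPOINTS, SampleDesign
from .errors import UserInputError
from .matrix import IntensityMatrix
from .synthetic import LFQ_PREFIX, PG_META_COLUMNS

# UniProt (e.g. F1SPF6, Q95339, NP-style RefSeq) accession shapes; used to
# decide whether a gene-less row still carries a usable identifier.
_ACCESSION_RE = re.compile(
    r"^(?:"
    r"(?:NP|XP|YP|AP|NM|XM)_\d+(?:\.\d+)?"  # RefSeq
    r"|[OPQ][0-9][A-Z0-9]{3}[0-9]"          # UniProt 6-char, O/P/Q class
    r"|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2}"  # UniProt other
    r")$"
)


def is_accession_like(protein_id: str) -> bool:
    return any(_ACCESSION_RE.match(part) for part in str(protein_id).split(";") if part)


@dataclass
class ProteinRecord:
    """One row of a proteinGroups table bound to the sample design."""

    protein_id: str
    gene: str
    unique_peptides: int
    pep: float
    is_reverse: bool
    is_contaminant: bool
    lfq: dict[str, float]  # sample_id -> observed raw intensity (missing omitted)

    def __post_init__(self) -> None:
        if not 0 <= self.pep <= 1:
            raise UserInputError(f"PEP out of [0, 1] for {self.protein_id!r}: {self.pep}")

    @property
    def is_annotated(self) -> bool:
        return bool(self.gene) or is_accession_like(self.protein_id)


@dataclass
class FilterReport:
    """Per-stage protein counts and dropped ids of the filter cascade."""

    n_input: int
    n_after_decoy_contaminant_annotation: int
    n_after_pep: int
    n_quantified_min_samples: int
    n_after_min_peptides: int
    dropped: dict[str, list[str]] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def counts(self) -> list[int]:
        return [
            self.n_input,
            self.n_after_decoy_contaminant_annotation,
            self.n_after_pep,
            self.n_quantified_min_samples,
            self.n_after_min_peptides,
        ]

    def __post_init__(self) -> None:
        c = self.counts()
        if any(a < b for a, b in zip(c, c[1:])):
            raise UserInputError(f"filter counts must be nonincreasing, got {c}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "counts": {
                        "n_input": self.n_input,
                        "n_after_decoy_contaminant_annotation": self.n_after_decoy_contaminant_annotation,
                        "n_after_pep": self.n_after_pep,
                        "n_quantified_min_samples": self.n_quantified_min_samples,
                        "n_after_min_peptides": self.n_after_min_peptides,
                    },
                    "dropped": self.dropped,
                    "parameters": self.parameters,
                },
                fh,
                indent=2,
            )


def read_protein_groups(path, design: SampleDesign) -> list[ProteinRecord]:
    """Parse a proteinGroups-dialect TSV into records bound to ``design``.

    LFQ intensity 0 is MaxQuant's encoding of "not quantified" and is
    parsed as missing.  Reverse/contaminant flags use the "+" convention.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"Reverse": str, "Potential contaminant": str},
        float_precision="round_trip",
    )
    missing = [c for c in PG_META_COLUMNS if c not in df.columns]
    if missing:
        raise UserInputError(f"protein groups table missing required column(s): {missing}")
    lfq_cols = [c for c in df.columns if c.startswith(LFQ_PREFIX)]
    lfq_samples = [c[len(LFQ_PREFIX):] for c in lfq_cols]
    want = set(design.sample_ids)
    missing_samples = want - set(lfq_samples)
    if missing_samples:
        raise UserInputError(f"no LFQ column for design sample(s): {sorted(missing_samples)}")
    extra = set(lfq_samples) - want
    if extra:
        raise UserInputError(f"LFQ column(s) with no design entry: {sorted(extra)}")

    records = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        lfq = {}
        for sid in design.sample_ids:
            v = float(d[LFQ_PREFIX + sid])
            if v > 0 and np.isfinite(v):
                lfq[sid] = v
        records.append(
            ProteinRecord(
                protein_id=str(d["Majority protein IDs"]) if pd.notna(d["Majority protein IDs"]) else "",
                gene=str(d["Gene names"]) if pd.notna(d["Gene names"]) else "",
                unique_peptides=int(d["Unique peptides"]),
                pep=float(d["PEP"]),
                is_reverse=str(d["Reverse"]).strip() == "+",
                is_contaminant=str(d["Potential contaminant"]).strip() == "+",
                lfq=lfq,
            )
        )
    return records


def filter_cascade(
    records: list[ProteinRecord],
    design: SampleDesign,
    pep_max: float = 0.05,
    min_samples: int = 5,
    min_unique_peptides: int = 2,
    min_samples_scope: str = "timepoint",
) -> tuple[IntensityMatrix, FilterReport]:
    """Apply the filter cascade; return the log2 matrix and a stage report.

    ``min_samples_scope`` controls the minimum-observation rule: the
    default ``"timepoint"`` pools both arms within a time point (9-10
    samples in the reference design); ``"cell"`` requires the quorum
    inside a single (group, timepoint) cell.
    """
    if min_samples_scope not in ("timepoint", "cell"):
        raise UserInputError("min_samples_scope must be 'timepoint' or 'cell'")
    if min_samples_scope == "timepoint":
        strata = [design.samples(timepoint=tp) for tp in TIMEPOINTS]
    else:
        strata = [
            design.samples(group=g, timepoint=tp)
            for g in ("NEVKP", "SCS")
            for tp in TIMEPOINTS
        ]
    if min_samples > max(len(s) for s in strata):
        raise UserInputError(
            "filter unsatisfiable: min_samples exceeds every stratum's sample count"
        )

    dropped: dict[str, list[str]] = {}

    stage1 = []
    dropped["decoy_contaminant_annotation"] = []
    for r in records:
        if r.is_reverse or r.is_contaminant or not r.is_annotated:
            dropped["decoy_contaminant_annotation"].append(r.protein_id)
        else:
            stage1.append(r)

    stage2 = []
    dropped["pep"] = []
    for r in stage1:
        if r.pep > pep_max:
            dropped["pep"].append(r.protein_id)
        else:
            stage2.append(r)

    # stage 3: log2 transform of observed values (no rows dropped)
    sample_ids = design.sample_ids
    values = np.full((len(stage2), len(sample_ids)), np.nan)
    for i, r in enumerate(stage2):
        for j, sid in enumerate(sample_ids):
            if sid in r.lfq:
                values[i, j] = np.log2(r.lfq[sid])
    log2 = pd.DataFrame(
        values, index=pd.Index([r.protein_id for r in stage2], name="protein_id"),
        columns=sample_ids,
    )

    observed = ~log2.isna()
    keep4 = np.zeros(len(stage2), dtype=bool)
    for s in strata:
        if s:
            keep4 |= observed[s].sum(axis=1).to_numpy() >= min_samples
    dropped["min_samples"] = [r.protein_id for r, k in zip(stage2, keep4) if not k]
    stage4 = [r for r, k in zip(stage2, keep4) if k]
    log2 = log2.loc[keep4]

    keep5 = np.array([r.unique_peptides >= min_unique_peptides for r in stage4], dtype=bool)
    dropped["min_peptides"] = [r.protein_id for r, k in zip(stage4, keep5) if not k]
    log2 = log2.loc[keep5]

    report = FilterReport(
        n_input=len(records),
        n_after_decoy_contaminant_annotation=len(stage1),
        n_after_pep=len(stage2),
        n_quantified_min_samples=len(stage4),
        n_after_min_peptides=int(keep5.sum()),
        dropped=dropped,
        parameters={
            "pep_max": pep_max,
            "min_samples": min_samples,
            "min_unique_peptides": min_unique_peptides,
            "min_samples_scope": min_samples_scope,
        },
    )
    return IntensityMatrix(log2, design), report
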