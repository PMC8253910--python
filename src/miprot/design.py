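"""Sample design: which biopsy belongs to which animal, arm and time point.

The experiment is a two-arm (NEVKP vs SCS) by three-time-point (BL, R30,
POD3) layout with repeated biopsies per animal.  A :class:`SampleDesign`
binds sample identifiers to that grid and is carried alongside every
intensity matrix so downstream statistics always know the factor levels
of each column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import UserInputError

GROUPS: tuple[str, ...] = ("NEVKP", "SCS")
TIMEPOINTS: tuple[str, ...] = ("BL", "R30", "POD3")

_COLUMNS = ["sample_id", "animal_id", "group", "timepoint"]


@dataclass(frozen=True)
class SampleDesign:
    """Immutable table of samples with animal, group and timepoint labels.

    Invariants (checked at construction):

    * sample ids unique;
    * at most one sample per (animal, timepoint);
    * group constant within an animal;
    * every (group, timepoint) cell is non-empty.

    Cells of size 1 are representable (a dropout can shrink a cell that
    far) but per-cell statistics such as the two-way ANOVA additionally
    require >=2 samples per cell and enforce that themselves.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _COLUMNS if c not in t.columns]
        if missing:
            raise UserInputError(f"design table missing columns: {missing}")
        t = t[_COLUMNS].reset_index(drop=True)
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise UserInputError(f"duplicate sample ids: {dup}")
        bad_group = set(t["group"]) - set(GROUPS)
        if bad_group:
            raise UserInputError(f"unknown group labels: {sorted(bad_group)}")
        bad_tp = set(t["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise UserInputError(f"unknown timepoint labels: {sorted(bad_tp)}")
        if t.duplicated(subset=["animal_id", "timepoint"]).any():
            raise UserInputError("more than one sample for an (animal, timepoint)")
        ngroups = t.groupby("animal_id")["group"].nunique()
        if (ngroups > 1).any():
            raise UserInputError("group is not constant within an animal")
        counts = t.groupby(["group", "timepoint"], observed=True).size()
        for g in GROUPS:
            for tp in TIMEPOINTS:
                if counts.get((g, tp), 0) == 0:
                    raise UserInputError(f"degenerate cell: no samples in ({g}, {tp})")
        object.__setattr__(self, "table", t)

    # -- accessors ---------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def samples(self, group: str | None = None, timepoint: str | None = None) -> list[str]:
        """Sample ids restricted to a group and/or timepoint."""
        t = self.table
        if group is not None:
            t = t[t["group"] == group]
        if timepoint is not None:
            t = t[t["timepoint"] == timepoint]
        return t["sample_id"].tolist()

    def cell_counts(self) -> pd.Series:
        """Number of samples per (group, timepoint) cell."""
        return self.table.groupby(["group", "timepoint"], observed=True).size()

    def drop_samples(self, sample_ids: list[str]) -> "SampleDesign":
        unknown = set(sample_ids) - set(self.sample_ids)
        if unknown:
            raise UserInputError(f"unknown sample ids in dropout: {sorted(unknown)}")
        kept = self.table[~self.table["sample_id"].isin(sample_ids)]
        counts = kept.groupby(["group", "timepoint"], observed=True).size()
        for g in GROUPS:
            for tp in TIMEPOINTS:
                if counts.get((g, tp), 0) == 0:
                    raise UserInputError(f"degenerate cell: dropout empties ({g}, {tp})")
        return SampleDesign(kept.reset_index(drop=True))

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "SampleDesign":
        return cls(pd.read_csv(path, dtype=str))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)
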