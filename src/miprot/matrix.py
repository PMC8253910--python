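"""The log2 intensity matrix container shared by all analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import SampleDesign
from .errors import UserInputError


@dataclass
class IntensityMatrix:
    """Proteins x samples matrix of log2 intensities with explicit missingness.

    ``values`` is indexed by protein id with one column per design sample,
    in design order; missing cells are NaN.
    """

    values: pd.DataFrame = field(repr=False)
    design: SampleDesign

    def __post_init__(self) -> None:
        want = self.design.sample_ids
        have = list(self.values.columns)
        if set(have) != set(want):
            raise UserInputError(
                "matrix columns do not match design samples "
                f"(missing {sorted(set(want) - set(have))}, "
                f"extra {sorted(set(have) - set(want))})"
            )
        if have != want:
            self.values = self.values[want]
        self.values.index.name = "protein_id"

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def missing_fraction(self) -> float:
        return float(self.values.isna().to_numpy().mean())

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), self.design)

    # -- I/O (TSV with "NA" for missing) -----------------------------------

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", na_rep="NA", index_label="protein_id")

    @classmethod
    def from_tsv(cls, path, design: SampleDesign) -> "IntensityMatrix":
        df = pd.read_csv(path, sep="\t", index_col="protein_id", na_values=["NA"])
        return cls(df, design)
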