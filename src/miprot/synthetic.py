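"""Synthetic proteinGroups-style data with known ground truth.

Generates datasets with the statistical structure the analysis pipeline
assumes: log-normal protein abundances on the log2 scale, planted
group/time/interaction effects on a known subset of proteins,
intensity-dependent left-censored (MNAR) missingness, decoy and
contaminant rows, peptide counts and PEP values, and the 28-of-30
dropout pattern of the two-arm three-timepoint porcine design.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .design import GROUPS, TIMEPOINTS, SampleDesign
from .errors import UserInputError
from .matrix import IntensityMatrix

#: Column layout of the proteinGroups dialect written by this module.
PG_META_COLUMNS = [
    "Majority protein IDs",
    "Gene names",
    "Unique peptides",
    "PEP",
    "Reverse",
    "Potential contaminant",
]

LFQ_PREFIX = "LFQ intensity "

#: Two samples removed from distinct early-timepoint cells, giving the
#: 28-sample layout: 9 BL (4 NEVKP, 5 SCS), 9 R30 (4, 5), 10 POD3 (5, 5).
DEFAULT_DROPOUT = ["NEVKP1_BL", "NEVKP2_R30"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic dataset generator."""

    n_proteins: int = 1000
    n_animals_per_group: int = 5
    dropout_samples: tuple[str, ...] = tuple(DEFAULT_DROPOUT)
    de_fraction: float = 0.05
    effect_size_log2: float = 2.0
    missing_target_fraction: float = 0.15
    contaminant_count: int = 10
    reverse_count: int = 10
    unannotated_count: int = 0
    seed: int = 0
    # distribution knobs
    base_log2_mean: float = 25.0
    base_log2_sd: float = 2.0
    noise_sd: float = 0.5
    censor_scale: float = 0.6
    hard_threshold: bool = False
    effect_mode: str = "divergent"
    pep_violation_fraction: float = 0.02
    single_peptide_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction <= 1:
            raise UserInputError("de_fraction must be in [0, 1]")
        if not 0 <= self.missing_target_fraction < 1:
            raise UserInputError("missing_target_fraction must be in [0, 1)")
        if self.n_proteins < 1:
            raise UserInputError("n_proteins must be positive")
        if self.noise_sd <= 0:
            raise UserInputError("noise_sd must be positive")
        if self.censor_scale <= 0:
            raise UserInputError("censor_scale must be positive")
        if not 0 <= self.pep_violation_fraction <= 1:
            raise UserInputError("pep_violation_fraction must be in [0, 1]")
        if not 0 <= self.single_peptide_fraction <= 1:
            raise UserInputError("single_peptide_fraction must be in [0, 1]")
        if self.effect_mode not in ("divergent", "cell"):
            raise UserInputError("effect_mode must be 'divergent' or 'cell'")

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "dropout_samples" in d and d["dropout_samples"] is not None:
            d["dropout_samples"] = tuple(d["dropout_samples"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dropout_samples"] = list(d["dropout_samples"])
        return d


@dataclass
class SyntheticTruth:
    """Ground truth per protein: planted effects and censoring parameters.

    ``interaction_effects`` columns are named ``inter_<group>_<timepoint>``,
    ``time_effects`` columns ``time_<timepoint>``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        effect_cols = [c for c in self.table.columns if c.startswith(("inter_", "time_"))]
        has_effect = (self.table[["group_effect"] + effect_cols] != 0).any(axis=1)
        # is_de means "carries at least one group-related (group or
        # interaction) effect"; pure time effects are not DE between arms.
        de_cols = ["group_effect"] + [c for c in effect_cols if c.startswith("inter_")]
        expected = (self.table[de_cols] != 0).any(axis=1)
        if not (self.table["is_de"] == expected).all():
            raise UserInputError("is_de inconsistent with planted effects")
        if (self.table["noise_sd"] <= 0).any():
            raise UserInputError("noise_sd must be positive")
        if (self.table["censor_scale"] <= 0).any():
            raise UserInputError("censor_scale must be positive")
        del has_effect

    @property
    def de_protein_ids(self) -> list[str]:
        return list(self.table.index[self.table["is_de"]])

    def to_json(self, path) -> None:
        payload = {
            "columns": list(self.table.columns),
            "index": list(self.table.index),
            "data": self.table.to_numpy().tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        df = pd.DataFrame(payload["data"], index=payload["index"], columns=payload["columns"])
        df.index.name = "protein_id"
        df["is_de"] = df["is_de"].astype(bool)
        return cls(df)


def generate_design(n_per_group: int = 5, dropout: list[str] | None = None) -> SampleDesign:
    """Build the 2-group x 3-timepoint design, minus dropped samples.

    Animal ids are ``<GROUP><i>``; sample ids ``<animal>_<timepoint>``.
    Dropping every sample of a (group, timepoint) cell raises
    ``degenerate cell``.
    """
    if n_per_group < 2:
        raise UserInputError("n_per_group must be >= 2")
    rows = []
    for g in GROUPS:
        for i in range(1, n_per_group + 1):
            animal = f"{g}{i}"
            for tp in TIMEPOINTS:
                rows.append((f"{animal}_{tp}", animal, g, tp))
    full = SampleDesign(pd.DataFrame(rows, columns=["sample_id", "animal_id", "group", "timepoint"]))
    if dropout:
        return full.drop_samples(list(dropout))
    return full


def _latent_matrix(truth: pd.DataFrame, design: SampleDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Complete latent log2 matrix: fixed effects plus Gaussian noise."""
    n = len(truth)
    cols = {}
    for _, s in design.table.iterrows():
        mean = (
            truth["base_log2"].to_numpy()
            + truth["group_effect"].to_numpy() * (s["group"] == "NEVKP")
            + truth[f"time_{s['timepoint']}"].to_numpy()
            + truth[f"inter_{s['group']}_{s['timepoint']}"].to_numpy()
        )
        cols[s["sample_id"]] = mean
    means = pd.DataFrame(cols, index=truth.index)
    noise = rng.normal(0.0, truth["noise_sd"].to_numpy()[:, None], size=(n, design.n_samples))
    return means + noise


def calibrate_censor_location(latent: np.ndarray, scale: float, target: float) -> float:
    """Censor location whose expected logistic missing fraction hits ``target``.

    Solves mean(expit((L - x) / scale)) = target over the realized latent
    values.  target == 0 returns -inf (nothing censored).
    """
    if scale <= 0:
        raise UserInputError("censor scale must be positive")
    if target == 0:
        return -np.inf
    x = np.asarray(latent, dtype=float).ravel()

    def f(loc: float) -> float:
        return float(expit((loc - x) / scale).mean()) - target

    lo = x.min() - 60 * scale
    hi = x.max() + 60 * scale
    return float(brentq(f, lo, hi, xtol=1e-10))


def generate_dataset(
    config: GeneratorConfig, design: SampleDesign
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a complete (uncensored) protein table plus its ground truth.

    The returned table follows the proteinGroups dialect with one raw
    (linear-scale) LFQ column per sample.  Decoy/contaminant/unannotated
    rows are appended after the ``n_proteins`` real proteins.  The truth
    table covers every row and records the calibrated censoring
    parameters used later by :func:`apply_mnar_censoring`.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    n_extra = config.contaminant_count + config.reverse_count + config.unannotated_count
    total = n + n_extra

    ids = [f"PROT{i:05d}" for i in range(1, n + 1)]
    genes = [f"GENE{i:05d}" for i in range(1, n + 1)]
    reverse = np.zeros(total, dtype=bool)
    contaminant = np.zeros(total, dtype=bool)
    k = n
    for j in range(config.contaminant_count):
        ids.append(f"CON__P{j + 1:05d}")
        genes.append(f"KRT{j + 1}")
        contaminant[k] = True
        k += 1
    for j in range(config.reverse_count):
        ids.append(f"REV__P{j + 1:05d}")
        genes.append("")
        reverse[k] = True
        k += 1
    for j in range(config.unannotated_count):
        # non-accession-like id with no gene symbol: removed by the
        # annotation stage of the filter cascade
        ids.append(f"UNANN{j + 1:05d}")
        genes.append("")
        k += 1

    truth = pd.DataFrame(index=pd.Index(ids, name="protein_id"))
    truth["base_log2"] = rng.normal(config.base_log2_mean, config.base_log2_sd, size=total)
    truth["group_effect"] = 0.0
    for tp in TIMEPOINTS:
        truth[f"time_{tp}"] = 0.0
    for g in GROUPS:
        for tp in TIMEPOINTS:
            truth[f"inter_{g}_{tp}"] = 0.0

    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    # Effects are planted so the between-arm difference appears only at
    # POD3.  "divergent" splits it symmetrically (+d on NEVKP, -d on SCS
    # at POD3), which loads the signal onto the interaction term;
    # "cell" bumps the single (NEVKP, POD3) cell, of which only a third
    # projects onto the interaction in a 2x3 layout (markedly lower
    # detection power at equal effect size).
    col = truth.columns.get_loc("inter_NEVKP_POD3")
    truth.iloc[de_idx, col] = config.effect_size_log2
    if config.effect_mode == "divergent":
        col_scs = truth.columns.get_loc("inter_SCS_POD3")
        truth.iloc[de_idx, col_scs] = -config.effect_size_log2
    truth["is_de"] = False
    truth.iloc[de_idx, truth.columns.get_loc("is_de")] = True
    truth["noise_sd"] = config.noise_sd

    latent = _latent_matrix(truth, design, rng)

    loc = calibrate_censor_location(
        latent.to_numpy(), config.censor_scale, config.missing_target_fraction
    )
    truth["censor_location"] = loc
    truth["censor_scale"] = config.censor_scale

    peptides = rng.integers(2, 45, size=total)
    single = rng.random(total) < config.single_peptide_fraction
    peptides[single] = 1
    pep = rng.uniform(0.0, 0.04, size=total)
    viol = rng.random(total) < config.pep_violation_fraction
    pep[viol] = rng.uniform(0.06, 0.5, size=int(viol.sum()))

    table = pd.DataFrame(
        {
            "Majority protein IDs": ids,
            "Gene names": genes,
            "Unique peptides": peptides,
            "PEP": pep,
            "Reverse": np.where(reverse, "+", ""),
            "Potential contaminant": np.where(contaminant, "+", ""),
        }
    )
    for sid in design.sample_ids:
        table[LFQ_PREFIX + sid] = np.exp2(latent[sid].to_numpy())
    return table, SyntheticTruth(truth)


def apply_mnar_censoring(
    matrix: IntensityMatrix, truth: SyntheticTruth, seed: int
) -> IntensityMatrix:
    """Censor a complete log2 matrix left-dependently on intensity.

    Each value ``x`` of protein ``p`` goes missing independently with
    probability ``logistic((censor_location_p - x) / censor_scale_p)``
    (or deterministically when ``x < censor_location_p`` in hard-threshold
    mode, signalled by ``censor_scale`` = +inf conventions are not used;
    see :func:`simulate` for the hard-threshold path).
    """
    values = matrix.values
    if values.isna().any().any():
        raise UserInputError("censoring expects a complete matrix")
    t = truth.table.loc[values.index]
    scale = t["censor_scale"].to_numpy()[:, None]
    if (scale <= 0).any():
        raise UserInputError("censor_scale must be positive")
    loc = t["censor_location"].to_numpy()[:, None]
    rng = np.random.default_rng(seed)
    p_miss = expit((loc - values.to_numpy()) / scale)
    mask = rng.random(values.shape) < p_miss
    out = values.where(~mask)
    return IntensityMatrix(out, matrix.design)


def apply_hard_censoring(matrix: IntensityMatrix, truth: SyntheticTruth) -> IntensityMatrix:
    """Deterministic variant: every value below its censor location is missing."""
    values = matrix.values
    t = truth.table.loc[values.index]
    loc = t["censor_location"].to_numpy()[:, None]
    mask = values.to_numpy() < loc
    return IntensityMatrix(values.where(~mask), matrix.design)


@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate`."""

    config: GeneratorConfig
    design: SampleDesign
    truth: SyntheticTruth
    table: pd.DataFrame          # proteinGroups dialect, raw scale, censored (NaN = missing)
    matrix: IntensityMatrix      # log2, censored, all rows
    complete: IntensityMatrix    # log2, no censoring


def simulate(config: GeneratorConfig, design: SampleDesign | None = None) -> SimulatedDataset:
    """Full generator pipeline: design -> latent table -> MNAR censoring."""
    if design is None:
        design = generate_design(config.n_animals_per_group, list(config.dropout_samples))
    table, truth = generate_dataset(config, design)
    lfq_cols = [LFQ_PREFIX + s for s in design.sample_ids]
    complete_values = pd.DataFrame(
        np.log2(table[lfq_cols].to_numpy()),
        index=pd.Index(table["Majority protein IDs"], name="protein_id"),
        columns=design.sample_ids,
    )
    complete = IntensityMatrix(complete_values, design)
    if config.hard_threshold:
        censored = apply_hard_censoring(complete, truth)
    else:
        censored = apply_mnar_censoring(complete, truth, seed=config.seed + 1)
    table = table.copy()
    mask = censored.values.isna().to_numpy()
    raw = table[lfq_cols].to_numpy()
    raw[mask] = np.nan
    table[lfq_cols] = raw
    return SimulatedDataset(config, design, truth, table, censored, complete)


def write_protein_groups(table: pd.DataFrame, path) -> None:
    """Write a proteinGroups-dialect TSV; missing LFQ values encode as 0."""
    missing = [c for c in PG_META_COLUMNS if c not in table.columns]
    if missing:
        raise UserInputError(f"table missing columns: {missing}")
    out = table.copy()
    lfq_cols = [c for c in out.columns if c.startswith(LFQ_PREFIX)]
    for c in lfq_cols:
        out[c] = out[c].fillna(0.0)
    out.to_csv(path, sep="\t", index=False)
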