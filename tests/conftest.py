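import numpy as np
import pandas as pd
import pytest

from miprot.design import SampleDesign
from miprot.synthetic import (
    DEFAULT_DROPOUT,
    GeneratorConfig,
    LFQ_PREFIX,
    generate_design,
    simulate,
)


@pytest.fixture(scope="session")
def design28() -> SampleDesign:
    """The reference 28-sample layout (two dropouts in early timepoints)."""
    return generate_design(5, list(DEFAULT_DROPOUT))


@pytest.fixture(scope="session")
def design30() -> SampleDesign:
    return generate_design(5, [])


@pytest.fixture(scope="session")
def small_sim():
    """Small planted-effect simulation shared by read-only tests."""
    cfg = GeneratorConfig(
        n_proteins=150,
        de_fraction=0.1,
        effect_size_log2=2.0,
        missing_target_fraction=0.15,
        noise_sd=0.5,
        seed=11,
        contaminant_count=5,
        reverse_count=5,
        pep_violation_fraction=0.0,
        single_peptide_fraction=0.0,
    )
    return simulate(cfg)


def make_cascade_fixture(design: SampleDesign) -> pd.DataFrame:
    """Ten-protein table exercising every stage of the filter cascade.

    2 reverse + 1 contaminant (stage 1), 1 with PEP 0.2 (stage 2),
    1 too sparse (stage 4), 1 single-peptide (stage 5), 4 clean:
    hand-derived stage counts are 10 -> 7 -> 6 -> 5 -> 4.
    """
    samples = design.sample_ids
    rng = np.random.default_rng(0)

    def full_row():
        return {LFQ_PREFIX + s: float(2 ** rng.uniform(20, 30)) for s in samples}

    def sparse_row():
        # 4 observed samples within every timepoint: fails the >=5 rule
        vals = {LFQ_PREFIX + s: 0.0 for s in samples}
        for tp in ("BL", "R30", "POD3"):
            for s in design.samples(timepoint=tp)[:4]:
                vals[LFQ_PREFIX + s] = float(2 ** rng.uniform(20, 30))
        return vals

    rows = []

    def add(pid, gene, peptides=10, pep=0.01, reverse="", contaminant="", lfq=None):
        rows.append(
            {
                "Majority protein IDs": pid,
                "Gene names": gene,
                "Unique peptides": peptides,
                "PEP": pep,
                "Reverse": reverse,
                "Potential contaminant": contaminant,
                **(lfq or full_row()),
            }
        )

    add("REV__P00001", "", reverse="+")
    add("REV__P00002", "", reverse="+")
    add("CON__P00001", "KRT1", contaminant="+")
    add("PROT00001", "GENE1", pep=0.2)
    add("PROT00002", "GENE2", lfq=sparse_row())
    add("PROT00003", "GENE3", peptides=1)
    add("PROT00004", "GENE4")
    add("PROT00005", "GENE5")
    add("PROT00006", "GENE6")
    add("PROT00007", "GENE7")
    return pd.DataFrame(rows)


@pytest.fixture()
def cascade_fixture(design28) -> pd.DataFrame:
    return make_cascade_fixture(design28)
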