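"""Run orchestration: simulate -> filter -> impute -> detest -> cluster.

A single YAML/JSON config drives the stage sequence; every stage writes
its outputs into the run directory and the run closes with a manifest
listing parameters, seeds, stage counts and a checksum for every file
produced.  Reruns with the same config are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .design import SampleDesign
from .diffexp import call_de
from .errors import MiprotError, UserInputError
from .impute import build_ensemble
from .ingest import filter_cascade, read_protein_groups
from .structure import cluster_heatmap, cluster_profiles, pca
from .synthetic import GeneratorConfig, simulate, write_protein_groups

DIRECTION_COLUMN = "Increased expression in"
TIMEPOINT_COLUMN = "Time point of significance"


def packaged_de_table_path():
    """Path of the packaged machine-readable differential-expression table."""
    return resources.files("miprot").joinpath("data/de_table.tsv")


def table1_audit(de_table) -> dict:
    """Tally a DE table: total rows, rows per direction, rows per timepoint."""
    if not isinstance(de_table, pd.DataFrame):
        de_table = pd.read_csv(de_table, sep="\t")
    for col in (DIRECTION_COLUMN, TIMEPOINT_COLUMN):
        if col not in de_table.columns:
            raise UserInputError(f"DE table missing column: {col!r}")
    return {
        "total": int(len(de_table)),
        "by_direction": de_table[DIRECTION_COLUMN].value_counts().to_dict(),
        "by_timepoint": de_table[TIMEPOINT_COLUMN].value_counts().to_dict(),
    }


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from one YAML/JSON file."""

    out_dir: str
    seed: int = 0
    simulate: dict | None = None           # GeneratorConfig fields
    protein_groups: str | None = None      # used when simulate is absent
    design: str | None = None
    filter: dict = field(default_factory=dict)
    impute: dict = field(default_factory=lambda: {"n_replicates": 20})
    detest: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=lambda: {"k": 8})

    def __post_init__(self) -> None:
        if self.simulate is None and (self.protein_groups is None or self.design is None):
            raise UserInputError(
                "config needs either a 'simulate' section or both "
                "'protein_groups' and 'design' paths"
            )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise UserInputError("config file must hold a mapping")
        return cls(**data)

    def to_file(self, path) -> None:
        payload = {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "simulate": self.simulate,
            "protein_groups": self.protein_groups,
            "design": self.design,
            "filter": self.filter,
            "impute": self.impute,
            "detest": self.detest,
            "cluster": self.cluster,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


class StageError(MiprotError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the stage sequence; return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "miprot_version": __version__,
        "seed": config.seed,
        "stages": {},
        "files": {},
    }

    def run_stage(name: str, fn):
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:  # annotate with the failing stage
            _write_manifest(out, manifest)
            raise StageError(name, exc) from exc

    # -- simulate / load ---------------------------------------------------
    truth = None
    if config.simulate is not None:
        def _simulate():
            gen_cfg = GeneratorConfig.from_dict({"seed": config.seed, **config.simulate})
            sim = simulate(gen_cfg)
            write_protein_groups(sim.table, out / "protein_groups.tsv")
            sim.design.to_csv(out / "design.csv")
            sim.truth.to_json(out / "truth.json")
            manifest["stages"]["simulate"] = {
                "config": gen_cfg.to_dict(),
                "n_rows": int(len(sim.table)),
                "n_samples": sim.design.n_samples,
            }
            return sim.design, out / "protein_groups.tsv", sim.truth

        design, pg_path, truth = run_stage("simulate", _simulate)
    else:
        design = SampleDesign.from_csv(config.design)
        pg_path = Path(config.protein_groups)

    # -- filter ------------------------------------------------------------
    def _filter():
        records = read_protein_groups(pg_path, design)
        matrix, report = filter_cascade(records, design, **config.filter)
        if matrix.shape[0] == 0:
            raise UserInputError("empty analysis matrix after filtering")
        report.to_json(out / "filter_report.json")
        matrix.to_tsv(out / "matrix.tsv")
        manifest["stages"]["filter"] = {
            "counts": report.counts(),
            "parameters": report.parameters,
        }
        return matrix

    matrix = run_stage("filter", _filter)

    # -- impute ------------------------------------------------------------
    def _impute():
        ens = build_ensemble(matrix, master_seed=config.seed, **config.impute)
        with open(out / "imputation.json", "w") as fh:
            json.dump(
                {
                    "n_replicates": ens.n_replicates,
                    "replicate_seeds": ens.replicate_seeds,
                    "tune_sigma": ens.tune_sigma,
                    "fits": {sid: f.to_dict() for sid, f in ens.fits.items()},
                },
                fh,
                indent=2,
            )
        manifest["stages"]["impute"] = {
            "n_replicates": ens.n_replicates,
            "missing_fraction": matrix.missing_fraction(),
        }
        return ens

    ensemble = run_stage("impute", _impute)

    # -- differential expression ------------------------------------------
    def _detest():
        de = call_de(ensemble, **config.detest)
        de.to_tsv(out / "de_table.tsv")
        manifest["stages"]["detest"] = {
            "alpha": de.alpha,
            "de_term": de.de_term,
            "n_significant": int(de.table["significant"].sum()),
        }
        return de

    de = run_stage("detest", _detest)

    # -- structure ---------------------------------------------------------
    def _cluster():
        first = ensemble.replicates[0]
        pca_res = pca(first)
        pca_res.scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample_id")
        with open(out / "pca_variance.json", "w") as fh:
            json.dump({"explained_variance_fraction": pca_res.explained_variance_fraction.tolist()}, fh)
        info = {"pca_pc1_fraction": float(pca_res.explained_variance_fraction[0])}
        sig = de.significant_ids
        k = int(config.cluster.get("k", 8))
        if len(sig) >= max(k, 2):
            sub = first.values.loc[sig]
            assignment = cluster_heatmap(sub, k=k)
            assignment.to_tsv(out / "clusters.tsv")
            profiles = cluster_profiles(sub, assignment, design)
            profiles.to_csv(out / "cluster_profiles.tsv", sep="\t", index=False)
            info["k"] = assignment.k
            info["n_clustered"] = len(sig)
        else:
            info["skipped"] = f"only {len(sig)} significant proteins (< k={k})"
        manifest["stages"]["cluster"] = info

    run_stage("cluster", _cluster)

    # -- truth recovery (synthetic runs only) ------------------------------
    if truth is not None:
        def _recover():
            true_de = set(truth.de_protein_ids)
            called = set(de.significant_ids)
            analyzed = set(de.table.index)
            tp = len(called & true_de)
            fp = len(called - true_de)
            fn = len((true_de & analyzed) - called)
            recovery = {
                "n_true_de": len(true_de),
                "n_true_de_analyzed": len(true_de & analyzed),
                "n_called": len(called),
                "true_positives": tp,
                "false_positives": fp,
                "false_negatives": fn,
                "sensitivity": tp / max(len(true_de & analyzed), 1),
                "false_discovery_proportion": fp / max(len(called), 1),
            }
            with open(out / "truth_recovery.json", "w") as fh:
                json.dump(recovery, fh, indent=2)
            manifest["stages"]["truth_recovery"] = recovery

        run_stage("truth_recovery", _recover)

    _write_manifest(out, manifest)
    return out


def _write_manifest(out: Path, manifest: dict) -> None:
    files = {}
    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            files[p.name] = _sha256(p)
    manifest["files"] = files
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
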