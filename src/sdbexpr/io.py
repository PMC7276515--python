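"""Readers and writers for the pipeline's file formats.

Canonical table dialect is tab-delimited with a header row; gene sets
use GMT; ranked lists use two-column .rnk. Output tables carry comment
lines recording the package version, seed and thresholds so every
artifact is traceable to its run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import ExpressionStudy
from .enrichment import GeneSetCollection
from .treatment import PairedStudy

__all__ = ["read_expression", "write_expression", "read_transcript_map",
           "write_transcript_map", "read_phenotypes", "read_gmt",
           "write_gmt", "read_rnk", "write_rnk", "read_table",
           "write_table", "read_config", "PipelineConfig",
           "load_expression_study"]


def read_expression(path) -> pd.DataFrame:
    """Samples x transcripts matrix; first column is the sample ID."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample ID {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate transcript ID {dup!r}")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_transcript_map(path) -> dict[str, str]:
    """Two-column TSV (transcript_id, gene_symbol)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: transcript map must have two columns")
    if df.iloc[:, 0].duplicated().any():
        dup = df.iloc[:, 0][df.iloc[:, 0].duplicated()].iloc[0]
        raise ValueError(f"{path}: transcript {dup!r} mapped twice")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_transcript_map(tmap: dict[str, str], path) -> None:
    pd.DataFrame(sorted(tmap.items()),
                 columns=["transcript_id", "gene_symbol"]).to_csv(
        path, sep="\t", index=False)


def read_phenotypes(path, required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in required or []:
        if col not in df.columns:
            raise ValueError(f"{path}: phenotype table lacks column {col!r}")
    return df


def load_expression_study(name: str, expression_path, map_path,
                          phenotype_path, stratum_col="stratum",
                          group_col="group") -> ExpressionStudy:
    expr = read_expression(expression_path)
    tmap = read_transcript_map(map_path)
    ph = read_phenotypes(phenotype_path, required=[stratum_col, group_col])
    ph = ph.loc[expr.index]
    return ExpressionStudy(name=name, expression=expr, transcript_map=tmap,
                           phenotypes=ph, stratum_col=stratum_col,
                           group_col=group_col)


# ---------------------------------------------------------------------------
# gene sets / ranked lists

def read_gmt(path) -> GeneSetCollection:
    sets, desc = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated "
                    f"fields (name, description, members)")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set {name!r}")
            sets[name] = set(parts[2:])
            desc[name] = parts[1]
    return GeneSetCollection(sets=sets, descriptions=desc,
                             source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "na")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_rnk(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene", "score"])
    return df


def write_rnk(ranked: pd.DataFrame, path) -> None:
    ranked[["gene", "score"]].to_csv(path, sep="\t", header=False,
                                     index=False)


# ---------------------------------------------------------------------------
# generic result tables with provenance header

def write_table(df: pd.DataFrame, path, seed=None,
                thresholds: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sdbexpr {__version__}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if thresholds:
            fh.write(f"# thresholds: {json.dumps(thresholds, sort_keys=True)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# pipeline configuration

@dataclass
class PipelineConfig:
    """File paths, model choices and thresholds for a full run."""

    cohort_a: dict = field(default_factory=dict)   # expression/map/phenotypes
    cohort_b: dict = field(default_factory=dict)
    paired: dict = field(default_factory=dict)     # pre/post paths
    gene_sets: str | None = None
    traits: list = field(default_factory=lambda: ["AHI", "avgO2", "minO2"])
    covariates_a: list = field(default_factory=list)
    covariates_b: list = field(default_factory=list)
    include_bmi: bool = False
    discovery_q: float = 0.05
    replication_p: float = 0.05
    treatment_p: float = 0.05
    enrichment_q: float = 0.05
    overlap_coefficient: float = 0.25
    n_permutations: int = 1000
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("discovery_q", "replication_p", "treatment_p",
                     "enrichment_q", "overlap_coefficient"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"threshold {name} must be in (0,1), got {v}")
        if not self.traits:
            raise ValueError("trait list is empty")

    def thresholds(self) -> dict:
        return {"discovery_q": self.discovery_q,
                "replication_p": self.replication_p,
                "treatment_p": self.treatment_p,
                "enrichment_q": self.enrichment_q,
                "overlap_coefficient": self.overlap_coefficient}


def read_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = PipelineConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    for section in (cfg.cohort_a, cfg.cohort_b, cfg.paired):
        for key, p in section.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"configured file missing: {key}={p}")
    if cfg.gene_sets and not Path(cfg.gene_sets).exists():
        raise FileNotFoundError(f"configured file missing: {cfg.gene_sets}")
    return cfg
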