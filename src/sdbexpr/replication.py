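"""Cross-replication of discovery transcripts in a second cohort.

Discovery transcripts passing a per-trait FDR gate (q < 0.05) are
matched "many to many" to every transcript of the same gene symbol on
the replication platform. A gene replicates when any matched transcript
shows a one-sided p < 0.05 in the direction of the discovery effect.
Both cohorts serve once as discovery and once as replication, and the
replicated gene lists are unioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_stats import bh_fdr, one_sided_p

__all__ = ["select_discoveries", "match_many_to_many", "cross_replicate",
           "CrossReplicationResult"]

DISCOVERY_Q = 0.05
REPLICATION_P = 0.05


def select_discoveries(assoc: pd.DataFrame, trait: str,
                       q_threshold: float = DISCOVERY_Q) -> pd.DataFrame:
    """Per-trait BH-FDR across all transcripts; keep rows with q below
    the threshold. The FDR family is the single trait within the
    discovery cohort — traits are never pooled."""
    if assoc.empty:
        raise ValueError("empty association table")
    sub = assoc[assoc["trait"] == trait].copy()
    if sub.empty:
        raise ValueError(f"trait {trait!r} absent from association table")
    sub["q"] = bh_fdr(sub["p"].to_numpy()).q
    return sub[sub["q"] < q_threshold].copy()


def match_many_to_many(discoveries: pd.DataFrame,
                       replication_map: dict[str, str]) -> pd.DataFrame:
    """Pair each discovery transcript with every replication-platform
    transcript sharing its gene symbol (exact, case-sensitive match).

    Discovery transcripts without a partner get one row with a null
    replication transcript, so unmatched genes stay visible downstream.
    """
    by_gene: dict[str, list[str]] = {}
    for t, g in replication_map.items():
        by_gene.setdefault(g, []).append(t)
    rows = []
    for _, d in discoveries.iterrows():
        partners = sorted(by_gene.get(d["gene"], []))
        if not partners:
            rows.append({"d_transcript": d["transcript"], "gene": d["gene"],
                         "r_transcript": None})
            continue
        for r in partners:
            rows.append({"d_transcript": d["transcript"], "gene": d["gene"],
                         "r_transcript": r})
    return pd.DataFrame(rows, columns=["d_transcript", "gene", "r_transcript"])


@dataclass
class CrossReplicationResult:
    """Record table plus derived gene lists for one or both directions."""

    records: pd.DataFrame
    replicated_genes: list[str] = field(default_factory=list)
    unmatched_genes: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        rec = self.records
        return {
            "n_discovery_transcripts": int(rec["d_transcript"].nunique()),
            "n_matched_pairs": int(rec["r_transcript"].notna().sum()),
            "n_unmatched_genes": len(self.unmatched_genes),
            "n_replicated_genes": len(self.replicated_genes),
        }


def _replicate_one_direction(discovery_assoc: pd.DataFrame,
                             replication_assoc: pd.DataFrame,
                             replication_map: dict[str, str],
                             trait: str,
                             q_threshold: float,
                             p_threshold: float) -> CrossReplicationResult:
    disc = select_discoveries(discovery_assoc, trait, q_threshold)
    # a zero discovery effect has no direction and cannot seed a
    # one-sided replication test
    disc = disc[disc["beta"] != 0]
    matches = match_many_to_many(disc, replication_map)
    rep = replication_assoc[replication_assoc["trait"] == trait]
    rep_by_t = rep.set_index("transcript")
    rows = []
    for _, d in disc.iterrows():
        mine = matches[matches["d_transcript"] == d["transcript"]]
        expected = int(np.sign(d["beta"]))
        for _, m in mine.iterrows():
            rt = m["r_transcript"]
            if rt is None or rt not in rep_by_t.index:
                rows.append({**_disc_cols(d, trait), "r_transcript": None,
                             "one_sided_p": np.nan, "pair_replicates": False})
                continue
            r = rep_by_t.loc[rt]
            p1 = one_sided_p(float(r["p"]), int(np.sign(r["beta"])), expected)
            rows.append({**_disc_cols(d, trait), "r_transcript": rt,
                         "one_sided_p": p1,
                         "pair_replicates": bool(p1 < p_threshold)})
    cols = ["d_transcript", "gene", "trait", "sign", "discovery_p",
            "discovery_q", "r_transcript", "one_sided_p", "pair_replicates"]
    records = pd.DataFrame(rows, columns=cols)
    if not records.empty:
        gene_flag = records.groupby("gene")["pair_replicates"].any()
        replicated = sorted(gene_flag[gene_flag].index)
        unmatched = sorted(set(records.loc[records["r_transcript"].isna(),
                                           "gene"])
                           - set(records.loc[records["r_transcript"].notna(),
                                             "gene"]))
    else:
        replicated, unmatched = [], []
    return CrossReplicationResult(records=records,
                                  replicated_genes=replicated,
                                  unmatched_genes=unmatched)


def _disc_cols(d, trait):
    return {"d_transcript": d["transcript"], "gene": d["gene"],
            "trait": trait, "sign": int(np.sign(d["beta"])),
            "discovery_p": float(d["p"]), "discovery_q": float(d["q"])}


def cross_replicate(assoc_a: pd.DataFrame, assoc_b: pd.DataFrame,
                    map_a: dict[str, str], map_b: dict[str, str],
                    trait: str,
                    q_threshold: float = DISCOVERY_Q,
                    p_threshold: float = REPLICATION_P,
                    ) -> CrossReplicationResult:
    """Bidirectional cross-replication for one trait.

    Runs A-as-discovery/B-as-replication and the reverse, concatenates
    the record tables (a ``direction`` column distinguishes them) and
    unions the replicated gene lists; a gene counts once even if found
    in both directions.
    """
    for assoc, label in ((assoc_a, "first"), (assoc_b, "second")):
        if assoc.empty or trait not in set(assoc["trait"]):
            raise ValueError(f"trait {trait!r} absent from {label} cohort")
    fwd = _replicate_one_direction(assoc_a, assoc_b, map_b, trait,
                                   q_threshold, p_threshold)
    rev = _replicate_one_direction(assoc_b, assoc_a, map_a, trait,
                                   q_threshold, p_threshold)
    fwd.records["direction"] = "A->B"
    rev.records["direction"] = "B->A"
    frames = [df for df in (fwd.records, rev.records) if not df.empty]
    records = (pd.concat(frames, ignore_index=True) if frames
               else fwd.records)
    return CrossReplicationResult(
        records=records,
        replicated_genes=sorted(set(fwd.replicated_genes)
                                | set(rev.replicated_genes)),
        unmatched_genes=sorted(set(fwd.unmatched_genes)
                               | set(rev.unmatched_genes)),
    )
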