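"""Published summary-statistic fixtures and the decision logic over them.

Machine-readable transcriptions of the two published result tables —
the cross-replication table (per-transcript discovery p/q, one-sided
cross-replication p and one-sided treatment p) and the meta-analysis
table (per-pair meta p/q and one-sided treatment p) — exercise the
pipeline's decision rules end-to-end without any raw cohort data:
FDR gate, direction-consistent replication, meta-gene selection, route
union, and the treatment-response call.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .meta import combine_discoveries, select_meta_genes
from .replication import DISCOVERY_Q, REPLICATION_P
from .treatment import RESPONDING_P

__all__ = ["load_cross_replication_table", "load_meta_analysis_table",
           "cross_replicated_genes", "meta_genes", "combined_genes",
           "responding_genes", "fixture_summary"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("sdbexpr.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"fos_probeset": str,
                                                "entrez_id": str})


def load_cross_replication_table() -> pd.DataFrame:
    """Per-transcript cross-replication records (10 rows, 8 genes)."""
    return _load("cross_replication_table.tsv")


def load_meta_analysis_table() -> pd.DataFrame:
    """Per-pair meta-analysis records (28 rows, 21 genes)."""
    return _load("meta_analysis_table.tsv")


def cross_replicated_genes(q_threshold: float = DISCOVERY_Q,
                           p_threshold: float = REPLICATION_P) -> list[str]:
    """Genes passing the bidirectional rule: discovery FDR q below the
    gate and a direction-consistent one-sided replication p below the
    threshold for at least one matched transcript."""
    t = load_cross_replication_table()
    ok = t[(t["discovery_q"] < q_threshold)
           & (t["cross_replication_p"] < p_threshold)]
    return sorted(ok["gene"].unique())


def meta_genes(q_threshold: float = 0.05) -> list[str]:
    """Genes with at least one transcript pair under the meta-analysis
    FDR gate."""
    t = load_meta_analysis_table()
    return select_meta_genes(t.assign(meta_q=t["meta_q"]),
                             q_threshold=q_threshold)


def combined_genes() -> pd.DataFrame:
    """Union of the two discovery routes with provenance tags."""
    return combine_discoveries(cross_replicated_genes(), meta_genes())


def responding_genes(p_threshold: float = RESPONDING_P) -> list[str]:
    """Carried-forward genes whose one-sided treatment-replication p is
    below the threshold in at least one discovery record."""
    records = pd.concat([
        load_cross_replication_table()[["gene", "heartbeat_p"]],
        load_meta_analysis_table()[["gene", "heartbeat_p"]],
    ], ignore_index=True)
    carried = set(combined_genes()["gene"])
    records = records[records["gene"].isin(carried)]
    flag = records.groupby("gene")["heartbeat_p"].min() < p_threshold
    return sorted(flag[flag].index)


def fixture_summary() -> dict:
    """Gene counts per route over the published fixtures."""
    combined = combined_genes()
    return {
        "cross_replicated_genes": len(cross_replicated_genes()),
        "meta_genes": len(meta_genes()),
        "combined_genes": len(combined),
        "meta_only_genes": int((combined["route"] == "meta-only").sum()),
        "responding_genes": len(responding_genes()),
    }
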