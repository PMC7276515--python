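"""Cohort-level meta-analysis over many-to-many matched transcript pairs.

Every transcript of one platform is paired with every transcript of the
same gene on the other platform (no discovery gate), the pair's two
per-SD effect estimates are combined by inverse-variance fixed-effects
meta-analysis, and BH-FDR is applied across all pairs of a trait. Genes
with at least one pair under the q threshold are carried forward, and
finally unioned with the cross-replication gene list.

Effects are combined on the per-SD-of-trait scale because the two
platforms' raw units are not comparable. A transcript matched to
several partners contributes several non-independent pairs; no
correlation adjustment is applied (a known caveat of the procedure).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import combine_calibrated_p
from .core_stats import EffectEstimate, bh_fdr, inverse_variance_meta

__all__ = ["meta_analyze", "select_meta_genes", "combine_discoveries"]

META_Q = 0.05


def meta_analyze(assoc_a: pd.DataFrame, assoc_b: pd.DataFrame,
                 trait: str, p_method: str = "calibrated-z") -> pd.DataFrame:
    """Pairwise meta-analysis of two cohorts' association tables.

    Association tables are the output of ``association.fit_study`` and
    already carry the gene symbol and per-SD effect columns. Returns one
    row per matched pair with combined beta/se (per-SD scale), meta p
    and meta q. Symmetric in cohort order up to swapping the pair-label
    columns.

    ``p_method`` selects the combined p: ``"calibrated-z"`` (default)
    combines the cohorts' calibrated p-values as signed z-scores with
    sqrt(n) weights, which stays calibrated when cohort SEs carry few
    degrees of freedom; ``"ivw-normal"`` is the large-sample normal
    approximation on the IVW combined z. Effect and SE are
    inverse-variance fixed-effects under both.
    """
    if p_method not in ("calibrated-z", "ivw-normal"):
        raise ValueError("p_method must be 'calibrated-z' or 'ivw-normal'")
    a = assoc_a[assoc_a["trait"] == trait]
    b = assoc_b[assoc_b["trait"] == trait]
    if a.empty or b.empty:
        raise ValueError(f"trait {trait!r} missing from a cohort")
    merged = a.merge(b, on=["gene", "trait"], suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("platforms share no gene symbols")
    rows = []
    for _, r in merged.iterrows():
        parts = [
            EffectEstimate(r["beta_sd_a"], r["se_sd_a"], r["p_a"], int(r["n_a"])),
            EffectEstimate(r["beta_sd_b"], r["se_sd_b"], r["p_b"], int(r["n_b"])),
        ]
        est = inverse_variance_meta(parts)
        p = (combine_calibrated_p(parts) if p_method == "calibrated-z"
             else est.p_two)
        rows.append({
            "transcript_a": r["transcript_a"],
            "transcript_b": r["transcript_b"],
            "gene": r["gene"], "trait": trait,
            "beta_sd": est.beta, "se_sd": est.se,
            "sign": est.sign, "meta_p": p, "n": est.n,
        })
    out = pd.DataFrame(rows)
    out["meta_q"] = bh_fdr(out["meta_p"].to_numpy()).q
    return out


def select_meta_genes(meta: pd.DataFrame,
                      q_threshold: float = META_Q) -> list[str]:
    """Distinct gene symbols with >=1 pair under the q threshold for
    >=1 trait. ``meta`` may be the concatenation of several traits'
    tables."""
    if meta.empty:
        raise ValueError("empty meta-analysis table")
    hits = meta[meta["meta_q"] < q_threshold]
    return sorted(hits["gene"].unique())


def combine_discoveries(cross_rep_genes: list[str],
                        meta_genes: list[str]) -> pd.DataFrame:
    """Deduplicated union of the two discovery routes, with provenance.

    Returns a table (gene, route) where route is ``cross-replication``,
    ``meta-only`` or ``both``.
    """
    cross = set(cross_rep_genes)
    meta_ = set(meta_genes)
    rows = []
    for g in sorted(cross | meta_):
        if g in cross and g in meta_:
            route = "both"
        elif g in cross:
            route = "cross-replication"
        else:
            route = "meta-only"
        rows.append({"gene": g, "route": route})
    return pd.DataFrame(rows, columns=["gene", "route"])
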