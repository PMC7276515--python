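"""Paired pre/post treatment analysis and sign-constrained replication.

Genes carried forward from discovery are tested in a paired pre/post
CPAP cohort: a paired t-test on per-subject log2 expression differences
gives a two-sided p and a mean fold change; the replication test is
one-sided, constrained so that a gene only counts as responding when
its expression moves *against* its severity association (genes higher
with more severe SDB should fall after effective treatment, and vice
versa).

Severity polarity: AHI higher = more severe; avgO2/minO2 higher = less
severe. Hence the severity association of an effect is its sign for
AHI and the negated sign for the oxygen-saturation traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import TRAITS
from .core_stats import one_sided_p

__all__ = ["PairedStudy", "paired_test", "paired_test_all",
           "expected_direction", "treatment_replicate"]

RESPONDING_P = 0.05


@dataclass
class PairedStudy:
    """Pre- and post-treatment expression for the same subjects.

    ``expr_pre`` and ``expr_post`` are subjects x genes DataFrames on
    log2 scale with identical index and columns.
    """

    expr_pre: pd.DataFrame
    expr_post: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.expr_pre.index.equals(self.expr_post.index):
            raise ValueError("pre/post subject IDs differ")
        if not self.expr_pre.columns.equals(self.expr_post.columns):
            raise ValueError("pre/post gene columns differ")
        if len(self.expr_pre) < 2:
            raise ValueError("paired analysis needs >=2 subjects")

    @property
    def genes(self) -> pd.Index:
        return self.expr_pre.columns


def paired_test(study: PairedStudy, gene: str) -> dict:
    """Paired t-test of post vs pre for one gene.

    Expression is assumed log2-scale, so the per-subject difference is
    the log2 fold change and ``mean_fc = 2**mean(d)``. Subjects with a
    missing pre or post value are dropped pairwise. Zero-variance
    differences yield t=NaN, p=1 (never "responding").
    """
    d = (study.expr_post[gene] - study.expr_pre[gene]).dropna().to_numpy()
    if len(d) < 2:
        raise ValueError(f"gene {gene!r}: <2 complete pairs")
    mean_d = float(np.mean(d))
    mean_fc = float(2.0 ** mean_d)
    if np.std(d, ddof=1) == 0:
        t, p = np.nan, 1.0
    else:
        t, p = stats.ttest_rel(study.expr_post[gene].to_numpy(),
                               study.expr_pre[gene].to_numpy(),
                               nan_policy="omit")
        t, p = float(t), float(p)
    direction = 1 if mean_fc > 1 else -1
    return {"gene": gene, "n_pairs": len(d), "mean_fc": mean_fc,
            "t": t, "p_two": max(p, np.finfo(float).tiny),
            "direction": direction}


def paired_test_all(study: PairedStudy) -> pd.DataFrame:
    """Vectorized paired t-tests for every gene in the study.

    Same statistic as :func:`paired_test`; used to rank the whole
    transcriptome by treatment response for enrichment analysis.
    """
    d = (study.expr_post - study.expr_pre).to_numpy(dtype=float)
    n = d.shape[0]
    mean_d = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(sd == 0, 1.0, p)
    t = np.where(sd == 0, np.nan, t)
    return pd.DataFrame({
        "gene": study.genes,
        "n_pairs": n,
        "mean_fc": 2.0 ** mean_d,
        "t": t,
        "p_two": np.maximum(p, np.finfo(float).tiny),
        "direction": np.where(mean_d > 0, 1, -1),
    })


def expected_direction(discovery_trait: str, discovery_sign: int) -> int:
    """Expected post-treatment direction for a carried-forward gene.

    A gene positively associated with severity should *decrease* after
    treatment (expected sign -1, fold change < 1), and vice versa.
    """
    if discovery_trait not in TRAITS:
        raise ValueError(f"unknown trait {discovery_trait!r}")
    if discovery_sign not in (-1, 1):
        raise ValueError("discovery sign must be -1 or +1")
    severity_assoc = (discovery_sign if discovery_trait == "AHI"
                      else -discovery_sign)
    return -severity_assoc


def treatment_replicate(carried: pd.DataFrame, study: PairedStudy,
                        p_threshold: float = RESPONDING_P,
                        require_unanimity: bool = False) -> pd.DataFrame:
    """Sign-constrained one-sided treatment test per carried record.

    ``carried`` has columns (gene, trait, sign) — one row per discovery
    record; a gene may appear under several traits. Each row gets its
    own expected direction and one-sided p; the gene-level
    ``responding`` flag is "any record passes" by default, or "all
    records pass" with ``require_unanimity``. Carried genes absent from
    the paired study are reported with null statistics and
    responding=False.
    """
    rows = []
    cache: dict[str, dict] = {}
    for _, rec in carried.iterrows():
        gene, trait, sign = rec["gene"], rec["trait"], int(rec["sign"])
        if gene not in study.genes:
            rows.append({"gene": gene, "trait": trait, "sign": sign,
                         "in_paired_study": False, "n_pairs": 0,
                         "mean_fc": np.nan, "t": np.nan, "p_two": np.nan,
                         "expected_direction": expected_direction(trait, sign),
                         "one_sided_p": np.nan, "responding": False})
            continue
        if gene not in cache:
            cache[gene] = paired_test(study, gene)
        pt = cache[gene]
        exp_dir = expected_direction(trait, sign)
        p1 = one_sided_p(pt["p_two"], pt["direction"], exp_dir)
        rows.append({"gene": gene, "trait": trait, "sign": sign,
                     "in_paired_study": True, "n_pairs": pt["n_pairs"],
                     "mean_fc": pt["mean_fc"], "t": pt["t"],
                     "p_two": pt["p_two"], "expected_direction": exp_dir,
                     "one_sided_p": p1,
                     "responding": bool(p1 < p_threshold)})
    out = pd.DataFrame(rows)
    if not out.empty:
        agg = all if require_unanimity else any
        gene_flag = out.groupby("gene")["responding"].agg(
            lambda s: agg(bool(v) for v in s))
        out["gene_responding"] = out["gene"].map(gene_flag)
    return out
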