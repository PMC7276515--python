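"""Preranked permutation gene-set enrichment.

The transcriptome is ranked by a signed per-gene statistic (association
z for a trait, or the paired t statistic for treatment response) and
each gene set is scored with the weighted Kolmogorov-Smirnov running
statistic: hits increment the running sum by |score|^weight normalized
over hits, misses decrement by 1/(N - set size); the enrichment score
(ES) is the signed maximal deviation from zero. Significance comes from
gene-label permutations (set membership randomized, ranked scores
fixed): per-set permutation p, NES = ES / mean(|null ES| of the same
sign), and FDR q from the pooled null NES distribution. Overlap edges
between significant sets use the overlap coefficient
|A∩B| / min(|A|, |B|).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneSetCollection", "build_ranked_list", "enrichment_score",
           "permute_and_score", "overlap_edges"]

MIN_SET_SIZE = 10
MAX_SET_SIZE = 500
ENRICHMENT_Q = 0.05
OVERLAP_THRESHOLD = 0.25


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. parsed from a GMT file)."""

    sets: dict[str, set]
    source: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) < 1:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def build_ranked_list(table: pd.DataFrame,
                      transcript_map: dict[str, str] | None = None,
                      seed: int | np.random.Generator = 0,
                      stat_col: str | None = None) -> pd.DataFrame:
    """Collapse a per-transcript statistic table to one score per gene.

    When a gene has several transcripts, one is selected uniformly at
    random under ``seed`` (the convention for multi-probe platforms).
    Returns a (gene, score) frame ordered by score descending, ties
    broken by gene symbol, ready to write as a .rnk file.
    """
    if table.empty:
        raise ValueError("empty statistics table")
    df = table.copy()
    if "gene" not in df.columns:
        if transcript_map is None:
            raise ValueError("need transcript_map when table lacks genes")
        df["gene"] = df["transcript"].map(transcript_map)
    if stat_col is None:
        if "beta" in df.columns and "se" in df.columns:
            df["score"] = df["beta"] / df["se"]
        elif "t" in df.columns:
            df["score"] = df["t"]
        elif "score" not in df.columns:
            raise ValueError("no statistic column found")
        stat_col = "score"
    else:
        df["score"] = df[stat_col]
    if df["score"].isna().any():
        raise ValueError("NaN scores in ranked list input")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    # stable random pick of one transcript per gene
    df = df.sample(frac=1.0, random_state=np.random.RandomState(
        rng.integers(2**31))).groupby("gene", sort=False).head(1)
    out = df[["gene", "score"]].sort_values(
        ["score", "gene"], ascending=[False, True]).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# enrichment score

def _es_from_positions(scores: np.ndarray, positions: np.ndarray,
                       weight: float) -> float:
    """ES from the sorted hit positions of one set; O(K) per evaluation.

    The running sum only changes slope at hits, so its extrema are
    attained immediately after a hit or immediately before one.
    """
    N = len(scores)
    K = len(positions)
    if K == 0:
        raise ValueError("set has no members in the ranked list")
    if K == N:
        return 0.0  # set equals the universe: no enrichment information
    pos = np.sort(positions)
    w = np.abs(scores[pos]) ** weight
    total = w.sum()
    if total == 0:  # all-zero scores under positive weight
        w = np.ones(K)
        total = float(K)
    hit_cum = np.cumsum(w) / total
    k = np.arange(1, K + 1)
    miss_after = (pos + 1 - k) / (N - K)     # misses up to & incl. pos_k
    miss_before = (pos - (k - 1)) / (N - K)  # misses strictly before pos_k
    after = hit_cum - miss_after
    before = np.concatenate([[0.0], hit_cum[:-1]]) - miss_before
    cand = np.concatenate([after, before])
    return float(cand[np.argmax(np.abs(cand))])


def enrichment_score(ranked: pd.DataFrame, members, weight: float = 1.0):
    """ES, full running sum, and leading-edge genes for one set.

    ``ranked`` is the (gene, score) output of ``build_ranked_list``;
    ``members`` any iterable of gene symbols. Raises if no member
    appears in the ranked list.
    """
    genes = ranked["gene"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    N = len(genes)
    hit = np.isin(genes, list(members))
    K = int(hit.sum())
    if K == 0:
        raise ValueError("set has no members in the ranked list")
    if K == N:
        return 0.0, np.zeros(N), []
    w = np.abs(scores) ** weight
    w_hit = np.where(hit, w, 0.0)
    total = w_hit.sum()
    if total == 0:
        w_hit = hit.astype(float)
        total = float(K)
    running = np.cumsum(w_hit / total - (~hit) / (N - K))
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    if es >= 0:
        leading = genes[: i_ext + 1][hit[: i_ext + 1]].tolist()
    else:
        leading = genes[i_ext:][hit[i_ext:]].tolist()
    return es, running, leading


# ---------------------------------------------------------------------------
# permutation analysis

def permute_and_score(ranked: pd.DataFrame, collection: GeneSetCollection,
                      n_perm: int = 1000,
                      seed: int | np.random.Generator = 0,
                      weight: float = 1.0,
                      min_size: int = MIN_SET_SIZE,
                      max_size: int = MAX_SET_SIZE) -> pd.DataFrame:
    """Gene-label permutation analysis of a whole collection.

    Null ES per set come from random same-size draws from the ranked
    genes (scores fixed). Permutation p is one-tailed on the observed
    ES's sign; NES normalizes by the mean same-sign null |ES|; FDR q
    follows the pooled-null-NES procedure (positive and negative sides
    handled separately). Sets whose in-list membership falls outside
    [min_size, max_size] are excluded; a set with no overlap at all is
    reported with ``testable=False``.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    genes = ranked["gene"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    N = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    prepared = []
    skipped = []
    for name, members in collection.sets.items():
        if len(members) > N:
            raise ValueError(f"gene set {name!r} larger than ranked list")
        pos = np.array(sorted(gene_pos[g] for g in members if g in gene_pos),
                       dtype=int)
        if len(pos) == 0:
            skipped.append({"set": name, "size": 0, "testable": False})
            continue
        if not (min_size <= len(pos) <= max_size):
            continue
        prepared.append((name, pos))
    if not prepared and not skipped:
        raise ValueError("no testable gene sets after size filtering")

    # one pool of permuted positions per distinct set size
    sizes = sorted({len(pos) for _, pos in prepared})
    null_by_size: dict[int, np.ndarray] = {}
    for K in sizes:
        null = np.empty(n_perm)
        for j in range(n_perm):
            perm_pos = rng.choice(N, size=K, replace=False)
            null[j] = _es_from_positions(scores, perm_pos, weight)
        null_by_size[K] = null

    rows = []
    null_nes_pool = []
    for name, pos in prepared:
        es, _, leading = enrichment_score(
            ranked, genes[pos], weight=weight)
        null = null_by_size[len(pos)]
        pos_null = null[null >= 0]
        neg_null = null[null < 0]
        if es >= 0:
            same = pos_null
            p = ((1 + np.sum(same >= es)) / (1 + len(same))
                 if len(same) else 1.0)
            norm = same.mean() if len(same) and same.mean() > 0 else np.nan
        else:
            same = neg_null
            p = ((1 + np.sum(same <= es)) / (1 + len(same))
                 if len(same) else 1.0)
            norm = -same.mean() if len(same) and same.mean() < 0 else np.nan
        nes = es / norm if np.isfinite(norm) else np.nan
        # normalized null for the pooled-FDR reference
        with np.errstate(invalid="ignore", divide="ignore"):
            nn = np.where(null >= 0,
                          null / (pos_null.mean() if len(pos_null) else np.nan),
                          -null / (neg_null.mean() if len(neg_null) else np.nan))
        null_nes_pool.append(nn[np.isfinite(nn)])
        rows.append({"set": name, "size": len(pos), "testable": True,
                     "es": es, "nes": nes, "perm_p": float(p),
                     "direction": "up" if es >= 0 else "down",
                     "leading_edge": ",".join(leading)})

    out = pd.DataFrame(rows + skipped)
    if rows:
        pool = np.concatenate(null_nes_pool)
        obs = out.loc[out["testable"] == True, "nes"].to_numpy(dtype=float)  # noqa: E712
        out.loc[out["testable"] == True, "fdr_q"] = _pooled_fdr(obs, pool)  # noqa: E712
    return out.reset_index(drop=True)


def _pooled_fdr(obs_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """GSEA-style FDR from the pooled null NES distribution."""
    q = np.full(len(obs_nes), np.nan)
    pos_null = null_nes[null_nes >= 0]
    neg_null = null_nes[null_nes < 0]
    pos_obs = obs_nes[obs_nes >= 0]
    neg_obs = obs_nes[obs_nes < 0]
    for i, nes in enumerate(obs_nes):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            num = (np.sum(pos_null >= nes) / len(pos_null)
                   if len(pos_null) else 0.0)
            den = (np.sum(pos_obs >= nes) / len(pos_obs)
                   if len(pos_obs) else 1.0)
        else:
            num = (np.sum(neg_null <= nes) / len(neg_null)
                   if len(neg_null) else 0.0)
            den = (np.sum(neg_obs <= nes) / len(neg_obs)
                   if len(neg_obs) else 1.0)
        q[i] = min(1.0, num / den) if den > 0 else 1.0
    return q


def overlap_edges(sets: dict[str, set],
                  threshold: float = OVERLAP_THRESHOLD) -> pd.DataFrame:
    """Undirected edges between set pairs with overlap coefficient
    |A∩B|/min(|A|,|B|) at or above the threshold; weight = coefficient."""
    names = sorted(sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = len(sets[a] & sets[b])
            denom = min(len(sets[a]), len(sets[b]))
            if denom == 0:
                continue
            coef = inter / denom
            if coef >= threshold:
                rows.append({"source": a, "target": b, "weight": coef})
    return pd.DataFrame(rows, columns=["source", "target", "weight"])
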