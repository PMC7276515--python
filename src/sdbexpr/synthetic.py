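"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of a two-cohort
discovery design plus a small paired treatment cohort:

* two cohorts on distinct platforms — different transcript IDs, 1-3
  transcripts per gene — that share gene symbols and planted effects;
* stratified samples (race/ethnic-group-like strata) with
  stratum-specific intercepts and a random-intercept grouping factor
  (expression chip in cohort A, family in cohort B);
* covariate confounding: traits are tied to age/BMI/sex through a
  Gaussian copula, so trait marginals hit their target moments exactly
  while remaining correlated with covariates that also load on
  expression;
* planted trait effects in a known gene subset with built-in severity
  polarity (severity-positive genes get positive AHI and negative
  avgO2/minO2 coefficients);
* a paired pre/post cohort in which planted severity-linked genes
  reverse after treatment.

Trait marginal targets default to realistic population values
(AHI mean 19.6, sd 18.9 events/hr; avgO2 94.2 (1.8) %; minO2 83.0
(7.7) %). A single global seed derives per-component child generators
deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import ExpressionStudy
from .treatment import PairedStudy
from .enrichment import GeneSetCollection

__all__ = ["CohortLayout", "SimulationConfig", "GroundTruth",
           "make_ground_truth", "simulate_cohort", "simulate_paired",
           "simulate_genesets", "simulate_all"]

TRAIT_PARAMS = {
    "AHI": {"mean": 19.6, "sd": 18.9},
    "avgO2": {"mean": 94.2, "sd": 1.8},
    "minO2": {"mean": 83.0, "sd": 7.7},
}


@dataclass
class CohortLayout:
    """Sampling structure of one cohort."""

    n_strata: int = 3
    n_per_stratum: int = 20
    group_kind: str = "chip"      # "chip": fixed-size blocks; "family": 1-4
    samples_per_group: int = 5


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    Defaults mirror a ~5x-reduced version of the real design: cohort A
    stratified 3x40 with chip blocks, cohort B a single 100-sample
    stratum with family blocks, 2000 genes with 1-3 transcripts each,
    50 planted genes at 0.5 per-SD effect, and a paired treatment
    cohort of 15 subjects. Strata much smaller than ~40 leave too few
    residual degrees of freedom per chip for calibrated tail
    probabilities, so cohort sizes are not reduced further.
    """

    n_genes: int = 2000
    transcripts_per_gene_probs: tuple = (0.5, 0.3, 0.2)  # P(1), P(2), P(3)
    n_planted: int = 50
    effect_size: float = 0.5        # per SD of trait, on log2 expression
    traits: tuple = ("AHI", "avgO2", "minO2")
    layout_a: CohortLayout = field(
        default_factory=lambda: CohortLayout(n_strata=3, n_per_stratum=40,
                                             group_kind="chip",
                                             samples_per_group=5))
    layout_b: CohortLayout = field(
        default_factory=lambda: CohortLayout(n_strata=1, n_per_stratum=100,
                                             group_kind="family"))
    # variance structure (log2 expression scale)
    chip_var: float = 0.2
    stratum_sd: float = 0.3
    residual_sd: float = 1.0
    transcript_sd: float = 0.3
    # covariate->trait confounding (copula weights) and covariate loadings
    age_confounding: float = 0.30
    bmi_confounding: float = 0.25
    sex_confounding: float = 0.15
    # weight of the shared per-sample severity factor in every trait's
    # latent; 0.8 gives inter-trait correlations ~0.8, matching how
    # strongly AHI and the oxygen-saturation indices co-vary
    severity_weight: float = 0.8
    covariate_loading_sd: float = 0.15
    bmi_loading_sd: float = 0.0     # BMI independent of expression by default
    # paired treatment cohort
    paired_n: int = 15
    reversal_effect: float = 1.0    # log2 shift of planted genes post-treatment
    paired_within_sd: float = 0.5
    paired_between_sd: float = 1.0
    # gene sets
    n_decoy_sets: int = 40
    set_size_range: tuple = (15, 60)
    n_planted_sets: int = 2

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.paired_n < 2:
            raise ValueError("counts must be positive (paired_n >= 2)")
        if self.n_planted > self.n_genes:
            raise ValueError("more planted genes than genes")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")
        if abs(sum(self.transcripts_per_gene_probs) - 1) > 1e-9:
            raise ValueError("transcripts-per-gene probabilities must sum to 1")

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"GENE{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class GroundTruth:
    """What was planted: per-gene trait, severity sign, effect size."""

    planted: pd.DataFrame      # gene, trait, severity_sign, trait_sign, effect
    reversal_genes: list[str]  # genes that reverse post-treatment
    planted_sets: list[str] = field(default_factory=list)

    def planted_genes(self) -> list[str]:
        return sorted(self.planted["gene"].unique())


def make_ground_truth(config: SimulationConfig,
                      rng: np.random.Generator) -> GroundTruth:
    """Choose planted genes, their trait, direction and effect size."""
    genes = rng.choice(config.gene_names(), size=config.n_planted,
                       replace=False)
    rows = []
    for i, g in enumerate(sorted(genes)):
        trait = config.traits[i % len(config.traits)]
        severity_sign = int(rng.choice([-1, 1]))
        trait_sign = severity_sign if trait == "AHI" else -severity_sign
        rows.append({"gene": g, "trait": trait,
                     "severity_sign": severity_sign,
                     "trait_sign": trait_sign,
                     "effect": config.effect_size})
    planted = pd.DataFrame(
        rows, columns=["gene", "trait", "severity_sign", "trait_sign",
                       "effect"])
    return GroundTruth(planted=planted,
                       reversal_genes=sorted(planted["gene"].unique()))


# ---------------------------------------------------------------------------
# cohort simulation

def _trait_quantile(trait: str, u: np.ndarray) -> np.ndarray:
    m, s = TRAIT_PARAMS[trait]["mean"], TRAIT_PARAMS[trait]["sd"]
    if trait == "AHI":
        shape = (m / s) ** 2
        scale = s**2 / m
        return stats.gamma.ppf(u, a=shape, scale=scale)
    a, b = (0.0 - m) / s, (100.0 - m) / s
    return stats.truncnorm.ppf(u, a, b, loc=m, scale=s)


def _phenotypes(config: SimulationConfig, layout: CohortLayout,
                rng: np.random.Generator, prefix: str) -> pd.DataFrame:
    n = layout.n_strata * layout.n_per_stratum
    age = rng.normal(65.0, 9.0, n)
    sex = rng.integers(0, 2, n).astype(float)
    bmi = rng.normal(29.5, 5.5, n)
    # five blood fractions drawn, four kept: the retained columns must
    # not sum to one or they would be collinear with the intercept
    cells = rng.dirichlet([10, 2, 5, 3, 4], size=n)[:, :4]
    strata = np.repeat([f"{prefix}str{i+1}" for i in range(layout.n_strata)],
                       layout.n_per_stratum)
    site = rng.choice(["site1", "site2"], size=n)
    # grouping factor
    if layout.group_kind == "chip":
        groups = []
        gid = 0
        for s in range(layout.n_strata):
            for j in range(layout.n_per_stratum):
                if j % layout.samples_per_group == 0:
                    gid += 1
                groups.append(f"{prefix}chip{gid}")
    else:
        groups, gid, left = [], 0, 0
        for _ in range(n):
            if left == 0:
                gid += 1
                left = int(rng.integers(1, 5))
            groups.append(f"{prefix}fam{gid}")
            left -= 1
    ph = pd.DataFrame({
        "age": age, "sex": sex, "bmi": bmi, "site": site,
        "neut": cells[:, 0], "nk": cells[:, 1],
        "tcell": cells[:, 2], "bcell": cells[:, 3],
        "stratum": strata, "group": groups,
    }, index=[f"{prefix}S{i+1:03d}" for i in range(n)])
    # traits through a Gaussian copula: every trait's latent carries the
    # same per-sample severity factor (so AHI, avgO2 and minO2 co-vary
    # strongly, with opposite polarity for the O2 traits) plus the
    # age/BMI/sex confounding component and trait-specific noise
    z_age = (age - 65.0) / 9.0
    z_bmi = (bmi - 29.5) / 5.5
    z_sex = (sex - 0.5) * 2
    w = np.array([config.age_confounding, config.bmi_confounding,
                  config.sex_confounding])
    base = w[0] * z_age + w[1] * z_bmi + w[2] * z_sex
    severity = rng.normal(size=n)
    a = config.severity_weight
    shared_var = a**2 + np.sum(w**2)
    resid = np.sqrt(max(1.0 - shared_var, 0.04))
    for trait in config.traits:
        sign = 1.0 if trait == "AHI" else -1.0
        latent = sign * (a * severity + base) + resid * rng.normal(size=n)
        u = stats.norm.cdf(latent / np.sqrt(shared_var + resid**2))
        ph[trait] = _trait_quantile(trait, np.clip(u, 1e-9, 1 - 1e-9))
    return ph, severity


def simulate_cohort(config: SimulationConfig, platform_label: str,
                    ground_truth: GroundTruth,
                    seed: int | np.random.Generator,
                    layout: CohortLayout | None = None) -> ExpressionStudy:
    """Simulate one cohort on its own transcript-ID namespace.

    ``platform_label`` prefixes sample, group and transcript IDs so two
    cohorts never share transcript IDs but do share gene symbols.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if layout is None:
        layout = config.layout_a if platform_label.endswith("A") else \
            config.layout_b
    genes = config.gene_names()
    ph, severity = _phenotypes(config, layout, rng, platform_label)
    n = len(ph)

    # per-gene structural parameters
    baseline = rng.normal(7.0, 1.0, config.n_genes)
    load_age = rng.normal(0.0, config.covariate_loading_sd, config.n_genes)
    load_sex = rng.normal(0.0, config.covariate_loading_sd, config.n_genes)
    load_cell = rng.normal(0.0, 2 * config.covariate_loading_sd,
                           (config.n_genes, 4))
    load_bmi = rng.normal(0.0, config.bmi_loading_sd, config.n_genes) \
        if config.bmi_loading_sd > 0 else np.zeros(config.n_genes)

    strata_codes = pd.factorize(ph["stratum"])[0]
    stratum_int = rng.normal(0.0, config.stratum_sd,
                             (layout.n_strata, config.n_genes))
    group_codes, group_labels = pd.factorize(ph["group"])
    group_int = rng.normal(0.0, np.sqrt(config.chip_var),
                           (len(group_labels), config.n_genes))

    z_age = ((ph["age"] - 65.0) / 9.0).to_numpy()
    z_sex = (ph["sex"] - 0.5).to_numpy()
    z_bmi = ((ph["bmi"] - 29.5) / 5.5).to_numpy()
    cells = ph[["neut", "nk", "tcell", "bcell"]].to_numpy()
    cells_c = cells - cells.mean(axis=0)

    G = (baseline[None, :]
         + stratum_int[strata_codes, :]
         + group_int[group_codes, :]
         + np.outer(z_age, load_age)
         + np.outer(z_sex, load_sex)
         + np.outer(z_bmi, load_bmi)
         + cells_c @ load_cell.T
         + rng.normal(0.0, config.residual_sd, (n, config.n_genes)))

    # planted effects load on the standardized severity factor, so a
    # planted gene associates with every trait in its severity-polarity
    # direction (positive AHI, negative avgO2/minO2 coefficients for a
    # severity-positive gene), attenuated by the trait's severity share
    z_sev = (severity - severity.mean()) / severity.std(ddof=1)
    gene_index = {g: i for i, g in enumerate(genes)}
    for _, row in ground_truth.planted.iterrows():
        G[:, gene_index[row["gene"]]] += \
            row["severity_sign"] * row["effect"] * z_sev

    # transcripts: shared gene signal plus transcript-specific offset/noise
    k_per_gene = rng.choice([1, 2, 3], size=config.n_genes,
                            p=config.transcripts_per_gene_probs)
    cols, names, tmap = [], [], {}
    for gi, g in enumerate(genes):
        for k in range(k_per_gene[gi]):
            tid = f"{platform_label}_{gi+1:05d}_{k+1}"
            offset = rng.normal(0.0, 0.5)
            cols.append(G[:, gi] + offset
                        + rng.normal(0.0, config.transcript_sd, n))
            names.append(tid)
            tmap[tid] = g
    expr = pd.DataFrame(np.column_stack(cols), index=ph.index, columns=names)
    return ExpressionStudy(name=platform_label, expression=expr,
                           transcript_map=tmap, phenotypes=ph,
                           stratum_col="stratum", group_col="group")


def simulate_paired(config: SimulationConfig, ground_truth: GroundTruth,
                    seed: int | np.random.Generator) -> PairedStudy:
    """Paired pre/post cohort; planted genes reverse their severity
    association after treatment (severity-positive genes decrease)."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    genes = config.gene_names()
    n = config.paired_n
    baseline = rng.normal(7.0, 1.0, config.n_genes)
    subject = rng.normal(0.0, config.paired_between_sd, (n, 1))
    pre = (baseline[None, :] + subject
           + rng.normal(0.0, config.paired_within_sd, (n, config.n_genes)))
    shift = np.zeros(config.n_genes)
    sev = ground_truth.planted.set_index("gene")["severity_sign"]
    for gi, g in enumerate(genes):
        if g in sev.index and g in ground_truth.reversal_genes:
            shift[gi] = -float(sev[g]) * config.reversal_effect
    post = (baseline[None, :] + subject + shift[None, :]
            + rng.normal(0.0, config.paired_within_sd, (n, config.n_genes)))
    idx = [f"HB{i+1:02d}" for i in range(n)]
    return PairedStudy(
        expr_pre=pd.DataFrame(pre, index=idx, columns=genes),
        expr_post=pd.DataFrame(post, index=idx, columns=genes))


def simulate_genesets(config: SimulationConfig, ground_truth: GroundTruth,
                      seed: int | np.random.Generator) -> GeneSetCollection:
    """Decoy sets drawn uniformly from the simulated genes, plus planted
    sets enriched for the planted gene list."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    genes = np.array(config.gene_names())
    lo, hi = config.set_size_range
    sets: dict[str, set] = {}
    for i in range(config.n_decoy_sets):
        size = min(int(rng.integers(lo, hi + 1)), len(genes))
        sets[f"DECOY_{i+1:03d}"] = set(rng.choice(genes, size, replace=False))
    # planted sets are direction-coherent: one (trait, severity-sign)
    # block each, padded with random genes, so the set moves as a unit
    # on its trait's ranking
    blocks = ground_truth.planted.groupby(["trait", "severity_sign"])
    ordered = sorted(blocks.groups, key=lambda k: -len(blocks.groups[k]))
    planted_names = []
    for i, key in enumerate(ordered[:config.n_planted_sets]):
        core = blocks.get_group(key)["gene"].to_numpy()
        pool = np.setdiff1d(genes, core)
        pad = rng.choice(pool, size=min(max(0, lo - len(core)), len(pool)),
                         replace=False)
        name = f"PLANTED_{key[0]}_{'UP' if key[1] > 0 else 'DOWN'}"
        sets[name] = set(core) | set(pad)
        planted_names.append(name)
    ground_truth.planted_sets = planted_names
    return GeneSetCollection(sets=sets, source="synthetic")


def simulate_all(config: SimulationConfig, seed: int) -> dict:
    """Generate both cohorts, the paired cohort, gene sets and ground
    truth from one global seed (child streams are spawned
    deterministically)."""
    ss = np.random.SeedSequence(seed)
    r_gt, r_a, r_b, r_p, r_gs = [np.random.default_rng(s)
                                 for s in ss.spawn(5)]
    gt = make_ground_truth(config, r_gt)
    study_a = simulate_cohort(config, "A", gt, r_a, layout=config.layout_a)
    study_b = simulate_cohort(config, "B", gt, r_b, layout=config.layout_b)
    paired = simulate_paired(config, gt, r_p)
    genesets = simulate_genesets(config, gt, r_gs)
    return {"ground_truth": gt, "study_a": study_a, "study_b": study_b,
            "paired": paired, "genesets": genesets}
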