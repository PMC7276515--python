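"""Per-transcript association of expression with an SDB trait.

Expression (outcome) is regressed on the trait (exposure) plus fixed
covariates, with a random intercept on the cohort's grouping factor
(expression chip or family), fitted by REML separately within each
stratum (e.g. race/ethnic group). When the variance component hits its
zero bound or the fit does not converge, an ordinary least-squares fit
with the same fixed effects is used instead. Per-stratum estimates are
then combined by inverse-variance fixed-effects meta-analysis.

Per-stratum two-sided p-values use a t reference by default (exact
residual df for the OLS fallback, containment df for the mixed fit);
the large-sample normal reference is available via
``ModelSpec(p_reference="normal")``. Cross-stratum combination reports
the inverse-variance fixed-effects estimate and SE; its p-value is, by
default, the sample-size-weighted combination of the per-stratum
calibrated z-scores, which agrees with the IVW normal p asymptotically
but stays calibrated when stratum SEs carry few degrees of freedom.

Trait severity polarity (used downstream): higher AHI = more severe;
higher avgO2/minO2 = less severe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .core_stats import EffectEstimate, inverse_variance_meta, wald_p
from .lmm import RandomInterceptDesign

logger = logging.getLogger(__name__)

TRAITS = ("AHI", "avgO2", "minO2")

__all__ = ["ExpressionStudy", "ModelSpec", "fit_transcript", "fallback_ols",
           "fit_study", "combine_calibrated_p", "TRAITS"]


@dataclass
class ExpressionStudy:
    """One cohort: expression matrix, transcript->gene map, phenotypes.

    Parameters
    ----------
    name : cohort label (also used as platform provenance).
    expression : DataFrame, samples x transcripts, normalized log-scale
        intensities.
    transcript_map : mapping of transcript ID -> gene symbol; every
        column of ``expression`` must be present.
    phenotypes : DataFrame indexed by sample ID carrying trait values,
        covariates, the stratum label column and the grouping-factor
        column.
    stratum_col, group_col : column names in ``phenotypes``.
    """

    name: str
    expression: pd.DataFrame
    transcript_map: dict[str, str]
    phenotypes: pd.DataFrame
    stratum_col: str = "stratum"
    group_col: str = "chip"

    def __post_init__(self) -> None:
        if not self.expression.index.equals(self.phenotypes.index):
            raise ValueError("sample IDs differ between expression matrix "
                             "and phenotype table")
        missing = [t for t in self.expression.columns
                   if t not in self.transcript_map]
        if missing:
            raise ValueError(f"transcripts without gene symbol: {missing[:5]}")
        for col in (self.stratum_col, self.group_col):
            if col not in self.phenotypes.columns:
                raise ValueError(f"phenotype table lacks column {col!r}")
        self._check_trait_ranges()

    def _check_trait_ranges(self) -> None:
        ph = self.phenotypes
        if "AHI" in ph and (ph["AHI"].dropna() < 0).any():
            raise ValueError("AHI must be non-negative")
        for t in ("avgO2", "minO2"):
            if t in ph:
                v = ph[t].dropna()
                if ((v <= 0) | (v > 100)).any():
                    raise ValueError(f"{t} must lie in (0, 100]")

    @property
    def strata(self) -> list:
        return sorted(self.phenotypes[self.stratum_col].unique())

    def genes(self) -> pd.Series:
        return pd.Series({t: self.transcript_map[t]
                          for t in self.expression.columns}, name="gene")


@dataclass
class ModelSpec:
    """Which trait and covariates to fit, and on which random intercept."""

    trait: str
    covariates: list[str] = field(default_factory=list)
    random_intercept: str | None = None   # None -> use study's group_col
    include_bmi: bool = False
    p_reference: str = "t"                # "t" or "normal", per-stratum p

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}; "
                             f"expected one of {TRAITS}")
        if self.p_reference not in ("t", "normal"):
            raise ValueError("p_reference must be 't' or 'normal'")

    def covariate_list(self) -> list[str]:
        cov = list(self.covariates)
        if self.include_bmi and "bmi" not in cov:
            cov.append("bmi")
        return cov


# ---------------------------------------------------------------------------
# design construction

def _design_matrix(ph: pd.DataFrame, trait: str, covariates: list[str]):
    """Fixed-effects matrix [intercept, trait, covariates...] with dummy
    coding for categorical covariates. Returns a DataFrame whose second
    column is the trait."""
    for c in [trait, *covariates]:
        if c not in ph.columns:
            raise ValueError(f"phenotype table lacks column {c!r}")
    cols = [pd.Series(1.0, index=ph.index, name="intercept"),
            ph[trait].astype(float)]
    for c in covariates:
        s = ph[c]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=c, drop_first=True, dtype=float)
            cols.extend(dummies[c2] for c2 in dummies.columns)
        else:
            cols.append(s.astype(float))
    X = pd.concat(cols, axis=1)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        # name the columns past the numerical rank in pivoted-QR order
        _, _, piv = linalg.qr(X.to_numpy(), pivoting=True)
        r = np.linalg.matrix_rank(X.to_numpy())
        bad = [X.columns[i] for i in piv[r:]]
        raise ValueError(f"collinear fixed-effect columns: {bad}")
    return X


def _stratum_frame(study: ExpressionStudy, spec: ModelSpec, stratum):
    ph = study.phenotypes
    mask = ph[study.stratum_col] == stratum
    if not mask.any():
        raise ValueError(f"no samples in stratum {stratum!r}")
    cov = spec.covariate_list()
    group_col = spec.random_intercept or study.group_col
    sub = ph.loc[mask, [spec.trait, *cov, group_col]].dropna()
    return sub, cov, group_col


def _p_value(beta: float, se: float, df: int, reference: str) -> float:
    if reference == "normal":
        return wald_p(beta, se)
    p = 2.0 * stats.t.sf(abs(beta / se), df=df)
    return float(max(p, np.finfo(float).tiny))


def _containment_df(n: int, p: int, n_groups: int) -> int:
    """Containment-style degrees of freedom for the mixed-fit t
    reference: the g group intercepts count against the residual df as
    if estimated as fixed effects. Conservative for between-group
    contrasts, close to exact for within-group exposure variation."""
    return max(n - p - (n_groups - 1), 3)


def combine_calibrated_p(ests: list[EffectEstimate]) -> float:
    """Two-sided p for a combined effect from calibrated component p's.

    Each component's two-sided p is converted to a signed z-score
    (exactly standard normal under the null when the component p is
    calibrated) and the z-scores are combined with sqrt(n) weights.
    Unlike the normal approximation on the IVW combined z, this stays
    calibrated when component standard errors carry few degrees of
    freedom.
    """
    z = np.array([np.sign(e.beta) * stats.norm.isf(e.p_two / 2)
                  for e in ests])
    w = np.sqrt(np.array([e.n for e in ests], dtype=float))
    zc = float(np.sum(w * z) / np.sqrt(np.sum(w**2)))
    return float(max(2 * stats.norm.sf(abs(zc)), np.finfo(float).tiny))


# ---------------------------------------------------------------------------
# single-transcript fits

def fit_transcript(study: ExpressionStudy, transcript: str, spec: ModelSpec,
                   stratum) -> tuple[EffectEstimate, str]:
    """REML random-intercept fit of one transcript in one stratum.

    Returns the trait effect and a flag naming the model that produced
    it (``"mixed"`` or ``"ols"``). Falls back to OLS when the grouping
    variance component is on its zero bound, REML fails to converge, or
    the variance component is unidentifiable (one sample per group).
    """
    sub, cov, group_col = _stratum_frame(study, spec, stratum)
    y = study.expression.loc[sub.index, transcript].astype(float)
    keep = y.notna()
    sub, y = sub[keep], y[keep]
    X = _design_matrix(sub, spec.trait, cov)
    n, p = X.shape
    if n < p + 3:
        raise ValueError(f"too few samples ({n}) in stratum {stratum!r} "
                         f"for {p} fixed effects")
    if np.ptp(y.to_numpy()) == 0 or np.ptp(sub[spec.trait].to_numpy()) == 0:
        raise ValueError("degenerate input: constant expression or trait "
                         f"in stratum {stratum!r}")
    groups = sub[group_col].to_numpy()
    if len(np.unique(groups)) == len(groups):
        return _ols_fit(y.to_numpy(), X, spec.p_reference), "ols"
    design = RandomInterceptDesign(X.to_numpy(), groups)
    fit = design.fit(y.to_numpy())
    if fit.on_boundary or not fit.converged:
        return _ols_fit(y.to_numpy(), X, spec.p_reference), "ols"
    beta, se = float(fit.beta[1]), float(fit.se[1])
    df = _containment_df(n, p, design.n_groups)
    return EffectEstimate(beta=beta, se=se,
                          p_two=_p_value(beta, se, df, spec.p_reference),
                          n=n), "mixed"


def _ols_fit(y: np.ndarray, X: pd.DataFrame,
             reference: str = "t") -> EffectEstimate:
    Xm = X.to_numpy()
    n, p = Xm.shape
    XtX_inv = linalg.inv(Xm.T @ Xm)
    beta_all = XtX_inv @ (Xm.T @ y)
    resid = y - Xm @ beta_all
    sigma2 = float(resid @ resid) / (n - p)
    beta = float(beta_all[1])
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    return EffectEstimate(beta=beta, se=se,
                          p_two=_p_value(beta, se, n - p, reference), n=n)


def fallback_ols(study: ExpressionStudy, transcript: str, spec: ModelSpec,
                 stratum) -> EffectEstimate:
    """OLS fit with the same fixed effects and no random intercept."""
    sub, cov, _ = _stratum_frame(study, spec, stratum)
    y = study.expression.loc[sub.index, transcript].astype(float)
    keep = y.notna()
    sub, y = sub[keep], y[keep]
    X = _design_matrix(sub, spec.trait, cov)
    if np.ptp(y.to_numpy()) == 0 or np.ptp(sub[spec.trait].to_numpy()) == 0:
        raise ValueError("degenerate input: constant expression or trait")
    return _ols_fit(y.to_numpy(), X, spec.p_reference)


# ---------------------------------------------------------------------------
# whole-study scan

def fit_study(study: ExpressionStudy, spec: ModelSpec) -> pd.DataFrame:
    """Fit every transcript in every stratum and combine across strata.

    The REML profile scan is batched: within a stratum the fixed-effect
    design and grouping structure are shared by all transcripts, so the
    design is factorized once and only the outcome changes per fit.

    Returns a table with one row per transcript: raw-trait-unit effect
    (beta, se, p, n), the per-SD-of-trait scale (beta_sd, se_sd; SD
    computed within-cohort), gene symbol and the models used.
    Transcripts failing in some strata are combined over the remaining
    ones (logged); transcripts failing everywhere are excluded and
    listed in ``result.attrs["failed_transcripts"]``.
    """
    transcripts = list(study.expression.columns)
    trait_sd = float(study.phenotypes[spec.trait].std(ddof=1))
    per_transcript: dict[str, list] = {t: [] for t in transcripts}
    models: dict[str, list] = {t: [] for t in transcripts}

    for stratum in study.strata:
        sub, cov, group_col = _stratum_frame(study, spec, stratum)
        X = _design_matrix(sub, spec.trait, cov)
        n, p = X.shape
        if n < p + 3:
            logger.warning("stratum %r skipped: %d samples for %d effects",
                           stratum, n, p)
            continue
        if np.ptp(X.iloc[:, 1].to_numpy()) == 0:
            logger.warning("stratum %r skipped: constant trait", stratum)
            continue
        Y = study.expression.loc[sub.index, transcripts].to_numpy(dtype=float)
        ok = ~np.isnan(Y).any(axis=0)
        ok &= np.ptp(Y, axis=0) != 0
        idx_ok = np.flatnonzero(ok)
        groups = sub[group_col].to_numpy()
        identifiable = len(np.unique(groups)) < len(groups)
        ols_cols: list[int] = []
        if identifiable:
            design = RandomInterceptDesign(X.to_numpy(), groups)
            fits = design.fit_many(Y[:, idx_ok])
            for j, fit in zip(idx_ok, fits):
                t = transcripts[j]
                if fit.on_boundary or not fit.converged:
                    ols_cols.append(j)
                    continue
                beta, se = float(fit.beta[1]), float(fit.se[1])
                df = _containment_df(n, p, design.n_groups)
                per_transcript[t].append(EffectEstimate(
                    beta=beta, se=se,
                    p_two=_p_value(beta, se, df, spec.p_reference), n=n))
                models[t].append("mixed")
        else:
            ols_cols = list(idx_ok)
        if ols_cols:
            for j, est in zip(ols_cols,
                              _ols_many(Y[:, ols_cols], X,
                                        spec.p_reference)):
                per_transcript[transcripts[j]].append(est)
                models[transcripts[j]].append("ols")
        # transcripts with NaN outcomes: per-transcript listwise deletion
        for j in np.flatnonzero(np.isnan(Y).any(axis=0)):
            t = transcripts[j]
            try:
                est, model = fit_transcript(study, t, spec, stratum)
            except ValueError as exc:
                logger.warning("transcript %s failed in stratum %r: %s",
                               t, stratum, exc)
                continue
            per_transcript[t].append(est)
            models[t].append(model)

    rows, failed = [], []
    for t in transcripts:
        ests = per_transcript[t]
        if not ests:
            failed.append(t)
            continue
        if len(ests) == 1:
            est = ests[0]
        else:
            est = inverse_variance_meta(ests)
            if spec.p_reference == "t":
                # IVW estimate, calibrated combined p: the normal IVW p
                # is anticonservative when stratum SEs carry few df
                est = EffectEstimate(beta=est.beta, se=est.se,
                                     p_two=combine_calibrated_p(ests),
                                     n=est.n)
        rows.append({
            "transcript": t, "gene": study.transcript_map[t],
            "trait": spec.trait,
            "beta": est.beta, "se": est.se, "p": est.p_two, "n": est.n,
            "beta_sd": est.beta * trait_sd, "se_sd": est.se * trait_sd,
            "model_used": "+".join(models[t]), "n_strata": len(ests),
        })
    out = pd.DataFrame(rows)
    out.attrs["failed_transcripts"] = failed
    out.attrs["cohort"] = study.name
    out.attrs["trait_sd"] = trait_sd
    if failed:
        logger.warning("%d transcripts failed in all strata", len(failed))
    return out


def _ols_many(Y: np.ndarray, X: pd.DataFrame,
              reference: str) -> list[EffectEstimate]:
    """Vectorized OLS of many outcomes on one design."""
    Xm = X.to_numpy()
    n, p = Xm.shape
    XtX_inv = linalg.inv(Xm.T @ Xm)
    B = XtX_inv @ (Xm.T @ Y)
    resid = Y - Xm @ B
    sigma2 = np.einsum("ij,ij->j", resid, resid) / (n - p)
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    out = []
    for beta, s in zip(B[1], se):
        out.append(EffectEstimate(
            beta=float(beta), se=float(s),
            p_two=_p_value(float(beta), float(s), n - p, reference), n=n))
    return out
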