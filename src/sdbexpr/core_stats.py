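"""Statistical primitives shared by every pipeline stage.

Three operations recur throughout the cross-cohort workflow: combining
effect estimates by inverse-variance weighting (fixed-effects
meta-analysis), Benjamini-Hochberg FDR adjustment, and converting a
two-sided p-value into a direction-aware one-sided p-value for
replication testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EffectEstimate",
    "QValueVector",
    "inverse_variance_meta",
    "bh_fdr",
    "one_sided_p",
]


@dataclass(frozen=True)
class EffectEstimate:
    """A single effect estimate: slope, standard error, two-sided p, n.

    ``beta`` is the estimated effect of the trait on expression (per unit
    or per SD of the trait, depending on provenance); ``se`` its standard
    error; ``p_two`` the two-sided p-value; ``n`` the sample count that
    produced it.
    """

    beta: float
    se: float
    p_two: float
    n: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.se) or self.se <= 0:
            raise ValueError("invalid standard error")
        if not (0 < self.p_two <= 1):
            raise ValueError(f"p_two must be in (0, 1], got {self.p_two}")

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def sign(self) -> int:
        return int(np.sign(self.beta))


@dataclass(frozen=True)
class QValueVector:
    """Paired vectors of raw p-values and BH-adjusted q-values."""

    p: np.ndarray
    q: np.ndarray


def inverse_variance_meta(effects: Sequence[EffectEstimate]) -> EffectEstimate:
    """Fixed-effects inverse-variance combination of effect estimates.

    Weights are ``1/se_i**2``; the combined standard error is
    ``(sum w_i)**-0.5`` and the combined two-sided p comes from the
    normal (Wald z) approximation. Sample sizes add.
    """
    if len(effects) == 0:
        raise ValueError("no effects to combine")
    se = np.array([e.se for e in effects], dtype=float)
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise ValueError("invalid standard error")
    beta = np.array([e.beta for e in effects], dtype=float)
    w = 1.0 / se**2
    beta_c = float(np.sum(w * beta) / np.sum(w))
    se_c = float(np.sum(w) ** -0.5)
    p_two = wald_p(beta_c, se_c)
    return EffectEstimate(beta=beta_c, se=se_c, p_two=p_two,
                          n=int(sum(e.n for e in effects)))


def wald_p(beta: float, se: float) -> float:
    """Two-sided p from the normal approximation of beta/se.

    Clipped away from exact zero so downstream (0, 1] invariants hold
    even for astronomically large z.
    """
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return float(max(p, np.finfo(float).tiny))


def bh_fdr(p: Sequence[float] | np.ndarray) -> QValueVector:
    """Benjamini-Hochberg step-up FDR adjustment.

    Input order is preserved; ties in p receive equal q; the enforced
    monotonicity pass guarantees a larger p never gets a strictly
    smaller q.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-d vector")
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values; pre-filter before FDR adjustment")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return QValueVector(p=p, q=q)


def one_sided_p(p_two: float, observed_sign: int, expected_sign: int) -> float:
    """Direction-aware one-sided p-value for replication testing.

    Converts a two-sided p into the one-sided p for the alternative in
    the *expected* direction: ``p_two / 2`` when the observed sign
    agrees, ``1 - p_two / 2`` when it disagrees. The expected sign comes
    from the discovery cohort; a directionless discovery effect cannot
    be tested.
    """
    if expected_sign == 0:
        raise ValueError("discovery effect has no direction")
    if expected_sign not in (-1, 1):
        raise ValueError(f"expected_sign must be -1 or +1, got {expected_sign}")
    if not (0 < p_two <= 1):
        raise ValueError(f"p_two must be in (0, 1], got {p_two}")
    # observed_sign == 0 (beta exactly zero) carries no directional
    # evidence either way: both tails give 1 - p_two/2 = p_two/2 = 0.5
    # only at p_two=1; treat it as disagreement, the conservative side.
    if observed_sign == expected_sign:
        return p_two / 2.0
    return 1.0 - p_two / 2.0
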