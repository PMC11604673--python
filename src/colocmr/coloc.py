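"""Single-causal-variant Bayesian colocalisation of two traits.

Given allele-aligned summary statistics for a quantitative exposure
(gene expression or protein level) and a binary outcome (disease
liability) over one cis-region, this module computes the posterior
probabilities of five mutually exclusive hypotheses, assuming at most
one causal variant per trait:

    H0  no association with either trait
    H1  association with the exposure only
    H2  association with the outcome only
    H3  both traits associated, two distinct causal variants
    H4  both traits associated, one shared causal variant

Per-variant evidence is the Wakefield approximate Bayes factor against
the null.  With V = se^2, W the prior effect variance and r = W/(W+V),

    log ABF = 0.5 * (log(1 - r) + r * z^2),    z = beta/se.

Hypothesis weights combine per-variant ABFs with prior probabilities
p1, p2, p12 that a variant is causal for the exposure only, the outcome
only, or both.  All accumulation is in log space: regional eQTL
z-scores can exceed 40, which overflows naive exponentials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .conversion import ConversionInput, z_to_beta_se
from .sumstats import HarmonisedRegion, SumstatRecord

__all__ = [
    "ColocPriors",
    "EffectPrior",
    "ColocResult",
    "log_abf",
    "coloc_abf",
    "coloc_from_effects",
    "decide_proceed",
    "HYPOTHESES",
]

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant prior causal probabilities (exposure-only, outcome-only, shared)."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if not (0.0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("require 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1.0:
            raise ValueError("priors must sum to < 1")


@dataclass(frozen=True)
class EffectPrior:
    """Prior SD of the true effect size (W^0.5 in the Wakefield ABF).

    ``sd_quant`` applies to per-SD quantitative-trait effects and
    ``sd_binary`` to log-odds effects; the defaults are the conventional
    choices for expression and disease GWAS respectively.
    """

    sd_quant: float = 0.15
    sd_binary: float = 0.2

    def __post_init__(self) -> None:
        if self.sd_quant <= 0 or self.sd_binary <= 0:
            raise ValueError("effect prior SDs must be positive")


@dataclass
class ColocResult:
    """Posterior hypothesis probabilities and the per-variant shared-causal posterior."""

    pp: np.ndarray  # shape (5,), P(H0..H4 | data)
    per_variant_h4: np.ndarray  # P(variant j is the shared causal one | H4)
    lead_variant: str
    variant_ids: list[str] = field(default_factory=list)

    @property
    def n_variants(self) -> int:
        return len(self.per_variant_h4)

    @property
    def pp_h4(self) -> float:
        return float(self.pp[4])

    def as_dict(self) -> dict[str, float]:
        return {h: float(p) for h, p in zip(HYPOTHESES, self.pp)}


def log_abf(beta: float, se: float, prior_sd: float) -> float:
    """Natural log of the Wakefield approximate Bayes factor against the null."""
    if not (se > 0 and prior_sd > 0):
        raise ValueError("se and prior_sd must be positive")
    if not (math.isfinite(beta) and math.isfinite(se)):
        raise ValueError("beta and se must be finite")
    V = se * se
    W = prior_sd * prior_sd
    r = W / (W + V)
    z = beta / se
    return 0.5 * (math.log1p(-r) + r * z * z)


def _exposure_effect(rec: SumstatRecord) -> tuple[float, float]:
    """(beta, se) for the exposure side, converting from z when needed."""
    if rec.beta is not None and rec.se is not None:
        return rec.beta, rec.se
    return z_to_beta_se(ConversionInput(z=rec.zscore, maf=rec.maf, n=rec.n))


def _outcome_effect(rec: SumstatRecord) -> tuple[float, float]:
    if rec.beta is None or rec.se is None:
        raise ValueError(
            f"{rec.variant_id}: outcome records must carry beta and se "
            "(log-odds scale); z-only binary-trait records are not converted"
        )
    return rec.beta, rec.se


def effect_arrays(region: HarmonisedRegion) -> tuple[np.ndarray, ...]:
    """Aligned (beta_exp, se_exp, beta_out, se_out) arrays over the region."""
    be, se_, bo, so = [], [], [], []
    for v in region.variants:
        b1, s1 = _exposure_effect(v.exposure)
        b2, s2 = _outcome_effect(v.outcome)
        be.append(b1)
        se_.append(s1)
        bo.append(b2)
        so.append(s2)
    return tuple(np.asarray(a, dtype=float) for a in (be, se_, bo, so))


def coloc_from_effects(
    beta_exp: np.ndarray,
    se_exp: np.ndarray,
    beta_out: np.ndarray,
    se_out: np.ndarray,
    variant_ids: list[str],
    priors: ColocPriors = ColocPriors(),
    effect_prior: EffectPrior = EffectPrior(),
    exposure_p: np.ndarray | None = None,
) -> ColocResult:
    """Colocalise from aligned effect arrays (the array-level work-horse)."""
    n = len(variant_ids)
    if n == 0:
        raise ValueError("empty region")
    l1 = np.array(
        [log_abf(b, s, effect_prior.sd_quant) for b, s in zip(beta_exp, se_exp)]
    )
    l2 = np.array(
        [log_abf(b, s, effect_prior.sd_binary) for b, s in zip(beta_out, se_out)]
    )
    log_s1 = float(logsumexp(l1))
    log_s2 = float(logsumexp(l2))
    l12 = l1 + l2
    log_s12 = float(logsumexp(l12))

    # H3 weight is p1*p2*(S1*S2 - S12); the difference is >= 0 because every
    # product term of S12 appears in S1*S2, vanishing exactly for one variant.
    d = log_s12 - (log_s1 + log_s2)
    if n == 1 or d >= 0.0:
        log_h3_sum = -np.inf
    else:
        log_h3_sum = log_s1 + log_s2 + math.log1p(-math.exp(d))

    log_w = np.array(
        [
            0.0,
            math.log(priors.p1) + log_s1,
            math.log(priors.p2) + log_s2,
            math.log(priors.p1) + math.log(priors.p2) + log_h3_sum,
            math.log(priors.p12) + log_s12,
        ]
    )
    pp = np.exp(log_w - logsumexp(log_w))
    pp /= pp.sum()

    per_variant_h4 = np.exp(l12 - log_s12)
    per_variant_h4 /= per_variant_h4.sum()

    lead = _lead_variant(per_variant_h4, variant_ids, exposure_p)
    return ColocResult(
        pp=pp,
        per_variant_h4=per_variant_h4,
        lead_variant=lead,
        variant_ids=list(variant_ids),
    )


def _lead_variant(
    per_variant_h4: np.ndarray,
    variant_ids: list[str],
    exposure_p: np.ndarray | None,
) -> str:
    """Argmax of the per-variant H4 posterior; ties by smaller exposure p, then id."""
    best = per_variant_h4.max()
    tied = np.flatnonzero(per_variant_h4 >= best * (1.0 - 1e-12))
    if len(tied) == 1:
        return variant_ids[int(tied[0])]
    if exposure_p is not None:
        keys = sorted(tied, key=lambda j: (exposure_p[j], variant_ids[j]))
    else:
        keys = sorted(tied, key=lambda j: variant_ids[j])
    return variant_ids[int(keys[0])]


def coloc_abf(
    region: HarmonisedRegion,
    priors: ColocPriors = ColocPriors(),
    effect_prior: EffectPrior = EffectPrior(),
) -> ColocResult:
    """Colocalise a harmonised region (exposure quantitative, outcome binary)."""
    if len(region) == 0:
        raise ValueError("cannot colocalise an empty region")
    beta_exp, se_exp, beta_out, se_out = effect_arrays(region)
    exposure_p = np.array([v.exposure.pvalue for v in region.variants])
    return coloc_from_effects(
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        region.variant_ids(),
        priors=priors,
        effect_prior=effect_prior,
        exposure_p=exposure_p,
    )


def decide_proceed(result: ColocResult, threshold: float = 0.8) -> bool:
    """Gate for downstream MR: proceed only when P(H4) strictly exceeds the threshold."""
    return result.pp_h4 > threshold
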