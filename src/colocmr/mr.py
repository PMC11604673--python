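"""Single-instrument (Wald-ratio) cis-Mendelian randomisation.

The causal effect of the exposure (target expression or protein level,
per SD) on disease liability (log-odds) is estimated at one genetic
instrument as the ratio of the outcome to the exposure association:

    theta = beta_out / beta_exp,     se(theta) = se_out / |beta_exp|

(first-order delta method, the two-sample MR convention; a second-order
option that propagates the exposure SE is available behind a flag).
Estimates are reported as OR per SD with 95% CI and a two-sided normal
p-value, and carry the instrument F statistic.  MR is gated on the
colocalisation posterior: it runs only at the lead shared causal variant
of regions with P(H4) above the threshold (default 0.8).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy import stats

from .coloc import ColocResult, _exposure_effect, _outcome_effect, decide_proceed
from .conversion import f_statistic
from .sumstats import HarmonisedRegion

__all__ = ["WaldEstimate", "ColocSkip", "wald_ratio", "mr_from_coloc", "WEAK_F"]

logger = logging.getLogger(__name__)

Z_95 = 1.959964  # exact normal 97.5% quantile to the precision reported
WEAK_F = 10.0


@dataclass(frozen=True)
class WaldEstimate:
    """MR effect per SD of exposure: log-OR, SE, OR with 95% CI, p, instrument F."""

    instrument: str
    theta: float
    se_theta: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    f_stat: float
    weak_instrument: bool = False

    def format_or(self) -> str:
        return f"{self.or_:.2f} ({self.ci_low:.2f}, {self.ci_high:.2f})"


@dataclass(frozen=True)
class ColocSkip:
    """Marker that MR was not run because the H4 gate failed."""

    pp_h4: float
    threshold: float


def wald_ratio(
    beta_exp: float,
    se_exp: float,
    beta_out: float,
    se_out: float,
    variant: str,
    second_order: bool = False,
) -> WaldEstimate:
    """Wald-ratio estimate of the outcome log-odds per SD of exposure.

    ``second_order`` adds the exposure-SE term
    sqrt(se_out^2/beta_exp^2 + beta_out^2 se_exp^2 / beta_exp^4); with the
    strong instruments this screen requires (F well above 100) the two
    differ negligibly.
    """
    if beta_exp == 0:
        raise ZeroDivisionError(f"{variant}: exposure effect is zero, ratio undefined")
    if not (se_exp > 0 and se_out > 0):
        raise ValueError(f"{variant}: standard errors must be positive")
    f = f_statistic(beta_exp, se_exp)
    weak = f < WEAK_F
    if weak:
        logger.warning("%s: weak instrument (F = %.2f < %.0f)", variant, f, WEAK_F)
    theta = beta_out / beta_exp
    if second_order:
        se_theta = math.sqrt(
            se_out**2 / beta_exp**2 + beta_out**2 * se_exp**2 / beta_exp**4
        )
    else:
        se_theta = se_out / abs(beta_exp)
    p = float(2.0 * stats.norm.sf(abs(theta) / se_theta))
    return WaldEstimate(
        instrument=variant,
        theta=theta,
        se_theta=se_theta,
        or_=math.exp(theta),
        ci_low=math.exp(theta - Z_95 * se_theta),
        ci_high=math.exp(theta + Z_95 * se_theta),
        p=p,
        f_stat=f,
        weak_instrument=weak,
    )


def mr_from_coloc(
    region: HarmonisedRegion,
    coloc: ColocResult,
    threshold: float = 0.8,
    second_order: bool = False,
) -> WaldEstimate | ColocSkip:
    """H4-gated MR at the colocalisation lead variant, unweighted.

    Returns a :class:`ColocSkip` recording P(H4) when the gate fails.
    """
    if not decide_proceed(coloc, threshold):
        return ColocSkip(pp_h4=coloc.pp_h4, threshold=threshold)
    try:
        v = region.find(coloc.lead_variant)
    except KeyError as exc:
        raise RuntimeError(
            f"coloc lead variant {coloc.lead_variant!r} missing from region"
        ) from exc
    b_exp, s_exp = _exposure_effect(v.exposure)
    b_out, s_out = _outcome_effect(v.outcome)
    return wald_ratio(b_exp, s_exp, b_out, s_out, v.variant_id, second_order)
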