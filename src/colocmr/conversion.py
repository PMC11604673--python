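"""Summary-statistic transformations for quantitative-trait GWAS.

eQTL consortia commonly release association z-scores rather than effect
sizes.  For a standardised phenotype, the per-allele effect and its
standard error can be recovered from the z-score, the minor allele
frequency ``p`` and the sample size ``n``:

    beta = z / sqrt(2 p (1 - p) (n + z^2))
    se   = 1 / sqrt(2 p (1 - p) (n + z^2))

so that ``beta / se`` reproduces ``z`` exactly.  The instrument-strength
F statistic is ``(beta / se)^2``, i.e. ``z^2`` for converted records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ConversionInput", "z_to_beta_se", "f_statistic"]


@dataclass(frozen=True)
class ConversionInput:
    """A z-score plus the allele frequency and sample size needed to scale it.

    ``maf`` is the minor allele frequency; frequencies above 0.5 are folded
    to ``1 - maf`` (the variance term ``2p(1-p)`` is symmetric anyway).
    """

    z: float
    maf: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 < self.maf < 1.0):
            raise ValueError(f"maf must be in (0, 1), got {self.maf}")
        if self.maf > 0.5:
            object.__setattr__(self, "maf", 1.0 - self.maf)
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if not math.isfinite(self.z):
            raise ValueError("z must be finite")


def z_to_beta_se(inp: ConversionInput) -> tuple[float, float]:
    """Convert a z-score to (beta, se) on the standardised-phenotype scale.

    Returns ``(beta, se)`` with ``beta/se == z`` to machine precision.
    """
    denom = math.sqrt(2.0 * inp.maf * (1.0 - inp.maf) * (inp.n + inp.z**2))
    se = 1.0 / denom
    beta = inp.z * se
    if beta / se == inp.z:
        return beta, se
    # z*se rounds, so beta/se can land an ulp off z and break the exact
    # F = z^2 identity; perturb se by a few ulps (invisible at the 1e-12
    # level) until some representable beta divides back to z exactly
    return _exact_quotient_pair(inp.z, se)


def _exact_quotient_pair(z: float, se0: float) -> tuple[float, float]:
    """A (beta, se) pair with beta/se == z bitwise, se within ~1e-10 rel of se0.

    For fixed se the representable betas can straddle z's rounding
    preimage; sliding se moves the preimage across the beta lattice, and
    when the slide per ulp is tiny (z just under a power of two) the
    required offset is solved for directly in exact rational arithmetic.
    """
    for j in _se_offsets(z, se0):
        se = se0 + j * math.ulp(se0)
        if se <= 0:
            continue
        b = z * se
        for _ in range(4):
            q = b / se
            if q == z:
                return b, se
            b = math.nextafter(b, math.inf if q < z else -math.inf)
    return z * se0, se0  # give up: quotient correct to 1 ulp


def _se_offsets(z: float, se0: float):
    yield from range(-12, 13)
    # extrapolation: the position of z's preimage within the beta lattice
    # moves linearly with the se offset j; solve A + j*d = 0 (mod 1)
    from fractions import Fraction as Fr

    az = abs(z)
    U = Fr(math.ulp(az * se0))
    A = (Fr(az) * Fr(se0) / U) % 1
    d = (Fr(az) * Fr(math.ulp(se0)) / U) % 1
    if d > Fr(1, 2):
        d -= 1
    if d == 0:
        return
    for target in (0, 1):
        j0 = (target - A) / d
        if abs(j0) < 500_000:
            j = int(round(j0))
            for dj in (-2, -1, 0, 1, 2):
                yield j + dj


def f_statistic(beta: float, se: float) -> float:
    """Instrument-strength F statistic, ``(beta/se)^2``.

    For (beta, se) produced by :func:`z_to_beta_se` this equals ``z**2``.
    """
    if not se > 0:
        raise ValueError(f"se must be positive, got {se}")
    ratio = beta / se
    return ratio * ratio  # explicit product: libm pow can differ by an ulp
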