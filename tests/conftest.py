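from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from colocmr.sumstats import HarmonisedRegion, HarmonisedVariant, SumstatRecord

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_record(
    variant_id: str,
    pos: int = 1000,
    beta: float | None = None,
    se: float | None = None,
    z: float | None = None,
    eaf: float = 0.3,
    n: int = 30_000,
    chrom: str = "1",
    ea: str = "A",
    oa: str = "G",
    p: float | None = None,
) -> SumstatRecord:
    rec = SumstatRecord(
        variant_id=variant_id,
        chrom=chrom,
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        n=n,
        beta=beta,
        se=se,
        z=z,
        p=p,
    )
    rec.validate()
    return rec


def region_from_effects(
    beta_exp, se_exp, beta_out, se_out, ids=None, eafs=None
) -> HarmonisedRegion:
    """A harmonised region built directly from aligned effect arrays."""
    m = len(beta_exp)
    ids = ids or [f"rs{j}" for j in range(m)]
    eafs = eafs if eafs is not None else np.full(m, 0.3)
    variants = []
    for j in range(m):
        e = make_record(
            ids[j], pos=1000 + j, beta=float(beta_exp[j]), se=float(se_exp[j]),
            eaf=float(eafs[j]),
        )
        o = make_record(
            ids[j], pos=1000 + j, beta=float(beta_out[j]), se=float(se_out[j]),
            eaf=float(eafs[j]), n=520_000,
        )
        variants.append(HarmonisedVariant(ids[j], 1000 + j, e, o))
    return HarmonisedRegion(variants=variants)


@pytest.fixture
def rng():
    return np.random.default_rng(20240913)
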