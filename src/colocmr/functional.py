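"""Missense-variant instrument arm.

Colocalisation can miss true target effects when its one-causal-variant
assumption is violated, so the screen carries a second arm: missense
variants in the coding region of the target gene, associated with the
target's expression/protein level at p < 1e-5, are used individually as
biologically anchored MR instruments.  Candidates are LD-pruned to
independence (pairwise r^2 < 0.2 in a reference panel) greedily in order
of association p-value, the field convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coloc import _exposure_effect, _outcome_effect
from .mr import WaldEstimate, wald_ratio
from .sumstats import HarmonisedRegion

__all__ = [
    "MissenseCandidate",
    "LDMatrix",
    "ld_r2",
    "select_instruments",
    "mr_functional",
    "read_candidates",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MissenseCandidate:
    """A coding missense variant considered as an MR instrument.

    ``maf`` below 0.01 is flagged (rare coding variants are common among
    missense hits) but is an annotation, not a filter.
    """

    variant_id: str
    gene: str
    consequence: str
    maf: float
    assoc_p_exposure: float
    in_gene_region: bool = True

    def __post_init__(self) -> None:
        if self.consequence != "missense":
            raise ValueError(
                f"{self.variant_id}: consequence must be 'missense', got {self.consequence!r}"
            )
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.variant_id}: maf must be in (0, 0.5]")
        if not (0.0 < self.assoc_p_exposure <= 1.0):
            raise ValueError(f"{self.variant_id}: p must be in (0, 1]")

    @property
    def is_rare(self) -> bool:
        return self.maf < 0.01


@dataclass
class LDMatrix:
    """Pairwise squared dosage correlations over an ordered variant list."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variant_ids)
        if r2.shape != (n, n):
            raise ValueError(f"r2 must be {n}x{n}, got {r2.shape}")
        if not np.allclose(r2, r2.T, atol=1e-10):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-10):
            raise ValueError("r2 diagonal must be 1")
        if r2.min() < -1e-12 or r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        self.r2 = np.clip(r2, 0.0, 1.0)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    @classmethod
    def from_dosages(cls, dosages: np.ndarray, variant_ids: Sequence[str]) -> "LDMatrix":
        """LD from an (n_samples, n_variants) dosage matrix."""
        dosages = np.asarray(dosages, dtype=float)
        if dosages.std(axis=0).min() == 0:
            bad = [variant_ids[j] for j in np.flatnonzero(dosages.std(axis=0) == 0)]
            raise ValueError(f"monomorphic variants in panel: {bad}")
        r = np.corrcoef(dosages, rowvar=False)
        m = r * r
        np.fill_diagonal(m, 1.0)
        return cls(list(variant_ids), np.clip(m, 0.0, 1.0))

    def lookup(self, id_i: str, id_j: str) -> float:
        try:
            i, j = self._index[id_i], self._index[id_j]
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]!r} absent from LD matrix") from None
        return float(self.r2[i, j])


def ld_r2(genotypes: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of dosage columns i and j."""
    g = np.asarray(genotypes, dtype=float)
    xi, xj = g[:, i], g[:, j]
    if xi.std() == 0 or xj.std() == 0:
        raise ValueError("LD undefined for a monomorphic variant")
    r = np.corrcoef(xi, xj)[0, 1]
    return float(min(r * r, 1.0))


def select_instruments(
    candidates: Sequence[MissenseCandidate],
    ld: LDMatrix,
    p_threshold: float = 1e-5,
    r2_threshold: float = 0.2,
) -> list[str]:
    """Greedy p-value-ranked LD pruning of gene-region missense candidates.

    Keeps candidates with exposure association p < ``p_threshold``, sorts
    ascending by p (ties by variant id for determinism), and accepts a
    variant iff its r^2 with every already-accepted variant is below
    ``r2_threshold``.
    """
    eligible = [
        c
        for c in candidates
        if c.in_gene_region and c.assoc_p_exposure < p_threshold
    ]
    for c in eligible:
        if c.variant_id not in ld._index:
            raise KeyError(f"candidate {c.variant_id!r} absent from LD matrix")
    eligible.sort(key=lambda c: (c.assoc_p_exposure, c.variant_id))
    accepted: list[str] = []
    for c in eligible:
        if all(ld.lookup(c.variant_id, a) < r2_threshold for a in accepted):
            accepted.append(c.variant_id)
    return accepted


def mr_functional(
    selected: Sequence[str], region: HarmonisedRegion
) -> list[WaldEstimate]:
    """One Wald estimate per selected missense instrument, never combined."""
    estimates: list[WaldEstimate] = []
    for vid in selected:
        try:
            v = region.find(vid)
        except KeyError:
            logger.info("functional instrument %s missing from harmonised region; skipped", vid)
            continue
        b_exp, s_exp = _exposure_effect(v.exposure)
        b_out, s_out = _outcome_effect(v.outcome)
        estimates.append(wald_ratio(b_exp, s_exp, b_out, s_out, vid))
    return estimates


def read_candidates(path: str | Path) -> list[MissenseCandidate]:
    """Read a candidate table TSV (variant_id, gene, consequence, maf, p_exposure)."""
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "gene", "consequence", "maf", "p_exposure"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")
    out = []
    for r in df.itertuples():
        out.append(
            MissenseCandidate(
                variant_id=str(r.variant_id),
                gene=str(r.gene),
                consequence=str(r.consequence),
                maf=float(r.maf),
                assoc_p_exposure=float(r.p_exposure),
                in_gene_region=bool(getattr(r, "in_gene_region", True)),
            )
        )
    return out
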