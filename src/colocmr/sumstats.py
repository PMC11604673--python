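"""Reading, windowing and allele-harmonisation of GWAS summary statistics.

Exposure (eQTL/pQTL) and outcome (disease) summary statistics arrive as
delimited text in heterogeneous dialects; a column map names the logical
fields.  Records are validated, windowed to a cis-region, and the two
traits are aligned to a shared variant set with the outcome effects
re-signed to the exposure's effect allele.  Variants whose alleles match
neither directly nor swapped are dropped and counted, as are strand-
ambiguous palindromic (A/T, C/G) variants when requested.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .regions import RegionSpec

__all__ = [
    "SumstatRecord",
    "HarmonisedVariant",
    "HarmonisedRegion",
    "read_sumstats",
    "write_sumstats",
    "extract_region",
    "harmonise",
]

logger = logging.getLogger(__name__)

# logical field -> default column name
DEFAULT_COLUMNS: dict[str, str] = {
    "id": "variant_id",
    "chrom": "chrom",
    "pos": "pos",
    "ea": "effect_allele",
    "oa": "other_allele",
    "beta": "beta",
    "se": "se",
    "z": "z",
    "eaf": "eaf",
    "n": "n",
    "n_cases": "n_cases",
    "p": "p",
}

MANDATORY_FIELDS = ("id", "chrom", "pos", "ea", "oa", "eaf", "n")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SumstatRecord:
    """One variant's association summary for one trait.

    ``beta``/``se`` are per-SD units for quantitative traits and log-odds
    for case-control traits; either (beta, se) or ``z`` must be present.
    ``eaf`` is the effect-allele frequency in the source study.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    n: int
    beta: float | None = None
    se: float | None = None
    z: float | None = None
    n_cases: int | None = None
    p: float | None = None

    def validate(self) -> None:
        """Raise ValueError on any invariant violation."""
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        has_beta_se = self.beta is not None and self.se is not None
        if not has_beta_se and self.z is None:
            raise ValueError(f"{self.variant_id}: need (beta, se) or z")
        if self.se is not None and not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be positive")
        if not (0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.variant_id}: eaf must be in (0, 1)")
        if self.n <= 0:
            raise ValueError(f"{self.variant_id}: n must be positive")
        if self.p is not None and not (0.0 < self.p <= 1.0):
            raise ValueError(f"{self.variant_id}: p must be in (0, 1]")
        if has_beta_se and self.z is not None:
            if abs(self.z - self.beta / self.se) >= 1e-6 * max(1.0, abs(self.z)):
                raise ValueError(f"{self.variant_id}: z inconsistent with beta/se")

    @property
    def zscore(self) -> float:
        """The association z-score, from ``z`` or ``beta/se``."""
        if self.z is not None:
            return self.z
        return self.beta / self.se  # type: ignore[operator]

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def pvalue(self) -> float:
        """Stored p-value, or the two-sided normal p implied by the z-score."""
        if self.p is not None:
            return self.p
        return float(2.0 * stats.norm.sf(abs(self.zscore)))

    @property
    def is_palindromic(self) -> bool:
        return _COMPLEMENT.get(self.effect_allele) == self.other_allele

    def flipped(self) -> "SumstatRecord":
        """The same association expressed on the opposite effect allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            beta=None if self.beta is None else -self.beta,
            z=None if self.z is None else -self.z,
        )


@dataclass(frozen=True)
class HarmonisedVariant:
    variant_id: str
    pos: int
    exposure: SumstatRecord
    outcome: SumstatRecord
    outcome_flipped: bool = False


@dataclass
class HarmonisedRegion:
    """Allele-aligned exposure/outcome records on the shared variant set."""

    variants: list[HarmonisedVariant]
    region: RegionSpec | None = None
    n_dropped_allele_mismatch: int = 0
    n_dropped_ambiguous: int = 0
    drop_log: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.variants)

    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def find(self, variant_id: str) -> HarmonisedVariant:
        for v in self.variants:
            if v.variant_id == variant_id:
                return v
        raise KeyError(f"variant {variant_id!r} not in harmonised region")

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with provenance (whether the outcome was re-signed)."""
        rows = []
        for v in self.variants:
            rows.append(
                {
                    "variant_id": v.variant_id,
                    "chrom": v.exposure.chrom,
                    "pos": v.pos,
                    "effect_allele": v.exposure.effect_allele,
                    "other_allele": v.exposure.other_allele,
                    "eaf_exposure": v.exposure.eaf,
                    "beta_exposure": v.exposure.beta,
                    "se_exposure": v.exposure.se,
                    "z_exposure": v.exposure.zscore,
                    "n_exposure": v.exposure.n,
                    "beta_outcome": v.outcome.beta,
                    "se_outcome": v.outcome.se,
                    "n_outcome": v.outcome.n,
                    "outcome_flipped": v.outcome_flipped,
                }
            )
        return pd.DataFrame(rows)


def _coerce_optional(value, cast):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return cast(value)


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[SumstatRecord]:
    """Read one trait's summary statistics from delimited text.

    ``column_map`` maps logical fields (id, chrom, pos, ea, oa, beta, se,
    z, eaf, n, n_cases, p) to the file's column names; unmapped optional
    fields are simply absent.  Rows failing record validation are dropped
    with a logged count; duplicate variant ids keep the smallest p-value.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [cols[f] for f in MANDATORY_FIELDS if cols[f] not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")

    def col(field_name):
        name = cols[field_name]
        return df[name] if name in df.columns else None

    records: list[SumstatRecord] = []
    n_invalid = 0
    beta_c, se_c, z_c, ncases_c, p_c = (col(f) for f in ("beta", "se", "z", "n_cases", "p"))
    for i in range(len(df)):
        try:
            rec = SumstatRecord(
                variant_id=str(df[cols["id"]].iloc[i]),
                chrom=str(df[cols["chrom"]].iloc[i]),
                pos=int(df[cols["pos"]].iloc[i]),
                effect_allele=str(df[cols["ea"]].iloc[i]).upper(),
                other_allele=str(df[cols["oa"]].iloc[i]).upper(),
                eaf=float(df[cols["eaf"]].iloc[i]),
                n=int(df[cols["n"]].iloc[i]),
                beta=_coerce_optional(None if beta_c is None else beta_c.iloc[i], float),
                se=_coerce_optional(None if se_c is None else se_c.iloc[i], float),
                z=_coerce_optional(None if z_c is None else z_c.iloc[i], float),
                n_cases=_coerce_optional(None if ncases_c is None else ncases_c.iloc[i], int),
                p=_coerce_optional(None if p_c is None else p_c.iloc[i], float),
            )
            rec.validate()
        except (ValueError, TypeError) as exc:
            n_invalid += 1
            logger.debug("dropping row %d: %s", i, exc)
            continue
        records.append(rec)
    if n_invalid:
        logger.info("%s: dropped %d invalid rows", path, n_invalid)
    if not records:
        raise ValueError(f"{path}: no valid summary-statistic rows")
    records = _dedupe(records)
    return records


def _dedupe(records: list[SumstatRecord]) -> list[SumstatRecord]:
    """Keep the smallest-p record per variant id, preserving input order."""
    best: dict[str, SumstatRecord] = {}
    order: list[str] = []
    n_dup = 0
    for rec in records:
        if rec.variant_id not in best:
            best[rec.variant_id] = rec
            order.append(rec.variant_id)
        else:
            n_dup += 1
            if rec.pvalue < best[rec.variant_id].pvalue:
                best[rec.variant_id] = rec
    if n_dup:
        logger.info("resolved %d duplicate variant ids (kept smallest p)", n_dup)
    return [best[v] for v in order]


def write_sumstats(records: Iterable[SumstatRecord], path: str | Path) -> None:
    """Write records as TSV using the default column names."""
    rows = []
    for r in records:
        rows.append(
            {
                "variant_id": r.variant_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "beta": r.beta,
                "se": r.se,
                "z": r.z,
                "eaf": r.eaf,
                "n": r.n,
                "n_cases": r.n_cases,
                "p": r.p,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def extract_region(
    records: Sequence[SumstatRecord], region: RegionSpec
) -> list[SumstatRecord]:
    """Records on the region's chromosome within the closed flank window, by pos."""
    lo, hi = region.window
    kept = [r for r in records if r.chrom == region.chrom and lo <= r.pos <= hi]
    return sorted(kept, key=lambda r: r.pos)


def _check_unique(records: Sequence[SumstatRecord], label: str) -> None:
    seen: set[str] = set()
    for r in records:
        if r.variant_id in seen:
            raise ValueError(f"duplicate variant id {r.variant_id!r} in {label}")
        seen.add(r.variant_id)


AMBIGUOUS_EAF_BAND = (0.42, 0.58)


def harmonise(
    exposure: Sequence[SumstatRecord],
    outcome: Sequence[SumstatRecord],
    drop_ambiguous: bool = True,
    infer_palindromic: bool = False,
    region: RegionSpec | None = None,
) -> HarmonisedRegion:
    """Align outcome records to the exposure's allele coding on shared variants.

    Variants present in only one trait are excluded.  Where the outcome's
    alleles are swapped relative to the exposure, the outcome beta/z sign
    is flipped and its eaf replaced by 1-eaf.  Alleles matching neither
    directly nor swapped drop the variant (counted); palindromic variants
    are dropped when ``drop_ambiguous`` (the default, since strand cannot
    be resolved from summary data alone).  ``infer_palindromic`` instead
    aligns palindromic variants by allele frequency — concordant
    minor/major status keeps the coding, discordant flips it — dropping
    only those with either eaf inside the ambiguous band (0.42, 0.58),
    where frequency is uninformative.
    """
    _check_unique(exposure, "exposure")
    _check_unique(outcome, "outcome")
    out_by_id = {r.variant_id: r for r in outcome}
    variants: list[HarmonisedVariant] = []
    n_mismatch = 0
    n_ambiguous = 0
    drop_log: list[tuple[str, str]] = []
    lo_band, hi_band = AMBIGUOUS_EAF_BAND
    for e in sorted(exposure, key=lambda r: r.pos):
        o = out_by_id.get(e.variant_id)
        if o is None:
            continue
        if e.is_palindromic and drop_ambiguous:
            if not infer_palindromic:
                n_ambiguous += 1
                drop_log.append((e.variant_id, "palindromic"))
                continue
            # strand is unknowable from alleles, so align by frequency
            if lo_band < e.eaf < hi_band or lo_band < o.eaf < hi_band:
                n_ambiguous += 1
                drop_log.append((e.variant_id, "palindromic_ambiguous_eaf"))
                continue
            flipped = (o.eaf > 0.5) != (e.eaf > 0.5)
            if flipped:
                o = replace(
                    o.flipped(),
                    effect_allele=e.effect_allele,
                    other_allele=e.other_allele,
                )
            variants.append(HarmonisedVariant(e.variant_id, e.pos, e, o, flipped))
            continue
        flipped = False
        if (o.effect_allele, o.other_allele) == (e.effect_allele, e.other_allele):
            pass
        elif (o.other_allele, o.effect_allele) == (e.effect_allele, e.other_allele):
            o = o.flipped()
            flipped = True
        else:
            n_mismatch += 1
            drop_log.append((e.variant_id, "allele_mismatch"))
            continue
        variants.append(HarmonisedVariant(e.variant_id, e.pos, e, o, flipped))
    if n_mismatch or n_ambiguous:
        logger.info(
            "harmonise: kept %d variants, dropped %d allele-mismatch, %d palindromic",
            len(variants),
            n_mismatch,
            n_ambiguous,
        )
    return HarmonisedRegion(
        variants=variants,
        region=region,
        n_dropped_allele_mismatch=n_mismatch,
        n_dropped_ambiguous=n_ambiguous,
        drop_log=drop_log,
    )
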