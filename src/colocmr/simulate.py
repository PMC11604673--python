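"""LD-structured synthetic GWAS summary statistics with known ground truth.

The real screen consumes three large GWAS (a T1D case-control GWAS of
18,942 cases / 501,638 controls, a whole-blood eQTL GWAS of n = 31,684
and a serum pQTL GWAS of n = 35,559) that cannot ship with a package,
so every pipeline stage is exercised on simulated regional data instead.

The generator works at the summary-statistic level.  A reference panel
of haplotypes is drawn by thresholding an AR(1) latent Gaussian (adjacent
correlation ``ld_decay``) at each variant's MAF quantile; diploid dosages
are sums of two haplotypes and their empirical correlation matrix R plays
the role of the 1000 Genomes European LD reference.  Marginal z-score
vectors for the exposure and the outcome are then drawn from

    z ~ MVN(R @ lambda, R)

where ``lambda`` carries the non-centrality sqrt(2 p (1-p) n) * effect at
the causal variant(s) — zero, one or two of them according to the causal
architecture H0-H4.  For the binary outcome the effective sample size
4 / (1/n_cases + 1/n_controls) replaces n.  Exposure z-scores are
converted to (beta, se) with the standard quantitative-trait formulae;
outcome records carry log-odds beta = z * se with se = 1/sqrt(2p(1-p)n_eff).

Named presets reproduce the qualitative architectures of the screen's
motivating findings: a strongly protective shared-variant region
(il2ra_like), a risk-increasing shared-variant region (il6r_like), a
distinct-causal-variants region where MR must be skipped (jak2_like),
and a shared causal missense variant feeding the functional arm
(tyk2_missense).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .conversion import ConversionInput, z_to_beta_se
from .functional import LDMatrix, MissenseCandidate
from .regions import RegionSpec
from .sumstats import SumstatRecord

__all__ = [
    "SimScenario",
    "SimPanel",
    "SimOutput",
    "effective_n",
    "simulate_panel",
    "simulate_sumstats",
    "make_study_fixture",
    "PRESETS",
    "write_panel_vcf",
    "read_panel_vcf",
]

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")

# non-palindromic (effect, other) pairs only, so default harmonisation keeps all
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class SimScenario:
    """Ground-truth causal architecture and sampling design for one region.

    ``exposure_effect`` is the per-allele effect on the exposure in SD
    units of the trait; ``outcome_effect`` the per-allele log-odds on the
    outcome.  Under a shared causal variant the causal per-SD log-OR is
    ``outcome_effect / exposure_effect``.
    """

    hypothesis: str
    n_variants: int = 80
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_decay: float = 0.9
    exposure_effect: float = 0.0
    outcome_effect: float = 0.0
    n_exposure: int = 31_684
    n_cases: int = 18_942
    n_controls: int = 501_638
    causal_index_exposure: int | None = None
    causal_index_outcome: int | None = None
    seed: int = 0
    n_haplotypes: int = 1000
    gene: str = "GENE"
    chrom: str = "1"
    region_start: int = 1_000_000
    variant_spacing: int = 2_000

    def __post_init__(self) -> None:
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"hypothesis must be one of {HYPOTHESES}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.5 + 1e-12):
            raise ValueError("maf_range must lie within (0, 0.5)")
        if not (0.0 <= self.ld_decay < 1.0):
            raise ValueError("ld_decay must be in [0, 1)")
        ce, co = self.causal_index_exposure, self.causal_index_outcome
        if self.hypothesis == "H0" and (ce is not None or co is not None):
            raise ValueError("H0 admits no causal variants")
        if self.hypothesis == "H1" and ce is None:
            raise ValueError("H1 requires causal_index_exposure")
        if self.hypothesis == "H2" and co is None:
            raise ValueError("H2 requires causal_index_outcome")
        if self.hypothesis == "H3" and (ce is None or co is None or ce == co):
            raise ValueError("H3 requires distinct causal indices")
        if self.hypothesis == "H4" and (ce is None or ce != co):
            raise ValueError("H4 requires a single shared causal index")

    @property
    def n_eff_outcome(self) -> float:
        return effective_n(self.n_cases, self.n_controls)

    def positions(self) -> np.ndarray:
        return self.region_start + self.variant_spacing * np.arange(self.n_variants)

    def region_spec(self, flank_bp: int = 0) -> RegionSpec:
        pos = self.positions()
        return RegionSpec(self.gene, self.chrom, int(pos[0]), int(pos[-1]), flank_bp)


def effective_n(n_cases: int, n_controls: int) -> float:
    """Effective sample size for an (imbalanced) case-control GWAS."""
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


@dataclass
class SimPanel:
    """Synthetic diploid reference panel with its empirical LD."""

    dosages: np.ndarray  # (n_individuals, n_variants) alt-allele counts
    haplotypes: np.ndarray  # (n_haplotypes, n_variants) 0/1
    variant_ids: list[str]
    positions: np.ndarray
    mafs: np.ndarray
    R: np.ndarray  # empirical dosage correlation

    def ld_matrix(self) -> LDMatrix:
        return LDMatrix(list(self.variant_ids), self.R**2)


@dataclass
class SimOutput:
    """Paired synthetic summary statistics, panel, and embedded truth."""

    exposure_sumstats: list[SumstatRecord]
    outcome_sumstats: list[SumstatRecord]
    panel: SimPanel
    truth: SimScenario
    missense_candidates: list[MissenseCandidate] = field(default_factory=list)


def simulate_panel(
    scenario: SimScenario, rng: np.random.Generator | None = None
) -> SimPanel:
    """Draw the haplotype panel and record its empirical dosage correlation."""
    rng = rng or np.random.default_rng(scenario.seed)
    m = scenario.n_variants
    n_hap = scenario.n_haplotypes
    lo, hi = scenario.maf_range
    mafs = rng.uniform(lo, hi, size=m)

    # AR(1) latent Gaussian along the chromosome, thresholded at the MAF quantile
    rho = scenario.ld_decay
    latent = np.empty((n_hap, m))
    latent[:, 0] = rng.standard_normal(n_hap)
    innov_sd = math.sqrt(1.0 - rho * rho)
    for j in range(1, m):
        latent[:, j] = rho * latent[:, j - 1] + innov_sd * rng.standard_normal(n_hap)
    thresholds = stats.norm.ppf(mafs)
    haplotypes = (latent < thresholds).astype(np.int8)

    # guard against monomorphic columns in small panels
    for j in range(m):
        col = haplotypes[:, j]
        if col.min() == col.max():
            flip = rng.integers(n_hap)
            col[flip] = 1 - col[flip]

    n_ind = n_hap // 2
    dosages = haplotypes[:n_ind] + haplotypes[n_ind : 2 * n_ind]
    R = np.atleast_2d(np.corrcoef(dosages.astype(float), rowvar=False))
    np.fill_diagonal(R, 1.0)

    ids = [f"rs{scenario.seed % 1000}{j:04d}" for j in range(m)]
    return SimPanel(
        dosages=dosages,
        haplotypes=haplotypes,
        variant_ids=ids,
        positions=scenario.positions(),
        mafs=mafs,
        R=R,
    )


def _mvn_z(mean: np.ndarray, R: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw z ~ MVN(mean, R), jittering the diagonal if R is barely not PSD."""
    for jitter in (0.0, 1e-8, 1e-6):
        try:
            L = np.linalg.cholesky(R + jitter * np.eye(len(R)))
            break
        except np.linalg.LinAlgError:
            continue
    else:
        raise np.linalg.LinAlgError("LD matrix not positive semi-definite")
    return mean + L @ rng.standard_normal(len(R))


def simulate_sumstats(
    scenario: SimScenario,
    R: np.ndarray | None = None,
    panel: SimPanel | None = None,
) -> SimOutput:
    """Generate paired exposure/outcome summary statistics under the scenario.

    ``R`` defaults to the empirical correlation of a freshly drawn panel.
    """
    rng = np.random.default_rng(scenario.seed)
    if panel is None:
        panel = simulate_panel(scenario, rng)
    if R is None:
        R = panel.R
    m = scenario.n_variants
    mafs = panel.mafs

    lam_exp = np.zeros(m)
    lam_out = np.zeros(m)
    ce, co = scenario.causal_index_exposure, scenario.causal_index_outcome
    if ce is not None:
        p = mafs[ce]
        lam_exp[ce] = scenario.exposure_effect * math.sqrt(
            2.0 * p * (1.0 - p) * scenario.n_exposure
        )
    if co is not None:
        p = mafs[co]
        lam_out[co] = scenario.outcome_effect * math.sqrt(
            2.0 * p * (1.0 - p) * scenario.n_eff_outcome
        )
    if scenario.hypothesis == "H3":
        r2 = float(R[ce, co] ** 2)
        if r2 >= 0.3:
            raise ValueError(
                f"H3 causal variants too correlated (panel r^2 = {r2:.3f} >= 0.3); "
                "increase their separation or lower ld_decay"
            )

    z_exp = _mvn_z(R @ lam_exp, R, rng)
    z_out = _mvn_z(R @ lam_out, R, rng)

    n_total_out = scenario.n_cases + scenario.n_controls
    n_eff = scenario.n_eff_outcome
    pair_idx = rng.integers(len(_ALLELE_PAIRS), size=m)

    exposure, outcome = [], []
    for j in range(m):
        ea, oa = _ALLELE_PAIRS[pair_idx[j]]
        vid = panel.variant_ids[j]
        pos = int(panel.positions[j])
        maf = float(mafs[j])
        b, s = z_to_beta_se(ConversionInput(z=float(z_exp[j]), maf=maf, n=scenario.n_exposure))
        exposure.append(
            SumstatRecord(
                variant_id=vid,
                chrom=scenario.chrom,
                pos=pos,
                effect_allele=ea,
                other_allele=oa,
                eaf=maf,
                n=scenario.n_exposure,
                beta=b,
                se=s,
                z=float(z_exp[j]),
                p=float(2.0 * stats.norm.sf(abs(z_exp[j]))),
            )
        )
        se_out = 1.0 / math.sqrt(2.0 * maf * (1.0 - maf) * n_eff)
        outcome.append(
            SumstatRecord(
                variant_id=vid,
                chrom=scenario.chrom,
                pos=pos,
                effect_allele=ea,
                other_allele=oa,
                eaf=maf,
                n=n_total_out,
                n_cases=scenario.n_cases,
                beta=float(z_out[j]) * se_out,
                se=se_out,
                z=float(z_out[j]),
                p=float(2.0 * stats.norm.sf(abs(z_out[j]))),
            )
        )
    return SimOutput(
        exposure_sumstats=exposure,
        outcome_sumstats=outcome,
        panel=panel,
        truth=scenario,
    )


# ---------------------------------------------------------------------------
# Named study presets

_CENTER = 40

PRESETS: dict[str, SimScenario] = {
    # strongly protective shared causal variant; per-SD OR ~ 0.22
    "il2ra_like": SimScenario(
        hypothesis="H4",
        gene="IL2RA",
        exposure_effect=0.14,
        outcome_effect=0.14 * math.log(0.22),
        causal_index_exposure=_CENTER,
        causal_index_outcome=_CENTER,
        seed=10,
    ),
    # risk-increasing shared causal variant; per-SD OR ~ 1.98
    "il6r_like": SimScenario(
        hypothesis="H4",
        gene="IL6R",
        exposure_effect=0.11,
        outcome_effect=0.11 * math.log(1.98),
        causal_index_exposure=_CENTER,
        causal_index_outcome=_CENTER,
        seed=11,
    ),
    # distinct causal variants in weak LD: colocalisation must veto MR
    "jak2_like": SimScenario(
        hypothesis="H3",
        gene="JAK2",
        exposure_effect=0.14,
        outcome_effect=0.15,
        causal_index_exposure=25,
        causal_index_outcome=55,
        seed=12,
    ),
    # shared causal missense variant; per-SD OR ~ 0.61 via the functional arm
    "tyk2_missense": SimScenario(
        hypothesis="H4",
        gene="TYK2",
        exposure_effect=0.13,
        outcome_effect=0.13 * math.log(0.61),
        causal_index_exposure=_CENTER,
        causal_index_outcome=_CENTER,
        seed=13,
    ),
    # no causal variant for either trait
    "null": SimScenario(hypothesis="H0", gene="NULL", seed=14),
}


def make_study_fixture(preset: str, seed: int | None = None) -> SimOutput:
    """Instantiate a named preset (optionally re-seeded) end to end.

    The ``tyk2_missense`` preset additionally attaches a missense candidate
    table: the causal missense variant itself, a tight-LD neighbour that
    greedy pruning must remove, a distant null missense failing the
    p < 1e-5 association filter, and an out-of-gene-region decoy.
    """
    try:
        scenario = PRESETS[preset]
    except KeyError:
        raise KeyError(f"unknown preset {preset!r}; known: {sorted(PRESETS)}") from None
    if seed is not None:
        scenario = replace(scenario, seed=seed)
    sim = simulate_sumstats(scenario)
    if preset == "tyk2_missense":
        sim.missense_candidates = _tyk2_candidates(sim)
    return sim


def _tyk2_candidates(sim: SimOutput) -> list[MissenseCandidate]:
    ids = sim.panel.variant_ids
    c = sim.truth.causal_index_exposure
    gene = sim.truth.gene

    def cand(j: int, in_region: bool = True) -> MissenseCandidate:
        rec = sim.exposure_sumstats[j]
        return MissenseCandidate(
            variant_id=ids[j],
            gene=gene,
            consequence="missense",
            maf=rec.maf,
            assoc_p_exposure=max(rec.pvalue, 5e-324),
            in_gene_region=in_region,
        )

    return [cand(c), cand(c + 1), cand(c + 25), cand(c - 25, in_region=False)]


def write_sim_output(sim: SimOutput, out_dir: str | Path) -> dict[str, Path]:
    """Emit exposure.tsv, outcome.tsv, panel.vcf, truth.json (+ candidates.tsv)."""
    import dataclasses
    import json

    import pandas as pd

    from .sumstats import write_sumstats

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": out / "exposure.tsv",
        "outcome": out / "outcome.tsv",
        "panel": out / "panel.vcf",
        "truth": out / "truth.json",
    }
    write_sumstats(sim.exposure_sumstats, paths["exposure"])
    write_sumstats(sim.outcome_sumstats, paths["outcome"])
    write_panel_vcf(sim.panel, sim.exposure_sumstats, paths["panel"])
    with open(paths["truth"], "w") as fh:
        json.dump(dataclasses.asdict(sim.truth), fh, indent=2)
    if sim.missense_candidates:
        paths["candidates"] = out / "candidates.tsv"
        pd.DataFrame(
            [
                {
                    "variant_id": c.variant_id,
                    "gene": c.gene,
                    "consequence": c.consequence,
                    "maf": c.maf,
                    "p_exposure": c.assoc_p_exposure,
                    "in_gene_region": c.in_gene_region,
                }
                for c in sim.missense_candidates
            ]
        ).to_csv(paths["candidates"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Reference-panel VCF round-trip (pysam)


def write_panel_vcf(panel: SimPanel, records: Sequence[SumstatRecord], path: str | Path) -> None:
    """Write the diploid panel as a phased VCF; ALT is the effect allele."""
    import pysam

    by_id = {r.variant_id: r for r in records}
    n_ind = panel.dosages.shape[0]
    samples = [f"S{i:04d}" for i in range(n_ind)]
    header = pysam.VariantHeader()
    chrom = by_id[panel.variant_ids[0]].chrom
    header.add_line(f"##contig=<ID={chrom},length={int(panel.positions[-1]) + 10_000}>")
    header.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", "1"), ("Type", "String"), ("Description", "Genotype")],
    )
    for s in samples:
        header.add_sample(s)
    h1 = panel.haplotypes[:n_ind]
    h2 = panel.haplotypes[n_ind : 2 * n_ind]
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j, vid in enumerate(panel.variant_ids):
            rec = by_id[vid]
            out = vf.new_record(
                contig=rec.chrom,
                start=int(panel.positions[j]) - 1,
                stop=int(panel.positions[j]),
                alleles=(rec.other_allele, rec.effect_allele),
                id=vid,
            )
            for i, s in enumerate(samples):
                out.samples[s]["GT"] = (int(h1[i, j]), int(h2[i, j]))
                out.samples[s].phased = True
            vf.write(out)


def read_panel_vcf(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Load alt-allele dosages (n_samples, n_variants) and variant ids from a VCF."""
    import pysam

    dosage_cols: list[np.ndarray] = []
    ids: list[str] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            gts = [rec.samples[s]["GT"] for s in rec.samples]
            dosage_cols.append(np.array([a + b for a, b in gts], dtype=float))
            ids.append(rec.id)
    return np.column_stack(dosage_cols), ids
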