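"""End-to-end screen orchestration and report writing.

For each configured target the screen runs: window the summary statistics
to the gene's cis-region, harmonise the two traits to a shared allele-
aligned variant set, colocalise, and — only when P(H4) clears the gate —
estimate the Wald ratio at the lead shared causal variant.  A functional
arm, when configured, LD-prunes missense candidates and adds one single-
variant MR estimate per independent instrument.  Genes with both eQTL
and pQTL exposure files appear as separate coloc rows; targets with no
exposure data yield an explicit no-data row rather than silent omission.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coloc import ColocPriors, ColocResult, EffectPrior, coloc_abf
from .functional import LDMatrix, mr_functional, read_candidates, select_instruments
from .mr import ColocSkip, WaldEstimate, mr_from_coloc
from .regions import RegionSpec, builtin_region
from .sumstats import HarmonisedRegion, extract_region, harmonise, read_sumstats

__all__ = [
    "TargetSpec",
    "FunctionalConfig",
    "ScreenConfig",
    "ScreenReport",
    "run_screen",
    "write_report",
    "load_config",
    "format_pp",
    "format_p",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetSpec:
    """One (gene, exposure trait) pair to screen against the outcome GWAS."""

    gene: str
    trait_type: str  # "eQTL" or "pQTL"
    exposure_file: str | None
    outcome_file: str
    region: RegionSpec | None = None

    def resolve_region(self) -> RegionSpec:
        return self.region if self.region is not None else builtin_region(self.gene)


@dataclass(frozen=True)
class FunctionalConfig:
    candidates_file: str
    panel_file: str | None = None  # VCF reference panel
    ld_file: str | None = None  # or a precomputed square r^2 TSV
    p_threshold: float = 1e-5
    r2_threshold: float = 0.2


@dataclass
class ScreenConfig:
    targets: list[TargetSpec]
    priors: ColocPriors = field(default_factory=ColocPriors)
    effect_prior: EffectPrior = field(default_factory=EffectPrior)
    h4_threshold: float = 0.8
    functional: FunctionalConfig | None = None
    drop_ambiguous: bool = True
    output_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("at least one target required")

    def semantic_dict(self) -> dict[str, Any]:
        """The fields that define the analysis (for the config hash)."""
        return {
            "targets": [
                {
                    "gene": t.gene,
                    "trait_type": t.trait_type,
                    "exposure_file": t.exposure_file,
                    "outcome_file": t.outcome_file,
                    "region": None
                    if t.region is None
                    else [t.region.gene, t.region.chrom, t.region.start, t.region.end, t.region.flank_bp],
                }
                for t in self.targets
            ],
            "priors": [self.priors.p1, self.priors.p2, self.priors.p12],
            "effect_prior": [self.effect_prior.sd_quant, self.effect_prior.sd_binary],
            "h4_threshold": self.h4_threshold,
            "drop_ambiguous": self.drop_ambiguous,
            "functional": None
            if self.functional is None
            else [
                self.functional.candidates_file,
                self.functional.panel_file,
                self.functional.ld_file,
                self.functional.p_threshold,
                self.functional.r2_threshold,
            ],
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.semantic_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ScreenReport:
    coloc_table: pd.DataFrame
    mr_table: pd.DataFrame
    skipped: list[dict[str, Any]]
    metadata: dict[str, Any]


def _coloc_row(gene: str, trait: str, res: ColocResult | None, status: str) -> dict[str, Any]:
    row: dict[str, Any] = {"gene": gene, "trait": trait, "status": status}
    for i, h in enumerate(("H0", "H1", "H2", "H3", "H4")):
        row[h] = None if res is None else float(res.pp[i])
    row["lead_variant"] = None if res is None else res.lead_variant
    row["n_variants"] = None if res is None else res.n_variants
    return row


def _mr_row(gene: str, trait: str, arm: str, est: WaldEstimate) -> dict[str, Any]:
    return {
        "target": gene,
        "trait": trait,
        "arm": arm,
        "instrument": est.instrument,
        "theta": est.theta,
        "se_theta": est.se_theta,
        "or_": est.or_,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "p": est.p,
        "f_stat": est.f_stat,
        "weak_instrument": est.weak_instrument,
    }


def _load_functional_ld(cfg: FunctionalConfig) -> LDMatrix:
    if cfg.ld_file is not None:
        df = pd.read_csv(cfg.ld_file, sep="\t", index_col=0)
        return LDMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))
    if cfg.panel_file is not None:
        from .simulate import read_panel_vcf

        dosages, ids = read_panel_vcf(cfg.panel_file)
        return LDMatrix.from_dosages(dosages, ids)
    raise ValueError("functional arm needs panel_file or ld_file")


def run_screen(config: ScreenConfig) -> ScreenReport:
    """Run the full colocalisation-gated MR screen over all targets."""
    coloc_rows: list[dict[str, Any]] = []
    mr_rows: list[dict[str, Any]] = []
    skipped: list[dict[str, Any]] = []
    harmonised: dict[str, HarmonisedRegion] = {}
    n_failed = 0

    candidates = ld = None
    if config.functional is not None:
        candidates = read_candidates(config.functional.candidates_file)
        ld = _load_functional_ld(config.functional)

    for target in config.targets:
        label = f"{target.gene}/{target.trait_type}"
        if target.exposure_file is None:
            logger.info("%s: no exposure data available", label)
            coloc_rows.append(_coloc_row(target.gene, target.trait_type, None, "no-data"))
            continue
        try:
            region = target.resolve_region()
            exposure = read_sumstats(target.exposure_file)
            outcome = read_sumstats(target.outcome_file)
            exp_region = extract_region(exposure, region)
            out_region = extract_region(outcome, region)
            harm = harmonise(
                exp_region, out_region, drop_ambiguous=config.drop_ambiguous, region=region
            )
            logger.info(
                "%s: %d shared variants (%d mismatch, %d palindromic dropped)",
                label,
                len(harm),
                harm.n_dropped_allele_mismatch,
                harm.n_dropped_ambiguous,
            )
            res = coloc_abf(harm, config.priors, config.effect_prior)
        except (OSError, ValueError, KeyError) as exc:
            logger.error("%s: failed (%s)", label, exc)
            coloc_rows.append(_coloc_row(target.gene, target.trait_type, None, f"error: {exc}"))
            n_failed += 1
            continue
        harmonised[target.gene] = harm
        coloc_rows.append(_coloc_row(target.gene, target.trait_type, res, "ok"))
        est = mr_from_coloc(harm, res, threshold=config.h4_threshold)
        if isinstance(est, ColocSkip):
            logger.info("%s: MR skipped, P(H4) = %.3f <= %.2f", label, est.pp_h4, est.threshold)
            skipped.append(
                {"target": target.gene, "trait": target.trait_type, "pp_h4": est.pp_h4}
            )
        else:
            mr_rows.append(_mr_row(target.gene, target.trait_type, "coloc-lead", est))

    if candidates is not None:
        assert ld is not None
        by_gene: dict[str, list] = {}
        for c in candidates:
            by_gene.setdefault(c.gene, []).append(c)
        for gene, gene_cands in by_gene.items():
            harm = harmonised.get(gene)
            if harm is None:
                logger.info("functional arm: no harmonised region for %s; skipped", gene)
                continue
            chosen = select_instruments(
                gene_cands,
                ld,
                p_threshold=config.functional.p_threshold,
                r2_threshold=config.functional.r2_threshold,
            )
            for est in mr_functional(chosen, harm):
                mr_rows.append(_mr_row(gene, "missense", "functional", est))

    if n_failed and n_failed == sum(1 for t in config.targets if t.exposure_file is not None):
        raise RuntimeError("all targets failed")

    meta = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "h4_threshold": config.h4_threshold,
    }
    coloc_cols = ["gene", "trait", "status", "H0", "H1", "H2", "H3", "H4", "lead_variant", "n_variants"]
    mr_cols = [
        "target", "trait", "arm", "instrument", "theta", "se_theta",
        "or_", "ci_low", "ci_high", "p", "f_stat", "weak_instrument",
    ]
    return ScreenReport(
        coloc_table=pd.DataFrame(coloc_rows, columns=coloc_cols),
        mr_table=pd.DataFrame(mr_rows, columns=mr_cols),
        skipped=skipped,
        metadata=meta,
    )


def format_pp(x: float | None) -> str:
    """Posterior probability as a percentage to one decimal."""
    return "" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{100.0 * x:.1f}"


def format_p(p: float) -> str:
    """p-value at two significant figures (scientific when small)."""
    return f"{p:.2g}"


def write_report(report: ScreenReport, out_dir: str | Path, fmt: str = "tsv") -> dict[str, Path]:
    """Write coloc.tsv / mr.tsv (display-formatted) and report.json (full precision)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if fmt not in ("tsv", "json"):
        raise ValueError(f"unknown report format {fmt!r}")

    coloc_disp = report.coloc_table.copy()
    for h in ("H0", "H1", "H2", "H3", "H4"):
        coloc_disp[h] = [format_pp(x) for x in coloc_disp[h]]
    mr_disp = report.mr_table.copy()
    if len(mr_disp):
        mr_disp["or_95ci"] = [
            f"{r.or_:.2f} ({r.ci_low:.2f}, {r.ci_high:.2f})" for r in report.mr_table.itertuples()
        ]
        mr_disp["p"] = [format_p(p) for p in report.mr_table["p"]]
        mr_disp["f_stat"] = [f"{f:.1f}" for f in report.mr_table["f_stat"]]
        mr_disp = mr_disp[["target", "trait", "arm", "instrument", "or_95ci", "p", "f_stat"]]
    else:
        mr_disp = pd.DataFrame(
            columns=["target", "trait", "arm", "instrument", "or_95ci", "p", "f_stat"]
        )

    if fmt == "tsv":
        paths["coloc"] = out / "coloc.tsv"
        coloc_disp.to_csv(paths["coloc"], sep="\t", index=False)
        paths["mr"] = out / "mr.tsv"
        mr_disp.to_csv(paths["mr"], sep="\t", index=False)

    payload = {
        "metadata": report.metadata,
        "coloc": report.coloc_table.to_dict(orient="records"),
        "mr": report.mr_table.to_dict(orient="records"),
        "skipped": report.skipped,
    }
    paths["json"] = out / "report.json"
    with open(paths["json"], "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return paths


def load_config(path: str | Path) -> ScreenConfig:
    """Build a ScreenConfig from a YAML/JSON file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    targets = []
    for t in raw["targets"]:
        region = None
        if "region" in t and t["region"] is not None:
            r = t["region"]
            region = RegionSpec(
                r.get("gene", t["gene"]),
                str(r["chrom"]),
                int(r["start"]),
                int(r["end"]),
                int(r.get("flank_bp", 1_000_000)),
            )
        targets.append(
            TargetSpec(
                gene=t["gene"],
                trait_type=t.get("trait_type", "eQTL"),
                exposure_file=t.get("exposure_file"),
                outcome_file=t["outcome_file"],
                region=region,
            )
        )
    priors = ColocPriors(**raw.get("priors", {}))
    effect_prior = EffectPrior(**raw.get("effect_prior", {}))
    functional = None
    if raw.get("functional"):
        functional = FunctionalConfig(**raw["functional"])
    return ScreenConfig(
        targets=targets,
        priors=priors,
        effect_prior=effect_prior,
        h4_threshold=float(raw.get("h4_threshold", 0.8)),
        functional=functional,
        drop_ambiguous=bool(raw.get("drop_ambiguous", True)),
        output_dir=str(raw.get("output_dir", ".")),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )
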