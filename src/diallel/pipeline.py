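"""End-to-end pipeline: simulate/load → cross → phenotype → decompose → scan.

The pipeline is driven by a :class:`PipelineConfig` (round-trippable through
YAML), executes the stages in order, writes every stage's tables as TSV
under the output directory, and finishes with a JSON manifest recording the
config, seeds, and a checksum per output file so reruns are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, design, griffing, inheritance, io, pheno, simdata

logger = logging.getLogger("diallel.pipeline")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Either ``genotypes_vcf`` + ``replicates_tsv`` point at existing inputs,
    or ``simulate=True`` generates them from the simulation block.  Every
    stochastic stage derives its seed from ``seed``.
    """

    out_dir: str = "diallel_run"
    seed: int = 1
    simulate: bool = True
    genotypes_vcf: str | None = None
    replicates_tsv: str | None = None
    # simulation block
    n_founders: int = 10
    n_sites: int = 500
    n_chromosomes: int = 16
    n_conditions: int = 3
    n_causal: int = 10
    additive_sd: float = 0.1
    dominance_fraction: float = 0.2
    overdominant_fraction: float = 0.05
    env_sd: float = 0.05
    n_replicates_hybrid: int = 6
    n_replicates_parent: int = 54
    # analysis block
    scheme: str = "half+diag"
    encodings: tuple[str, ...] = ("additive", "overdominant")
    n_perm: int = 100
    alpha: float = 0.05
    maf_low: float = 0.05
    maf_rare: float = 0.01

    def to_yaml(self, path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        if "encodings" in raw:
            raw["encodings"] = tuple(raw["encodings"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary.

    Stages: simulate (or load) founders and replicate table → enumerate
    crosses and synthesize hybrid genotypes (after site filtering and
    long-range LD pruning) → aggregate replicates into phenotypes →
    combining abilities and heritabilities per condition → inheritance-mode
    classification → dual-encoding mixed-model GWAS with permutation
    thresholds and MAF-enrichment summary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    manifest: dict = {"config": dataclasses.asdict(config), "outputs": {}}

    def _write(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        frame.to_csv(path, sep="\t", index=False)
        manifest["outputs"][name] = _sha256(path)

    try:
        stage = "simulate"
        if config.simulate:
            founders = simdata.simulate_founders(
                config.n_founders,
                config.n_sites,
                n_chromosomes=config.n_chromosomes,
                seed=config.seed,
            )
            if config.scheme == "full":
                crosses = design.enumerate_full_diallel(founders.parent_ids)
            else:
                crosses = design.enumerate_half_diallel(
                    founders.parent_ids, include_diagonal=config.scheme == "half+diag"
                )
            models = {
                f"cond{k+1}": simdata.simulate_trait_model(
                    founders,
                    n_causal=config.n_causal,
                    additive_sd=config.additive_sd,
                    dominance_fraction=config.dominance_fraction,
                    overdominant_fraction=config.overdominant_fraction,
                    env_sd=config.env_sd,
                    seed=config.seed * 1000 + k,
                )
                for k in range(config.n_conditions)
            }
            replicates = simdata.simulate_colony_data(
                founders,
                crosses,
                models,
                n_replicates_hybrid=config.n_replicates_hybrid,
                n_replicates_parent=config.n_replicates_parent,
                seed=config.seed + 7,
            )
            io.write_vcf(founders, out / "founders.vcf")
            manifest["outputs"]["founders.vcf"] = _sha256(out / "founders.vcf")
            _write("replicates.tsv", replicates)
        else:
            stage = "load"
            if not config.genotypes_vcf or not Path(config.genotypes_vcf).exists():
                raise FileNotFoundError(f"genotype input missing: {config.genotypes_vcf}")
            founders = io.read_vcf(config.genotypes_vcf)
            if config.scheme == "full":
                crosses = design.enumerate_full_diallel(founders.parent_ids)
            else:
                crosses = design.enumerate_half_diallel(
                    founders.parent_ids, include_diagonal=config.scheme == "half+diag"
                )

        stage = "design"
        founders, filter_report = design.filter_sites(founders)
        founders, prune_report = design.prune_long_range_ld(founders)
        manifest["filter_report"] = filter_report
        manifest["prune_report"] = {
            k: v for k, v in prune_report.items() if k != "classes"
        }
        panel = design.synthesize_hybrid_genotypes(founders, crosses)

        stage = "pheno"
        if not config.simulate:
            if not config.replicates_tsv or not Path(config.replicates_tsv).exists():
                raise FileNotFoundError(f"phenotype input missing: {config.replicates_tsv}")
            replicates = io.read_replicates_tsv(config.replicates_tsv)
        phenotypes = pheno.aggregate_replicates(replicates)
        _write("phenotypes.tsv", phenotypes.summary)

        stage = "griffing"
        results = griffing.analyze_diallel(phenotypes, panel)
        herit = griffing.heritability_summary(results)
        _write("heritability.tsv", herit)
        gca_rows = []
        for cond, res in results.items():
            for parent, g in res.gca.items():
                gca_rows.append({"condition": cond, "parent": parent, "gca": g,
                                 "e_g": res.e_g[parent]})
        _write("gca.tsv", pd.DataFrame(gca_rows))
        sca_rows = []
        for cond, res in results.items():
            for (p1, p2), s in res.sca.items():
                sca_rows.append({"condition": cond, "parent1": p1, "parent2": p2,
                                 "sca": s, "e_s": res.e_s[(p1, p2)]})
        _write("sca.tsv", pd.DataFrame(sca_rows))

        stage = "inheritance"
        inh_frames, inh_summaries = [], []
        for cond in phenotypes.conditions():
            calls = inheritance.classify_panel(phenotypes, panel, cond)
            if not calls:
                continue
            inh_frames.append(inheritance.calls_to_frame(calls))
            summ = inheritance.summarize_condition(calls)
            inh_summaries.append(
                {
                    "condition": cond,
                    "fraction_separable": summ["fraction_separable"],
                    "predominant_modes": ";".join(summ["predominant_modes"]),
                    "overdominance_fraction": summ["overdominance_fraction_all"],
                    "underdominance_fraction": summ["underdominance_fraction_all"],
                }
            )
        if inh_frames:
            _write("inheritance_calls.tsv", pd.concat(inh_frames, ignore_index=True))
            _write("inheritance_summary.tsv", pd.DataFrame(inh_summaries))

        stage = "assoc"
        assoc_frames = []
        for cond in phenotypes.conditions():
            assoc_frames.append(
                assoc.association_scan(
                    panel,
                    phenotypes,
                    cond,
                    encodings=config.encodings,
                    n_perm=config.n_perm,
                    alpha=config.alpha,
                    seed=config.seed + 13,
                )
            )
        results_df = pd.concat(assoc_frames, ignore_index=True)
        _write("associations.tsv", results_df)
        if results_df["maf_source"].notna().any():
            enrich = assoc.maf_enrichment(
                results_df, {"low": config.maf_low, "rare": config.maf_rare}
            )
            enrich.pop("scatter", None)
            manifest["maf_enrichment"] = enrich

        stage = "manifest"
        manifest["seed"] = config.seed
        with (out / "manifest.json").open("w") as fh:
            json.dump(manifest, fh, indent=2, default=float)
        logger.info("pipeline complete: %s", out)
        return manifest
    except Exception as exc:
        logger.exception("pipeline failed at stage %r", stage)
        raise PipelineError(stage) from exc


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str):
        super().__init__(f"pipeline failed at stage {stage!r}")
        self.stage = stage
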