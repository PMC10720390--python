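"""End-to-end pipeline: simulate/ingest -> classify -> PRS -> association ->
absolute risk, driven by a single YAML config, with a reproducible run
manifest (config snapshot, seeds, file digests, warnings)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .absolute_risk import (
    cohort_category_frequencies,
    curves_to_frame,
    monte_carlo_ci,
    monte_carlo_ci_weighted,
)
from .association import fit_joint_model, fit_marginal_models, test_interaction, write_covariance, write_or_table
from .io_cohort import assemble_cohort, logger, read_dosages, read_phenotypes, read_rate_schedule, read_scoring_file
from .prs import score_and_categorize
from .synthetic_data import (
    SimConfig,
    generate_annotations,
    generate_cohort,
    generate_rare_genotypes,
    generate_rates,
    write_rare_inputs,
)
from .variant_classify import (
    DEFAULT_GENE_PANEL,
    INSILICO_RULES,
    classify_variants,
    determine_carriers,
    read_annotations,
    write_classifications,
)

_SCHEMA = {
    "seed": int,
    "outdir": str,
    "simulate": dict,
    "inputs": dict,
    "classify": dict,
    "prs": dict,
    "assoc": dict,
    "absrisk": dict,
}


class ConfigError(ValueError):
    """The run config violates the schema."""


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    outputs: dict = field(default_factory=dict)
    digests: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def add(self, name: str, path) -> None:
        p = Path(path)
        self.outputs[name] = str(p)
        self.digests[name] = hashlib.sha256(p.read_bytes()).hexdigest()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "seed": self.seed,
                    "config": self.config,
                    "outputs": self.outputs,
                    "sha256": self.digests,
                    "warnings": self.warnings,
                },
                fh,
                indent=2,
                default=str,
            )


def _validate(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    for key, val in cfg.items():
        if key not in _SCHEMA:
            raise ConfigError(f"unknown config field {key!r}")
        if not isinstance(val, _SCHEMA[key]):
            raise ConfigError(f"config field {key!r} must be {(_SCHEMA[key]).__name__}, got {type(val).__name__}")
    if "seed" not in cfg:
        raise ConfigError("config field 'seed' is required")
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ConfigError("config needs a 'simulate' block or an 'inputs' block")
    rule = cfg.get("classify", {}).get("insilico_rule", "all")
    if rule not in INSILICO_RULES:
        raise ConfigError(f"classify.insilico_rule must be one of {INSILICO_RULES}")
    if "inputs" in cfg:
        for k, p in cfg["inputs"].items():
            if not Path(p).exists():
                raise ConfigError(f"input {k!r} does not exist: {p}")


def run_pipeline(config_path) -> RunManifest:
    """Execute all stages in dependency order; identical config + seed
    reproduces identical output digests."""
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    _validate(cfg)
    seed = int(cfg["seed"])
    outdir = Path(cfg.get("outdir", "polyrisk_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=seed)

    # --- stage: simulate or ingest -----------------------------------------
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"])
        n_plpd = int(sim_kwargs.pop("n_plpd", 51))
        n_benign = int(sim_kwargs.pop("n_benign", 100))
        rate_shape = sim_kwargs.pop("rate_shape", "exponential-increase")
        rate_scale = float(sim_kwargs.pop("rate_scale", 0.0005))
        if "allele_freq_range" in sim_kwargs:
            sim_kwargs["allele_freq_range"] = tuple(sim_kwargs["allele_freq_range"])
        sim = generate_cohort(SimConfig(seed=seed, **sim_kwargs))
        paths = sim.write(outdir / "sim")
        records, truth = generate_annotations(n_plpd=n_plpd, n_benign=n_benign, seed=seed + 1)
        rare_geno = generate_rare_genotypes(sim.carrier_truth, truth, seed=seed + 2)
        rates = generate_rates(rate_shape, rate_scale)
        paths.update(write_rare_inputs(outdir / "sim", records, truth, rare_geno, rates))
        for k, p in paths.items():
            manifest.add(f"sim_{k}", p)
        scoring_path, dosage_path = paths["scoring"], paths["dosages"]
        pheno_path, annot_path = paths["phenotypes"], paths["annotations"]
        rare_geno_path, rates_path = paths["rare_genotypes"], paths["rates"]
    else:
        ins = cfg["inputs"]
        try:
            scoring_path, dosage_path = ins["scoring"], ins["dosages"]
            pheno_path, annot_path = ins["phenotypes"], ins["annotations"]
            rare_geno_path, rates_path = ins["rare_genotypes"], ins["rates"]
        except KeyError as e:
            raise ConfigError(f"inputs block missing entry {e}") from e

    scoring = read_scoring_file(scoring_path)
    dosages = read_dosages(dosage_path)
    phenotypes = read_phenotypes(pheno_path)
    rates = read_rate_schedule(rates_path)

    # --- stage: classify ----------------------------------------------------
    ccfg = cfg.get("classify", {})
    panel = frozenset(ccfg.get("genes", sorted(DEFAULT_GENE_PANEL)))
    results = classify_variants(read_annotations(annot_path), panel, ccfg.get("insilico_rule", "all"))
    class_path = outdir / "classification.tsv"
    write_classifications(results, class_path)
    manifest.add("classification", class_path)
    rare_geno = pd.read_csv(rare_geno_path, sep="\t", dtype={"individual_id": str}).set_index("individual_id")
    carriers = determine_carriers(rare_geno, results)

    # --- stage: PRS ---------------------------------------------------------
    control_ids = [p.individual_id for p in phenotypes if p.status == "control"]
    prs_results, prs_report = score_and_categorize(scoring, dosages, control_ids,
                                                   standardize=bool(cfg.get("prs", {}).get("standardize", False)))
    prs_path = outdir / "prs.tsv"
    prs_results.to_csv(prs_path, sep="\t", index_label="individual_id")
    manifest.add("prs", prs_path)
    if prs_report.dropped_low_maf or prs_report.dropped_absent:
        manifest.warnings.append(
            f"prs: dropped {len(prs_report.dropped_low_maf)} low-MAF and "
            f"{len(prs_report.dropped_absent)} absent variants"
        )

    cohort, join_report = assemble_cohort(phenotypes, dosages, carriers, prs_results)
    cohort_path = outdir / "cohort.tsv"
    cohort.to_csv(cohort_path, sep="\t", index_label="individual_id")
    manifest.add("cohort", cohort_path)
    if join_report.drops:
        manifest.warnings.append(f"assemble_cohort: dropped {join_report.drops} rows")

    # --- stage: association -------------------------------------------------
    acfg = cfg.get("assoc", {})
    outcomes = acfg.get("outcomes", ["overall", "aggressive", "nonaggressive", "metastatic"])
    tables = {}
    for outcome in outcomes:
        table = fit_joint_model(cohort, outcome, firth=bool(acfg.get("firth", False)))
        tables[outcome] = table
        p = outdir / f"or_{outcome}.tsv"
        write_or_table(table, p)
        manifest.add(f"or_{outcome}", p)
        pc = outdir / f"cov_{outcome}.tsv"
        write_covariance(table, pc)
        manifest.add(f"cov_{outcome}", pc)
    carrier_tab, prs_tab = fit_marginal_models(cohort, "overall")
    for name, tab in (("carrier_marginal", carrier_tab), ("prs_marginal", prs_tab)):
        p = outdir / f"or_{name}.tsv"
        write_or_table(tab, p)
        manifest.add(f"or_{name}", p)
    inter = test_interaction(cohort, "overall")
    inter_path = outdir / "interaction.json"
    with open(inter_path, "w") as fh:
        json.dump(vars(inter), fh, indent=2)
    manifest.add("interaction", inter_path)

    # --- stage: absolute risk -----------------------------------------------
    rcfg = cfg.get("absrisk", {})
    age_start, age_end = int(rcfg.get("age_start", 40)), int(rcfg.get("age_end", 85))
    n_iter = int(rcfg.get("n_iter", 1000))
    prevalence = float(rcfg.get("prevalence", 0.167))
    w_agg = float(rcfg.get("w_agg", 0.37))
    freqs = cohort_category_frequencies(cohort, prevalence=prevalence)
    rates = rates.restrict(age_start, age_end)
    if "aggressive" in tables and "nonaggressive" in tables:
        curves = monte_carlo_ci_weighted(tables["aggressive"], tables["nonaggressive"], freqs,
                                         rates, w_agg=w_agg, n_iter=n_iter, seed=seed + 3,
                                         age_start=age_start, age_end=age_end)
    else:
        curves = monte_carlo_ci(tables[outcomes[0]], freqs, rates, n_iter=n_iter, seed=seed + 3,
                                age_start=age_start, age_end=age_end)
    ar_path = outdir / "absolute_risk.tsv"
    curves_to_frame(curves).to_csv(ar_path, sep="\t", index=False)
    manifest.add("absolute_risk", ar_path)

    meta_path = outdir / "run_manifest.json"
    manifest.write(meta_path)
    logger.info("pipeline complete: %d outputs under %s", len(manifest.outputs), outdir)
    return manifest
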