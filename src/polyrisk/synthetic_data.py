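"""Synthetic cohort generator.

Emulates a case-control study of disease risk driven by rare pathogenic
variant carrier status and a common-variant polygenic score:

* PRS variant dosages are binomial(2, f_j) with f_j uniform over a
  configurable allele-frequency range; weights are drawn once and fixed.
* Carrier status is Bernoulli; the underlying frequency is solved so that the
  expected frequency AMONG CONTROLS matches the configured value (0.6% by
  default, as carriers are enriched in cases).
* Disease status follows a logistic model on carrier status, PRS-tertile
  indicators (tertiles of the generated score distribution), an optional
  continuous per-SD PRS term, an optional tertile-x-carrier product term, and
  small age/study/PC nuisance effects; the intercept is solved numerically so
  the realized case fraction matches the configured (case-enriched) design.
* Case type is a mixture: 37% aggressive by default, with a metastatic
  subset; clinical fields (Gleason, stage, PSA, death) are filled so the
  phenotype classifier reproduces the intended labels, using staging for US
  studies and PSA rules for the Ugandan study.

The generator does not model LD between PRS variants, haplotypes, dosage
uncertainty or relatedness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io_cohort import (
    PhenotypeRecord,
    RateSchedule,
    write_dosages,
    write_rate_schedule,
    write_scoring_file,
)
from .variant_classify import (
    DEFAULT_GENE_PANEL,
    INSILICO_TOOLS,
    VariantAnnotationRecord,
    write_annotations,
)

_LOG = np.log


def _default_true_log_or() -> dict:
    # marginal effect sizes echoing the study: carrier OR 4.51,
    # high-vs-intermediate PRS OR 3.02, low-vs-intermediate 0.57
    return {
        "carrier": _LOG(4.51),
        "prs_per_sd": 0.0,
        "high_vs_int": _LOG(3.02),
        "low_vs_int": _LOG(0.57),
    }


@dataclass
class SimConfig:
    """Generator settings; defaults echo the study's printed marginals."""

    n_individuals: int = 3220
    n_prs_variants: int = 254
    allele_freq_range: tuple = (0.05, 0.5)
    weight_scale: float = 0.1
    carrier_freq_controls: float = 0.006
    true_log_or: dict = field(default_factory=_default_true_log_or)
    case_fraction: float = 0.558  # case-enriched sampling, 1,796 / 3,220
    aggressive_fraction_of_cases: float = 0.37
    metastatic_fraction_of_aggressive: float = 0.25
    interaction_log_or: float = 0.0
    population_prevalence: float = 0.167
    uganda_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.allele_freq_range
        if not (0 < lo <= hi < 0.5 or (0 < lo <= hi <= 0.5)):
            raise ValueError("allele_freq_range must lie in (0, 0.5]")
        for name in ("carrier_freq_controls", "case_fraction", "aggressive_fraction_of_cases",
                     "metastatic_fraction_of_aggressive", "population_prevalence"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.n_prs_variants < 1:
            raise ValueError("n_prs_variants must be >= 1")
        defaults = _default_true_log_or()
        merged = dict(defaults)
        merged.update(self.true_log_or)
        unknown = set(merged) - set(defaults)
        if unknown:
            raise ValueError(f"unknown true_log_or keys: {sorted(unknown)}")
        self.true_log_or = merged


@dataclass
class SimCohort:
    """In-memory bundle of all generated inputs plus ground truth."""

    scoring: pd.DataFrame
    dosages: pd.DataFrame
    phenotypes: list
    carrier_truth: pd.Series
    true_params: dict

    def phenotype_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.phenotypes:
            d = {
                "individual_id": r.individual_id,
                "status": r.status,
                "age": r.age,
                "study": r.study,
                "country": r.country,
                "gleason": r.gleason,
                "stage": r.stage,
                "psa": r.psa,
                "died_of_disease": r.died_of_disease,
                "family_history": r.family_history,
            }
            for k, v in enumerate(r.pcs):
                d[f"pc{k + 1}"] = v
            rows.append(d)
        return pd.DataFrame(rows)

    def write(self, outdir) -> dict:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "scoring": out / "scoring.tsv",
            "dosages": out / "dosages.tsv",
            "phenotypes": out / "phenotypes.csv",
            "carrier_truth": out / "carrier_truth.tsv",
            "true_params": out / "true_params.json",
        }
        write_scoring_file(self.scoring, paths["scoring"])
        write_dosages(self.dosages, paths["dosages"])
        self.phenotype_frame().to_csv(paths["phenotypes"], index=False)
        self.carrier_truth.rename("carrier").to_csv(paths["carrier_truth"], sep="\t",
                                                    index_label="individual_id")
        with open(paths["true_params"], "w") as fh:
            json.dump(self.true_params, fh, indent=2, default=float)
        return {k: str(v) for k, v in paths.items()}


def _solve_intercept_and_carrier_freq(eta0, eta1, cfg) -> tuple[float, float]:
    """Find (alpha, q): intercept giving the target case fraction and carrier
    frequency giving the target carrier frequency among controls.

    eta0/eta1 are the linear predictors without intercept for non-carriers /
    carriers. Expectations are taken over the generated covariates.
    """

    def case_fraction(alpha, q):
        p1 = expit(alpha + eta1)
        p0 = expit(alpha + eta0)
        return q * p1.mean() + (1 - q) * p0.mean()

    def alpha_for(q):
        f = lambda a: case_fraction(a, q) - cfg.case_fraction
        return brentq(f, -30.0, 30.0, xtol=1e-8)

    def control_carrier_freq(q):
        a = alpha_for(q)
        s1 = (1.0 - expit(a + eta1)).mean()
        s0 = (1.0 - expit(a + eta0)).mean()
        return q * s1 / (q * s1 + (1 - q) * s0), a

    target = cfg.carrier_freq_controls
    if target == 0:
        return alpha_for(0.0), 0.0

    def g(q):
        return control_carrier_freq(q)[0] - target

    q = brentq(g, target / 50.0, min(0.9, target * 50.0), xtol=1e-10)
    return alpha_for(q), q


def _weighted_quantile(x: np.ndarray, w: np.ndarray, prob: float) -> float:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws) - 0.5 * ws
    cw /= ws.sum()
    return float(np.interp(prob, cw, xs))


def _control_anchored_truth(scores, z, eta_cov, cfg):
    """Fixed point for the generator's true tertile cut points.

    The analysis anchors tertiles to the CONTROL score distribution, which is
    case-depleted relative to the generated population; defining the true
    categories on population tertiles would make the analysis estimate a
    different (attenuated) contrast. The generator therefore solves for cut
    points that are tertiles of the expected control score distribution,
    jointly with the intercept and carrier frequency.
    """
    t = cfg.true_log_or
    c1, c2 = np.quantile(scores, [1.0 / 3.0, 2.0 / 3.0])
    sd = scores.std() or 1.0
    alpha = q_carrier = None
    for _ in range(12):
        is_low = scores < c1
        is_high = scores >= c2
        eta_cat = t["low_vs_int"] * is_low + t["high_vs_int"] * is_high + t["prs_per_sd"] * z
        inter = cfg.interaction_log_or * (is_high.astype(float) - is_low.astype(float))
        eta0 = eta_cov + eta_cat
        eta1 = eta0 + t["carrier"] + inter
        alpha, q_carrier = _solve_intercept_and_carrier_freq(eta0, eta1, cfg)
        # P(control) per individual, marginal over carrier status
        w = (1 - q_carrier) * (1.0 - expit(alpha + eta0)) + q_carrier * (1.0 - expit(alpha + eta1))
        c1n = _weighted_quantile(scores, w, 1.0 / 3.0)
        c2n = _weighted_quantile(scores, w, 2.0 / 3.0)
        moved = max(abs(c1n - c1), abs(c2n - c2))
        c1, c2 = c1n, c2n
        if moved < 1e-4 * sd:
            break
    return c1, c2, alpha, q_carrier


def generate_cohort(cfg: SimConfig) -> SimCohort:
    """Draw a complete synthetic case-control cohort; deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_individuals, cfg.n_prs_variants
    ids = np.array([f"ind{str(i).zfill(6)}" for i in range(n)])

    lo, hi = cfg.allele_freq_range
    freqs = rng.uniform(lo, hi, size=m)
    weights = rng.uniform(0.0, 2.0 * cfg.weight_scale, size=m)
    variant_ids = [f"rsSYN{j:05d}" for j in range(m)]
    alleles = rng.choice(list("ACGT"), size=(m, 2))
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")
    scoring = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chr": rng.integers(1, 23, size=m),
            "pos": np.sort(rng.integers(1, 2_000_000, size=m)),
            "effect_allele": alleles[:, 0],
            "other_allele": alleles[:, 1],
            "weight": weights,
        }
    )
    dosages = rng.binomial(2, freqs, size=(n, m)).astype(float)
    dose_df = pd.DataFrame(dosages, index=pd.Index(ids, name="individual_id"), columns=variant_ids)

    scores = dosages @ weights
    z = (scores - scores.mean()) / scores.std()

    # nuisance covariates with small true effects
    uganda = rng.random(n) < cfg.uganda_fraction
    study = np.where(uganda, "UGPCS", rng.choice(["MEC", "LAC"], size=n, p=[0.7, 0.3]))
    country = np.where(uganda, "Uganda", "US")
    age = np.clip(np.round(rng.normal(66, 8, size=n)), 40, 90).astype(int)
    pcs = rng.normal(0.0, 1.0, size=(n, 10))
    study_eff = {"MEC": 0.0, "LAC": 0.05, "UGPCS": 0.1}
    pc_eff = np.full(10, 0.02)
    eta_cov = 0.005 * (age - 66) + np.vectorize(study_eff.get)(study) + pcs @ pc_eff

    t = cfg.true_log_or
    q1, q2, alpha, q_carrier = _control_anchored_truth(scores, z, eta_cov, cfg)
    is_low = scores < q1
    is_high = scores >= q2
    eta_cat = t["low_vs_int"] * is_low + t["high_vs_int"] * is_high + t["prs_per_sd"] * z
    inter = cfg.interaction_log_or * (is_high.astype(float) - is_low.astype(float))
    eta0 = eta_cov + eta_cat
    eta1 = eta0 + t["carrier"] + inter
    carrier = rng.random(n) < q_carrier
    p_case = expit(alpha + np.where(carrier, eta1, eta0))
    case = rng.random(n) < p_case

    aggressive = case & (rng.random(n) < cfg.aggressive_fraction_of_cases)
    metastatic = aggressive & (rng.random(n) < cfg.metastatic_fraction_of_aggressive)
    died = aggressive & (rng.random(n) < 0.10)

    # pre-draw clinical fields in bulk, then pick per phenotype class
    g_low = rng.integers(5, 8, size=n)
    g_high = rng.integers(8, 11, size=n)
    u = rng.random((n, 4))
    fh = rng.random(n) < 0.15
    phenos = []
    for i in range(n):
        gleason = stage = psa = None
        if case[i]:
            if uganda[i]:
                if metastatic[i]:
                    gleason, psa = 9, 101.0 + 399.0 * u[i, 0]
                elif aggressive[i]:
                    gleason, psa = int(g_high[i]), 51.0 + 49.0 * u[i, 1]
                else:
                    gleason, psa = int(g_low[i]), 1.0 + 49.0 * u[i, 2]
            else:
                if metastatic[i]:
                    gleason, stage, psa = 9, "metastatic", 20.0 + 180.0 * u[i, 0]
                elif aggressive[i]:
                    gleason, stage, psa = int(g_high[i]), "regional", 5.0 + 40.0 * u[i, 1]
                else:
                    gleason, stage, psa = int(g_low[i]), "localized", 1.0 + 19.0 * u[i, 2]
        else:
            psa = 0.3 + 3.6 * u[i, 3]
        phenos.append(
            PhenotypeRecord(
                individual_id=ids[i],
                status="case" if case[i] else "control",
                age=int(age[i]),
                study=str(study[i]),
                country=str(country[i]),
                gleason=gleason,
                stage=stage,
                psa=float(psa),
                died_of_disease=bool(died[i] and case[i]),
                family_history=bool(fh[i]),
                pcs=tuple(pcs[i]),
            )
        )

    true_params = {
        "alpha": alpha,
        "carrier_base_freq": q_carrier,
        "true_log_or": dict(t),
        "interaction_log_or": cfg.interaction_log_or,
        "tertile_cutpoints": [float(q1), float(q2)],
        "population_prevalence": cfg.population_prevalence,
        "case_fraction_target": cfg.case_fraction,
        "case_fraction_realized": float(case.mean()),
        "carrier_freq_controls_realized": float(carrier[~case].mean()) if (~case).any() else float("nan"),
        "seed": cfg.seed,
    }
    return SimCohort(
        scoring=scoring,
        dosages=dose_df,
        phenotypes=phenos,
        carrier_truth=pd.Series(carrier, index=pd.Index(ids, name="individual_id"), name="carrier"),
        true_params=true_params,
    )


# ---------------------------------------------------------------------------
# Rare-variant annotations covering every classification rule branch

_PLPD_KINDS = ("frameshift_indel", "stop_gained", "splice_donor_acceptor_loss",
               "clinvar_missense", "clinvar_conflict_missense", "insilico_missense",
               "clinvar_exon_boundary")
_BENIGN_KINDS = ("synonymous_damaging", "intronic_clinvar", "utr5", "utr3",
                 "inframe_indel", "near_splice", "common_truncating",
                 "missense_no_evidence", "missense_majority_only", "missense_too_few_calls",
                 "outside_panel_truncating")


def _all_damaging():
    return {tool: "damaging" for tool in INSILICO_TOOLS}


def generate_annotations(gene_panel=DEFAULT_GENE_PANEL, n_plpd: int = 51, n_benign: int = 100,
                         seed: int = 0):
    """Emit annotation records with known ground truth, cycling through record
    kinds so every decision branch of the classifier is exercised.

    Returns ``(records, truth)`` where truth is a DataFrame with columns
    variant_id, plpd_truth, kind.
    """
    if n_plpd < 0 or n_benign < 0:
        raise ValueError("counts must be nonnegative")
    rng = np.random.default_rng(seed)
    genes = sorted(gene_panel)
    records, truth = [], []
    counter = 0

    def rare_maf():
        return float(rng.uniform(0.0002, 0.009))

    def add(kind, plpd):
        nonlocal counter
        vid = f"var{counter:05d}"
        counter += 1
        gene = genes[counter % len(genes)]
        clinvar, insilico, maf = {}, {}, rare_maf()
        if kind in ("frameshift_indel", "stop_gained", "splice_donor_acceptor_loss"):
            consequence = kind
        elif kind == "clinvar_missense":
            consequence = "missense"
            clinvar = {"InVitae": "pathogenic" if counter % 2 else "likely_pathogenic"}
        elif kind == "clinvar_conflict_missense":
            consequence = "missense"
            clinvar = {"Ambry": "likely_pathogenic", "GeneDX": "benign"}
        elif kind == "insilico_missense":
            consequence = "missense"
            insilico = _all_damaging()
        elif kind == "clinvar_exon_boundary":
            consequence = "exon_boundary_codon_change"
            clinvar = {"Emory": "pathogenic"}
        elif kind == "synonymous_damaging":
            consequence = "synonymous"
            insilico = _all_damaging()
            clinvar = {"SCRP": "pathogenic"}
        elif kind == "intronic_clinvar":
            consequence = "intronic"
            clinvar = {"InSiGHT": "pathogenic"}
        elif kind in ("utr5", "utr3", "inframe_indel"):
            consequence = {"utr5": "utr5", "utr3": "utr3", "inframe_indel": "inframe_indel"}[kind]
            insilico = _all_damaging()
        elif kind == "near_splice":
            consequence = "near_splice_outside_2bp"
        elif kind == "common_truncating":
            consequence = "frameshift_indel"
            maf = float(rng.uniform(0.011, 0.2))
        elif kind == "missense_no_evidence":
            consequence = "missense"
            insilico = {tool: "tolerated" for tool in INSILICO_TOOLS}
        elif kind == "missense_majority_only":
            consequence = "missense"
            insilico = dict(zip(INSILICO_TOOLS, ["damaging", "damaging", "damaging", "tolerated", "tolerated"]))
        elif kind == "missense_too_few_calls":
            consequence = "missense"
            insilico = dict(zip(INSILICO_TOOLS, ["damaging", "damaging", "missing", "missing", "missing"]))
        elif kind == "outside_panel_truncating":
            consequence = "stop_gained"
        else:  # pragma: no cover
            raise AssertionError(kind)
        records.append(
            VariantAnnotationRecord(
                variant_id=vid,
                gene="CFTR" if kind == "outside_panel_truncating" else gene,
                consequence=consequence,
                clinvar_assertions=clinvar,
                insilico_calls=insilico,
                maf=maf,
            )
        )
        truth.append({"variant_id": vid, "plpd_truth": plpd, "kind": kind})

    for k in range(n_plpd):
        add(_PLPD_KINDS[k % len(_PLPD_KINDS)], True)
    for k in range(n_benign):
        add(_BENIGN_KINDS[k % len(_BENIGN_KINDS)], False)
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    truth_df = pd.DataFrame([truth[i] for i in order])
    return records, truth_df


def generate_rare_genotypes(carrier_truth: pd.Series, truth: pd.DataFrame, seed: int = 0,
                            benign_het_rate: float = 0.01) -> pd.DataFrame:
    """Allele-count matrix over the annotated rare variants, consistent with
    the carrier ground truth: every true carrier is het at one randomly chosen
    true-P/LP/D variant; benign-variant hets are sprinkled uniformly."""
    rng = np.random.default_rng(seed)
    ids = carrier_truth.index
    variants = list(truth["variant_id"])
    g = pd.DataFrame(0, index=ids, columns=variants, dtype=int)
    plpd_vars = list(truth.loc[truth["plpd_truth"], "variant_id"])
    if carrier_truth.any() and not plpd_vars:
        raise ValueError("carriers present but no true P/LP/D variants to place them on")
    for ind in ids[carrier_truth.to_numpy(dtype=bool)]:
        g.loc[ind, plpd_vars[rng.integers(0, len(plpd_vars))]] = 1
    benign_vars = list(truth.loc[~truth["plpd_truth"], "variant_id"])
    if benign_vars:
        mask = rng.random((len(ids), len(benign_vars))) < benign_het_rate
        g.loc[:, benign_vars] = g.loc[:, benign_vars].to_numpy() + mask.astype(int)
    return g


def generate_rates(shape: str = "exponential-increase", scale: float = 0.001,
                   age_start: int = 40, age_end: int = 85,
                   mortality_scale: float = 0.005) -> RateSchedule:
    """Synthetic registry-style rate schedule on a 1-year grid.

    ``flat`` repeats the anchor hazard at every age; ``exponential-increase``
    doubles the hazard every 10 years from the anchor at ``age_start``.
    """
    if scale <= 0 or mortality_scale <= 0:
        raise ValueError("scale must be positive")
    ages = np.arange(age_start, age_end + 1)
    if shape == "flat":
        inc = np.full(len(ages), scale)
        mort = np.full(len(ages), mortality_scale)
    elif shape == "exponential-increase":
        growth = 2.0 ** ((ages - age_start) / 10.0)
        inc = scale * growth
        mort = mortality_scale * growth
    else:
        raise ValueError(f"unknown shape {shape!r}; choose flat or exponential-increase")
    if np.any(inc >= 1) or np.any(mort >= 1):
        raise ValueError("generated hazard reaches 1; lower the scale or age range")
    return RateSchedule(ages, inc, mort)


def write_rare_inputs(outdir, records, truth: pd.DataFrame, genotypes: pd.DataFrame,
                      rates: RateSchedule | None = None) -> dict:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotations": out / "annotations.tsv",
        "annotation_truth": out / "annotation_truth.tsv",
        "rare_genotypes": out / "rare_genotypes.tsv",
    }
    write_annotations(records, paths["annotations"])
    truth.to_csv(paths["annotation_truth"], sep="\t", index=False)
    genotypes.to_csv(paths["rare_genotypes"], sep="\t", index_label="individual_id")
    if rates is not None:
        paths["rates"] = out / "rates.csv"
        write_rate_schedule(rates, paths["rates"])
    return {k: str(v) for k, v in paths.items()}
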