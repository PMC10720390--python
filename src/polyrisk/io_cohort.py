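"""Readers/writers for the pipeline's file formats, phenotype classification
and cohort assembly.

File formats
------------
* PRS scoring file: TSV with header
  ``variant_id  chr  pos  effect_allele  other_allele  weight``
  (PGS-Catalog-style).
* Rate schedule: CSV with header
  ``age_start, age_end, incidence_per_100k, mortality_per_100k``;
  age bands are inclusive on both ends, rates are per 100,000 person-years
  and are converted to per-person-year hazards by division (registry-rate
  convention; no exponential conversion).
* Phenotypes: CSV with header matching :class:`PhenotypeRecord` fields;
  missing values are empty cells.
* Dosages: TSV, first column ``individual_id``, one column per variant,
  entries in [0, 2]; optionally derived from a VCF (``DS`` or ``GT``).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("polyrisk")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s [%(name)s] %(message)s"))
    logger.addHandler(_h)
logger.setLevel(logging.INFO)

SCORING_COLUMNS = ["variant_id", "chr", "pos", "effect_allele", "other_allele", "weight"]
RATE_COLUMNS = ["age_start", "age_end", "incidence_per_100k", "mortality_per_100k"]

#: the six joint PRS x carrier categories; intermediate-PRS non-carrier is
#: the reference for all odds-ratio contrasts.
PRS_LEVELS = ["low", "intermediate", "high"]
JOINT_CATEGORIES = [
    "low_noncarrier",
    "low_carrier",
    "intermediate_noncarrier",
    "intermediate_carrier",
    "high_noncarrier",
    "high_carrier",
]
REFERENCE_CATEGORY = "intermediate_noncarrier"

PHENOTYPE_CLASSES = ["aggressive", "nonaggressive", "metastatic-aggressive", "unclassified", "control"]


class FormatError(ValueError):
    """A file does not conform to its documented layout."""


@dataclass
class PhenotypeRecord:
    """One study participant's clinical record.

    ``gleason``, ``stage`` and ``psa`` may be ``None`` (missing);
    ``stage`` is one of ``localized``/``regional``/``metastatic``.
    """

    individual_id: str
    status: str  # "case" | "control"
    age: int
    study: str = "study1"
    country: str = "US"
    gleason: int | None = None
    stage: str | None = None
    psa: float | None = None
    died_of_disease: bool = False
    family_history: bool | None = None
    pcs: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.status not in ("case", "control"):
            raise ValueError(f"status must be case/control, got {self.status!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.psa is not None and self.psa < 0:
            raise ValueError("psa must be nonnegative")


@dataclass
class RateSchedule:
    """Age-indexed population incidence and competing-mortality hazards,
    both as per-person-year probabilities on a strictly increasing age grid."""

    ages: np.ndarray
    incidence: np.ndarray
    mortality: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.incidence = np.asarray(self.incidence, dtype=float)
        self.mortality = np.asarray(self.mortality, dtype=float)
        if not (len(self.ages) == len(self.incidence) == len(self.mortality)):
            raise ValueError("ages/incidence/mortality lengths differ")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        for name, arr in (("incidence", self.incidence), ("mortality", self.mortality)):
            if np.any(arr < 0) or np.any(arr >= 1):
                raise ValueError(f"{name} hazards must lie in [0, 1)")

    def restrict(self, age_start: int, age_end: int) -> "RateSchedule":
        m = (self.ages >= age_start) & (self.ages <= age_end)
        if not m.any():
            raise ValueError(f"no ages in [{age_start}, {age_end}]")
        return RateSchedule(self.ages[m], self.incidence[m], self.mortality[m])


@dataclass
class JoinReport:
    n_phenotypes: int
    n_dosage: int
    n_joined: int
    drops: int
    dropped_ids: list


def read_scoring_file(path) -> pd.DataFrame:
    """Read a PRS scoring file (TSV) into a DataFrame in file order.

    Raises :class:`FormatError` naming any missing column, and on duplicate
    variant ids.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    for col in SCORING_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"scoring file missing column {col!r}")
    dup = df["variant_id"][df["variant_id"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate variant id(s) in scoring file: {sorted(set(dup))[:5]}")
    df["weight"] = df["weight"].astype(float)
    if not np.isfinite(df["weight"]).all():
        raise FormatError("non-finite weight in scoring file")
    return df[SCORING_COLUMNS]


def write_scoring_file(df: pd.DataFrame, path) -> None:
    df[SCORING_COLUMNS].to_csv(path, sep="\t", index=False)


def read_rate_schedule(path, expand: bool = True) -> RateSchedule:
    """Read an age-band rate CSV and convert to per-person-year hazards.

    Rates in the file are per 100,000 person-years; division by 1e5 gives the
    annual hazard. With ``expand=True`` each band (inclusive ends) is expanded
    to a 1-year grid with the band's rate repeated; otherwise the schedule is
    indexed by band starts.
    """
    df = pd.read_csv(path)
    for col in RATE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"rate file missing column {col!r}")
    if len(df) == 0:
        raise FormatError("no rate rows")
    if (df[["incidence_per_100k", "mortality_per_100k"]] < 0).any().any():
        raise FormatError("negative rate in rate file")
    df = df.sort_values("age_start").reset_index(drop=True)
    if (df["age_end"] < df["age_start"]).any():
        raise FormatError("age_end < age_start in a rate band")
    ends = df["age_end"].to_numpy()
    starts = df["age_start"].to_numpy()
    if np.any(starts[1:] <= ends[:-1]):
        raise FormatError("overlapping age bands in rate file")
    inc = df["incidence_per_100k"].to_numpy() / 1e5
    mort = df["mortality_per_100k"].to_numpy() / 1e5
    if not expand:
        return RateSchedule(starts, inc, mort)
    ages, li, lm = [], [], []
    for s, e, i, m in zip(starts, ends, inc, mort):
        for a in range(int(s), int(e) + 1):
            ages.append(a)
            li.append(i)
            lm.append(m)
    return RateSchedule(np.array(ages), np.array(li), np.array(lm))


def write_rate_schedule(sched: RateSchedule, path) -> None:
    """Write a schedule back to the band CSV format (1-year bands)."""
    pd.DataFrame(
        {
            "age_start": sched.ages,
            "age_end": sched.ages,
            "incidence_per_100k": sched.incidence * 1e5,
            "mortality_per_100k": sched.mortality * 1e5,
        }
    ).to_csv(path, index=False)


def read_phenotypes(path) -> list[PhenotypeRecord]:
    """Read the phenotype CSV into records; empty cells become missing."""
    df = pd.read_csv(path, dtype={"individual_id": str})
    required = ["individual_id", "status", "age"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"phenotype file missing column {col!r}")
    pc_cols = [c for c in df.columns if c.startswith("pc")]
    recs = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def _get(key, default=None):
            v = d.get(key, default)
            return default if (v is None or (isinstance(v, float) and np.isnan(v))) else v

        recs.append(
            PhenotypeRecord(
                individual_id=str(d["individual_id"]),
                status=str(d["status"]),
                age=int(d["age"]),
                study=str(_get("study", "study1")),
                country=str(_get("country", "US")),
                gleason=(None if _get("gleason") is None else int(_get("gleason"))),
                stage=(None if _get("stage") is None else str(_get("stage"))),
                psa=(None if _get("psa") is None else float(_get("psa"))),
                died_of_disease=bool(_get("died_of_disease", False)),
                family_history=(None if _get("family_history") is None else bool(_get("family_history"))),
                pcs=tuple(float(_get(c, 0.0)) for c in pc_cols),
            )
        )
    return recs


def read_dosages(path) -> pd.DataFrame:
    """Read a dosage TSV into a DataFrame indexed by individual_id."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    if "individual_id" not in df.columns:
        raise FormatError("dosage file missing column 'individual_id'")
    df = df.set_index("individual_id")
    return df.astype(float)


def write_dosages(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="individual_id")


def dosages_from_vcf(path, scoring: pd.DataFrame) -> pd.DataFrame:
    """Extract effect-allele dosages for the scoring variants from a VCF.

    Uses the ``DS`` FORMAT field when present, else allele counts from ``GT``.
    Dosage counts the scoring file's effect allele (1-based VCF coordinates):
    if effect/other are swapped relative to REF/ALT the dosage is flipped to
    ``2 - d``; variants whose allele pair does not match are dropped with a
    warning.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as e:  # pragma: no cover
        raise ImportError("VCF ingestion requires the optional cyvcf2 dependency") from e

    wanted = {}
    for row in scoring.itertuples(index=False):
        wanted[(str(row.chr), int(row.pos))] = (row.variant_id, row.effect_allele.upper(), row.other_allele.upper())
    vcf = VCF(str(path), gts012=True)  # 0/1/2 = alt-allele count, 3 = missing
    samples = list(vcf.samples)
    cols = {}
    for rec in vcf:
        key = (str(rec.CHROM), int(rec.POS))
        if key not in wanted:
            continue
        vid, eff, oth = wanted[key]
        ref, alts = rec.REF.upper(), [a.upper() for a in rec.ALT]
        if len(alts) != 1:
            logger.warning("variant %s is multi-allelic; dropped", vid)
            continue
        alt = alts[0]
        try:
            ds = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
        except (KeyError, TypeError, ValueError):
            gt = np.asarray(rec.gt_types, dtype=float)  # 0=hom ref,1=het,2=hom alt,3=unknown
            ds = np.where(gt == 3, np.nan, np.where(gt == 2, 2.0, gt))
        if (ref, alt) == (oth, eff):
            dose = ds
        elif (ref, alt) == (eff, oth):
            dose = 2.0 - ds
        else:
            logger.warning("variant %s alleles %s/%s mismatch scoring %s/%s; dropped", vid, ref, alt, eff, oth)
            continue
        cols[vid] = dose
    return pd.DataFrame(cols, index=pd.Index(samples, name="individual_id"))


def classify_phenotype(rec: PhenotypeRecord) -> str:
    """Classify one participant's disease phenotype.

    Cases are aggressive when Gleason > 7, stage is regional/metastatic,
    PSA > 50 ng/mL, or the participant died of the disease; the metastatic
    subset is stage = metastatic (US) or PSA > 100 ng/mL (Uganda, where
    staging is unavailable) and always counts as aggressive. Nonaggressive
    requires Gleason <= 7 with localized stage (US) or PSA <= 50 (Uganda).
    Cases matching neither rule (missing fields) are unclassified.
    """
    if rec.status == "control":
        if rec.gleason is not None or rec.stage is not None:
            logger.warning("control %s has case-only clinical fields; ignored", rec.individual_id)
        return "control"
    ugandan = rec.country == "Uganda"
    aggressive = (
        (rec.gleason is not None and rec.gleason > 7)
        or (rec.stage in ("regional", "metastatic"))
        or (rec.psa is not None and rec.psa > 50)
        or rec.died_of_disease
    )
    metastatic = (rec.psa is not None and rec.psa > 100) if ugandan else (rec.stage == "metastatic")
    if metastatic:
        return "metastatic-aggressive"
    if aggressive:
        return "aggressive"
    if ugandan:
        nonaggressive = rec.gleason is not None and rec.gleason <= 7 and rec.psa is not None and rec.psa <= 50
    else:
        nonaggressive = rec.gleason is not None and rec.gleason <= 7 and rec.stage == "localized"
    return "nonaggressive" if nonaggressive else "unclassified"


def joint_category(prs_category: str, carrier: bool) -> str:
    if prs_category not in PRS_LEVELS:
        raise ValueError(f"unknown PRS category {prs_category!r}")
    return f"{prs_category}_{'carrier' if carrier else 'noncarrier'}"


def assemble_cohort(
    phenotypes: list[PhenotypeRecord],
    dosages: pd.DataFrame,
    carriers: pd.Series,
    prs_results: pd.DataFrame,
) -> tuple[pd.DataFrame, JoinReport]:
    """Inner-join phenotypes, carrier flags and PRS results into the
    analysis-ready cohort table.

    Rows missing genotypes, carrier status or a PRS score are dropped and
    counted in the returned :class:`JoinReport`. The resulting frame has one
    row per retained individual with columns: status, outcome (phenotype
    class), age, study, country, carrier, prs_score, prs_category,
    joint_category and pc1..pc10.
    """
    ids = [r.individual_id for r in phenotypes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate individual_id in phenotypes: {dupes[:5]}")
    pheno = pd.DataFrame(
        {
            "individual_id": ids,
            "status": [r.status for r in phenotypes],
            "outcome": [classify_phenotype(r) for r in phenotypes],
            "age": [r.age for r in phenotypes],
            "study": [r.study for r in phenotypes],
            "country": [r.country for r in phenotypes],
        }
    ).set_index("individual_id")
    npc = max((len(r.pcs) for r in phenotypes), default=0)
    for k in range(npc):
        pheno[f"pc{k + 1}"] = [r.pcs[k] if k < len(r.pcs) else 0.0 for r in phenotypes]

    keep = pheno.index
    for other in (dosages.index, carriers.index, prs_results.index):
        keep = keep.intersection(other)
    if len(keep) == 0:
        raise ValueError("no overlapping individual ids across inputs")
    # drop individuals whose PRS score is missing (too much missingness)
    keep = keep[prs_results.loc[keep, "score"].notna()]
    if len(keep) == 0:
        raise ValueError("no individuals with a valid PRS score after joining")

    cohort = pheno.loc[keep].copy()
    cohort["carrier"] = carriers.loc[keep].astype(bool)
    cohort["prs_score"] = prs_results.loc[keep, "score"].astype(float)
    cohort["prs_category"] = prs_results.loc[keep, "category"]
    cohort["joint_category"] = [
        joint_category(c, k) for c, k in zip(cohort["prs_category"], cohort["carrier"])
    ]
    report = JoinReport(
        n_phenotypes=len(pheno),
        n_dosage=len(dosages),
        n_joined=len(cohort),
        drops=len(pheno) - len(cohort),
        dropped_ids=sorted(pheno.index.difference(keep)),
    )
    if report.drops:
        logger.info("assemble_cohort: dropped %d of %d phenotype rows", report.drops, len(pheno))
    return cohort.sort_index(), report
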