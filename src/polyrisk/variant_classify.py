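"""Rare-variant pathogenicity classification and carrier determination.

A variant is called P/LP/D (pathogenic / likely pathogenic / deleterious)
when it is rare (MAF < 1%) and either (a) predicted to truncate or
significantly alter the protein (frameshift indel, stop gain, loss of an
essential splice donor/acceptor), or (b) a missense / exon-boundary codon
change asserted pathogenic or likely pathogenic in ClinVar by at least one
clinical laboratory, or (c) such a missense change called damaging by the
in-silico predictor consensus (PolyPhen2-HumDiv, PolyPhen2-HumVar, LRT,
MutationTaster, SIFT). Intronic, UTR, in-frame indel, synonymous and
near-splice (outside the 2 bp consensus site) variants are excluded
regardless of other evidence.

A carrier holds at least one alternate allele at at least one P/LP/D variant
in the gene panel (default BRCA2, ATM, NBN, PALB2).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_cohort import FormatError, logger

DEFAULT_GENE_PANEL = frozenset({"BRCA2", "ATM", "NBN", "PALB2"})
SECONDARY_GENE_PANEL = frozenset({"BRCA1", "RAD50", "MLH1", "MSH6"})

TRUNCATING = frozenset({"frameshift_indel", "stop_gained", "splice_donor_acceptor_loss"})
MISSENSE_LIKE = frozenset({"missense", "exon_boundary_codon_change"})
EXCLUDED = frozenset(
    {"intronic", "utr5", "utr3", "inframe_indel", "synonymous", "near_splice_outside_2bp"}
)
CONSEQUENCES = TRUNCATING | MISSENSE_LIKE | EXCLUDED

INSILICO_TOOLS = ("PolyPhen2-HumDiv", "PolyPhen2-HumVar", "LRT", "MutationTaster", "SIFT")
INSILICO_RULES = ("all", "majority", "any")

MAF_THRESHOLD = 0.01


@dataclass
class VariantAnnotationRecord:
    """One rare variant's annotation: consequence class, per-laboratory
    ClinVar assertions, five in-silico predictor calls, and MAF."""

    variant_id: str
    gene: str
    consequence: str
    clinvar_assertions: dict  # laboratory -> pathogenic|likely_pathogenic|benign|vus|none
    insilico_calls: dict  # tool -> damaging|tolerated|missing
    maf: float

    def __post_init__(self):
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if not 0 <= self.maf <= 0.5:
            raise ValueError(f"maf must be in [0, 0.5], got {self.maf}")


@dataclass
class ClassificationResult:
    variant_id: str
    plpd: bool
    rule_fired: str

    def __post_init__(self):
        if self.plpd and not self.rule_fired:
            raise ValueError("rule_fired must be set when plpd is true")


def _insilico_consensus(calls: dict, rule: str) -> bool:
    votes = [calls.get(t, "missing") for t in INSILICO_TOOLS]
    damaging = sum(v == "damaging" for v in votes)
    present = sum(v != "missing" for v in votes)
    if rule == "any":
        return damaging >= 1
    if present < 3:  # too few informative predictors for a consensus
        return False
    if rule == "all":
        return damaging == present
    if rule == "majority":
        return damaging * 2 > present
    raise ValueError(f"unknown insilico rule {rule!r}; choose from {INSILICO_RULES}")


def classify_variant(
    rec: VariantAnnotationRecord,
    gene_panel=DEFAULT_GENE_PANEL,
    insilico_rule: str = "all",
) -> ClassificationResult:
    """Apply the P/LP/D decision rules to one annotated variant.

    Exclusion classes dominate every other field; the MAF < 1% filter is
    applied next; truncating consequences are P/LP/D outright; missense-like
    consequences require a ClinVar pathogenic/likely-pathogenic assertion by
    at least one laboratory or an in-silico consensus (``insilico_rule``:
    ``all`` — every non-missing predictor damaging with >= 3 informative;
    ``majority``; ``any``). Genes outside the panel are skipped (not P/LP/D,
    audit label ``outside_panel``).
    """
    vid = rec.variant_id
    if rec.gene not in gene_panel:
        return ClassificationResult(vid, False, "outside_panel")
    if rec.consequence in EXCLUDED:
        return ClassificationResult(vid, False, "excluded_class")
    if rec.maf >= MAF_THRESHOLD:
        return ClassificationResult(vid, False, "common_maf")
    if rec.consequence in TRUNCATING:
        return ClassificationResult(vid, True, "truncating")
    # missense-like: ClinVar assertion wins, then in-silico consensus
    asserted = {lab: a for lab, a in rec.clinvar_assertions.items() if a in ("pathogenic", "likely_pathogenic")}
    if asserted:
        conflict = any(a == "benign" for a in rec.clinvar_assertions.values())
        label = "clinvar" + (";clinvar_conflict" if conflict else "")
        return ClassificationResult(vid, True, label)
    if _insilico_consensus(rec.insilico_calls, insilico_rule):
        return ClassificationResult(vid, True, "insilico")
    return ClassificationResult(vid, False, "no_evidence")


def classify_variants(records, gene_panel=DEFAULT_GENE_PANEL, insilico_rule: str = "all"):
    """Classify a list of annotation records; order-independent by construction."""
    return [classify_variant(r, gene_panel, insilico_rule) for r in records]


def determine_carriers(genotypes: pd.DataFrame, results) -> pd.Series:
    """Flag carriers: >= 1 alternate allele at >= 1 P/LP/D variant.

    ``genotypes`` is individuals x variants with allele counts {0, 1, 2};
    variants classified P/LP/D but absent from the genotype table are ignored
    with a warning. Returns a boolean Series indexed by individual_id.
    """
    plpd_ids = [r.variant_id for r in results if r.plpd]
    present = [v for v in plpd_ids if v in genotypes.columns]
    missing = set(plpd_ids) - set(present)
    if missing:
        logger.warning("determine_carriers: %d P/LP/D variants absent from genotypes", len(missing))
    if not present:
        return pd.Series(False, index=genotypes.index, name="carrier")
    return (genotypes[present] >= 1).any(axis=1).rename("carrier")


# ---------------------------------------------------------------------------
# TSV interface: clinvar and insilico fields as semicolon-delimited pairs

def _parse_pairs(cell: str) -> dict:
    if not isinstance(cell, str) or not cell.strip():
        return {}
    out = {}
    for item in cell.split(";"):
        item = item.strip()
        if not item:
            continue
        if ":" not in item:
            raise FormatError(f"malformed pair {item!r} (expected key:value)")
        k, v = item.split(":", 1)
        out[k.strip()] = v.strip()
    return out


def _format_pairs(d: dict) -> str:
    return ";".join(f"{k}:{v}" for k, v in d.items())


ANNOTATION_COLUMNS = ["variant_id", "gene", "consequence", "clinvar", "insilico", "maf"]


def read_annotations(path) -> list[VariantAnnotationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"annotation file missing column {col!r}")
    return [
        VariantAnnotationRecord(
            variant_id=str(r.variant_id),
            gene=str(r.gene),
            consequence=str(r.consequence),
            clinvar_assertions=_parse_pairs(r.clinvar),
            insilico_calls=_parse_pairs(r.insilico),
            maf=float(r.maf),
        )
        for r in df.itertuples(index=False)
    ]


def write_annotations(records, path) -> None:
    pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in records],
            "gene": [r.gene for r in records],
            "consequence": [r.consequence for r in records],
            "clinvar": [_format_pairs(r.clinvar_assertions) for r in records],
            "insilico": [_format_pairs(r.insilico_calls) for r in records],
            "maf": [r.maf for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def write_classifications(results, path) -> None:
    pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in results],
            "plpd": [r.plpd for r in results],
            "rule_fired": [r.rule_fired for r in results],
        }
    ).to_csv(path, sep="\t", index=False)
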