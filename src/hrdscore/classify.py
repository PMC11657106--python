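"""Biomarker grouping, mutation origin, and cohort assembly.

Groups, in precedence order: ``tBRCAm`` (any deleterious BRCA1/BRCA2
alteration) > ``non-BRCA-HRRm`` (deleterious alteration in the 13-gene HRR
panel) > ``non-HRRm``. A tumor with both a non-HRR alteration and a BRCA or
HRR-panel alteration keeps the higher-precedence group. Tumors with
co-occurring BRCA1+BRCA2 alterations, or alterations in multiple distinct
HRR-panel genes, are flagged ineligible for individual-gene analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .genome_model import GenomeSpec, SegmentProfile
from .scores import ScarScores, ScoringConfig, classify_hrd, gis
from .zygosity import GeneLocus, apply_manual_review, call_zygosity

__all__ = [
    "DEFAULT_HRR_PANEL",
    "VariantCall",
    "TumorRecord",
    "BiomarkerAssignment",
    "ContractError",
    "read_variants",
    "write_variants",
    "assign_group",
    "assign_origin",
    "build_cohort",
]

BRCA_GENES = frozenset({"BRCA1", "BRCA2"})

#: 13-gene homologous-recombination-repair panel used to define non-BRCA HRRm.
DEFAULT_HRR_PANEL = frozenset(
    {
        "ATM", "BARD1", "BRIP1", "CDK12", "CHEK1", "CHEK2", "FANCL",
        "PALB2", "PPP2R2A", "RAD51B", "RAD51C", "RAD51D", "RAD54L",
    }
)

DELETERIOUS = ("deleterious", "suspected-deleterious")
SUBTYPES = (
    "missense", "splice", "loss/rearrangement", "nonsense",
    "frameshift/indel", "amplification",
)
GERMLINE_STATUSES = ("positive", "negative", "not-done")

VARIANT_COLUMNS = [
    "sample", "gene", "classification", "subtype", "homozygous", "germline_test",
]


class ContractError(RuntimeError):
    """Operation called outside its contract (e.g. origin of a non-BRCAm)."""


@dataclass(frozen=True)
class VariantCall:
    sample_id: str
    gene: str
    classification: str  # deleterious | suspected-deleterious | other
    subtype: str = "frameshift/indel"
    homozygous: bool = False
    germline_test: str = "not-done"  # positive | negative | not-done

    def __post_init__(self) -> None:
        if self.germline_test not in GERMLINE_STATUSES:
            raise ValueError(f"bad germline_test {self.germline_test!r}")

    @property
    def is_deleterious(self) -> bool:
        return self.classification in DELETERIOUS


@dataclass
class TumorRecord:
    """One tumor sample: annotations plus its copy-number profile.

    ``scores`` may carry a precomputed :class:`ScarScores` (e.g. when only a
    GIS value is known); otherwise scores are computed from ``profile``.
    A missing profile models assay failure.
    """

    sample_id: str
    variants: list[VariantCall] = field(default_factory=list)
    profile: Optional[SegmentProfile] = None
    scores: Optional[ScarScores] = None
    study: str = ""
    setting: str = ""  # newly-diagnosed | PSROC
    histology: str = ""
    race: str = ""
    primary_location: str = ""

    def deleterious_genes(self) -> set[str]:
        return {v.gene for v in self.variants if v.is_deleterious}

    def resolve_scores(
        self, genome: Optional[GenomeSpec], cfg: ScoringConfig
    ) -> ScarScores:
        if self.scores is not None:
            return self.scores
        if self.profile is None or not self.profile.valid or genome is None:
            return ScarScores.invalid(self.sample_id)
        return gis(self.profile, genome, cfg)


@dataclass(frozen=True)
class BiomarkerAssignment:
    sample_id: str
    group: str  # tBRCAm | non-BRCA-HRRm | non-HRRm
    brca_origin: str  # germline | somatic | undetermined | n/a
    brca_genes: frozenset
    gene_level_eligible: bool
    hrd: str  # positive | negative | unknown


def read_variants(path: str | Path) -> dict[str, list[VariantCall]]:
    """Read a variant TSV (sample, gene, classification, subtype, homozygous,
    germline_test) into per-sample lists."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns {missing}")
    out: dict[str, list[VariantCall]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.sample, []).append(
            VariantCall(
                sample_id=row.sample,
                gene=row.gene,
                classification=row.classification,
                subtype=row.subtype,
                homozygous=str(row.homozygous).lower() in ("1", "true", "yes"),
                germline_test=row.germline_test,
            )
        )
    return out


def write_variants(
    variants: Mapping[str, Sequence[VariantCall]] | Iterable[VariantCall],
    path: str | Path,
) -> None:
    if isinstance(variants, Mapping):
        flat = [v for vs in variants.values() for v in vs]
    else:
        flat = list(variants)
    flat.sort(key=lambda v: (v.sample_id, v.gene, v.subtype))
    lines = ["\t".join(VARIANT_COLUMNS)]
    for v in flat:
        lines.append(
            f"{v.sample_id}\t{v.gene}\t{v.classification}\t{v.subtype}"
            f"\t{str(v.homozygous).lower()}\t{v.germline_test}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def assign_origin(record: TumorRecord) -> str:
    """Origin of a tumor BRCA mutation.

    germline      germline test positive
    somatic       tumor-positive with a negative germline test
    undetermined  no germline test performed
    """
    brca_variants = [
        v for v in record.variants if v.is_deleterious and v.gene in BRCA_GENES
    ]
    if not brca_variants:
        raise ContractError(
            f"{record.sample_id}: assign_origin requires a tumor BRCA mutation"
        )
    statuses = {v.germline_test for v in brca_variants}
    if "positive" in statuses:
        return "germline"
    if "negative" in statuses:
        return "somatic"
    return "undetermined"


def assign_group(
    record: TumorRecord,
    hrr_panel: frozenset | set = DEFAULT_HRR_PANEL,
    genome: Optional[GenomeSpec] = None,
    cfg: ScoringConfig = ScoringConfig(),
) -> BiomarkerAssignment:
    """Assign biomarker group, BRCA origin, gene-level eligibility, and HRD
    status. Only deleterious / suspected-deleterious variants are considered.
    """
    genes = record.deleterious_genes()
    brca_hit = frozenset(genes & BRCA_GENES)
    hrr_hit = genes & set(hrr_panel) - BRCA_GENES

    if brca_hit:
        group = "tBRCAm"
    elif hrr_hit:
        group = "non-BRCA-HRRm"
    else:
        group = "non-HRRm"

    eligible = not (len(brca_hit) == 2 or len(hrr_hit) >= 2)
    origin = assign_origin(record) if group == "tBRCAm" else "n/a"
    scores = record.resolve_scores(genome, cfg)
    hrd = classify_hrd(scores, tbrcam=bool(brca_hit), cfg=cfg)
    return BiomarkerAssignment(
        sample_id=record.sample_id,
        group=group,
        brca_origin=origin,
        brca_genes=brca_hit,
        gene_level_eligible=eligible,
        hrd=hrd,
    )


def build_cohort(
    records: Sequence[TumorRecord],
    cfg: ScoringConfig = ScoringConfig(),
    hrr_panel: frozenset | set = DEFAULT_HRR_PANEL,
    loci: Optional[Mapping[str, GeneLocus]] = None,
    genome: Optional[GenomeSpec] = None,
    manual_review: bool = True,
) -> pd.DataFrame:
    """One row per sample with scores, HRD status, biomarker group, origin,
    and per-mutated-gene zygosity calls. Deterministic given its inputs."""
    ids = [r.sample_id for r in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")

    rows = []
    for rec in records:
        assignment = assign_group(rec, hrr_panel, genome, cfg)
        scores = rec.resolve_scores(genome, cfg)
        zyg_parts = []
        if loci:
            profile = rec.profile or SegmentProfile(rec.sample_id, [], valid=False)
            for gene in sorted(rec.deleterious_genes()):
                if gene not in loci:
                    continue
                call = call_zygosity(profile, loci[gene], rec.variants)
                if manual_review:
                    call = apply_manual_review(
                        call, rec.variants, profile, loci[gene]
                    )
                zyg_parts.append(f"{gene}:{call.status}")
        subtypes = sorted(
            {v.subtype for v in rec.variants if v.is_deleterious}
        )
        rows.append(
            {
                "sample_id": rec.sample_id,
                "study": rec.study,
                "setting": rec.setting,
                "histology": rec.histology,
                "race": rec.race,
                "location": rec.primary_location,
                "group": assignment.group,
                "brca_genes": ",".join(sorted(assignment.brca_genes)),
                "brca_origin": assignment.brca_origin,
                "gene_level_eligible": assignment.gene_level_eligible,
                "subtype": ",".join(subtypes),
                "loh": scores.loh,
                "tai": scores.tai,
                "lst": scores.lst,
                "gis": scores.gis,
                "valid": scores.valid,
                "hrd": assignment.hrd,
                "zygosity": ";".join(zyg_parts),
            }
        )
    columns = [
        "sample_id", "study", "setting", "histology", "race", "location",
        "group", "brca_genes", "brca_origin", "gene_level_eligible",
        "subtype", "loh", "tai", "lst", "gis", "valid", "hrd", "zygosity",
    ]
    return pd.DataFrame(rows, columns=columns)
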