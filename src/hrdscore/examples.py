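"""Worked-example cohorts used by the test suite and the acceptance report.

Each builder encodes the marginal counts of a large published pooled
ovarian-cancer trial cohort as explicit per-sample records, so the
classifier / zygosity caller / summarizer can be exercised end to end and
checked against the printed percentages. The counts are inputs, not
outputs: every reported number below is recomputed by running the pipeline
over the records.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import TumorRecord, VariantCall
from .genome_model import GenomeSpec, Segment, SegmentProfile, load_genome
from .scores import ScarScores
from .zygosity import GeneLocus

__all__ = [
    "brca_prevalence_cohort",
    "brca_zygosity_fixture",
    "hrr_hrd_cohort",
    "four_trial_cohort",
    "brca_origin_cohort",
]


def _record(i: int, genes: list[str], prefix: str, **kwargs) -> TumorRecord:
    sid = f"{prefix}{i:05d}"
    variants = [
        VariantCall(sample_id=sid, gene=g, classification="deleterious",
                    **kwargs)
        for g in genes
    ]
    return TumorRecord(sample_id=sid, variants=variants)


def brca_prevalence_cohort() -> list[TumorRecord]:
    """2147 tumors: 692 BRCA1-only, 323 BRCA2-only, 6 with both, and 1126
    without a BRCA alteration (carrying a TP53 alteration instead)."""
    records = []
    i = 0
    for count, genes in (
        (692, ["BRCA1"]),
        (323, ["BRCA2"]),
        (6, ["BRCA1", "BRCA2"]),
        (1126, ["TP53"]),
    ):
        for _ in range(count):
            records.append(_record(i, genes, "P"))
            i += 1
    return records


@dataclass
class ZygosityFixture:
    profiles: list[SegmentProfile]
    variants: dict[str, list[VariantCall]]
    locus: GeneLocus
    genome: GenomeSpec


def brca_zygosity_fixture() -> ZygosityFixture:
    """838 evaluable BRCA-mutated tumors: 815 with the BRCA locus wholly
    inside minor-copy-zero segments, 23 wholly in balanced 2-copy state."""
    genome = load_genome("toy")
    locus = GeneLocus("BRCA1", "chrA", 30_000_000, 30_100_000)
    profiles, variants = [], {}
    for i in range(838):
        sid = f"Z{i:05d}"
        if i < 815:
            segs = [
                Segment("chrA", 0, 20_000_000, 1, 1),
                Segment("chrA", 20_000_000, 40_000_000, 1, 0),
                Segment("chrA", 40_000_000, 200_000_000, 1, 1),
            ]
        else:
            segs = [Segment("chrA", 0, 200_000_000, 1, 1)]
        profiles.append(SegmentProfile(sample_id=sid, segments=segs))
        variants[sid] = [
            VariantCall(sample_id=sid, gene="BRCA1",
                        classification="deleterious")
        ]
    return ZygosityFixture(profiles, variants, locus, genome)


def _scored(i: int, genes: list[str], gis_value, prefix: str) -> TumorRecord:
    rec = _record(i, genes, prefix)
    if gis_value is None:
        rec.scores = ScarScores.invalid(rec.sample_id)
    else:
        rec.scores = ScarScores(
            sample_id=rec.sample_id, loh=gis_value, tai=0, lst=0,
            gis=gis_value, valid=True, raw_sum=gis_value,
        )
    return rec


def hrr_hrd_cohort() -> list[TumorRecord]:
    """121 tumors with a single HRR-panel alteration and no BRCA alteration:
    55 with GIS at/above the cutoff, 52 below, 14 with assay failure."""
    records = []
    for i in range(121):
        gis_value = 60 if i < 55 else (20 if i < 107 else None)
        records.append(_scored(i, ["RAD51C"], gis_value, "H"))
    return records


def four_trial_cohort() -> list[TumorRecord]:
    """1788 tumors mimicking a four-trial genomic cohort: 121 with a single
    qualifying HRR-panel alteration (55 of them scoring at/above the
    cutoff), enough additional non-BRCA tumors at/above the cutoff to bring
    the non-BRCA HRD-positive total to 319, a BRCA-mutated block, and the
    remainder below the cutoff or failed."""
    records = []
    i = 0
    # 121 non-BRCA HRRm: 55 high, 52 low, 14 failed
    for k in range(121):
        gis_value = 60 if k < 55 else (20 if k < 107 else None)
        records.append(_scored(i, ["CDK12"], gis_value, "F"))
        i += 1
    # 264 non-HRRm at/above cutoff -> 55 + 264 = 319 HRD-positive non-BRCA
    for _ in range(264):
        records.append(_scored(i, ["TP53"], 50, "F"))
        i += 1
    # 500 BRCA-mutated tumors (HRD-positive by mutation, GIS immaterial)
    for _ in range(500):
        records.append(_scored(i, ["BRCA1"], 65, "F"))
        i += 1
    # remaining 903 non-HRRm below the cutoff
    while i < 1788:
        records.append(_scored(i, ["TP53"], 20, "F"))
        i += 1
    return records


def brca_origin_cohort() -> list[TumorRecord]:
    """857 BRCA-mutated tumors with a valid GIS: germline test positive for
    693, negative for 113, not performed for 51."""
    records = []
    i = 0
    for count, status in ((693, "positive"), (113, "negative"), (51, "not-done")):
        for _ in range(count):
            rec = _record(i, ["BRCA1"], "O", germline_test=status)
            rec.scores = ScarScores(
                sample_id=rec.sample_id, loh=50, tai=0, lst=0, gis=50,
                valid=True, raw_sum=50,
            )
            records.append(rec)
            i += 1
    return records
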