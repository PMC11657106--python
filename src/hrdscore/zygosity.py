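"""Gene-level zygosity (biallelic-loss) calling.

A gene is biallelic when both copies are non-functional: the locus sits
wholly inside minor-copy-zero segments, or the variant table carries a
homozygous deleterious call, or two or more distinct deleterious variants
hit the gene. A call is unknown when a minor-copy-zero / non-zero boundary
falls strictly inside the locus, or the copy-number assay failed. Region
calls require minor copy number exactly zero — imbalance alone never
upgrades a call.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import yaml

from .genome_model import GenomeSpec, Segment, SegmentProfile

__all__ = [
    "GeneLocus",
    "ZygosityCall",
    "ZygosityConfigError",
    "load_loci",
    "call_zygosity",
    "apply_manual_review",
]

BIALLELIC = "biallelic"
HETEROZYGOUS = "heterozygous"
UNKNOWN = "unknown"

_UNKNOWN_BASES = {"boundary", "assay-failure"}


class ZygosityConfigError(ValueError):
    """Locus configuration inconsistent with the profile/genome."""


@dataclass(frozen=True)
class GeneLocus:
    """Genomic interval of a gene, 0-based half-open."""

    gene: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene}: empty locus")
        if self.start < 0:
            raise ValueError(f"{self.gene}: negative start")

    def validate(self, genome: GenomeSpec) -> None:
        if self.chromosome not in genome:
            raise ZygosityConfigError(
                f"{self.gene}: unknown chromosome {self.chromosome!r}"
            )
        if self.end > genome[self.chromosome].length:
            raise ZygosityConfigError(
                f"{self.gene}: locus extends past {self.chromosome}"
            )


@dataclass(frozen=True)
class ZygosityCall:
    sample_id: str
    gene: str
    status: str  # biallelic | heterozygous | unknown
    basis: str   # region-LOH | homozygous-variant | multi-variant |
                 # manual-correction | boundary | assay-failure

    def __post_init__(self) -> None:
        if self.status == UNKNOWN and self.basis not in _UNKNOWN_BASES:
            raise ValueError(
                f"unknown status requires basis in {_UNKNOWN_BASES}, got {self.basis}"
            )


def load_loci(path: str | Path, genome: GenomeSpec | None = None) -> dict[str, GeneLocus]:
    """Load gene loci from YAML ({gene, chromosome, start, end} entries) or
    4-column BED (chrom, start, end, gene). The preset name ``"sim"`` loads
    the packaged loci used with simulated cohorts."""
    if path == "sim":
        import importlib.resources

        with importlib.resources.as_file(
            importlib.resources.files("hrdscore.data") / "sim_loci.yaml"
        ) as p:
            return load_loci(p, genome)
    path = Path(path)
    loci: dict[str, GeneLocus] = {}
    if path.suffix.lower() == ".bed":
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, gene = line.split("\t")[:4]
            loci[gene] = GeneLocus(gene, chrom, int(start), int(end))
    else:
        doc = yaml.safe_load(path.read_text())
        for entry in doc["loci"]:
            locus = GeneLocus(
                gene=str(entry["gene"]),
                chromosome=str(entry["chromosome"]),
                start=int(entry["start"]),
                end=int(entry["end"]),
            )
            loci[locus.gene] = locus
    if genome is not None:
        for locus in loci.values():
            locus.validate(genome)
    return loci


def _deleterious(variants: Sequence, gene: str) -> list:
    return [
        v
        for v in variants
        if v.gene == gene
        and v.classification in ("deleterious", "suspected-deleterious")
    ]


def _overlapping(profile: SegmentProfile, locus: GeneLocus) -> list[Segment]:
    return [
        s
        for s in profile.segments
        if s.chromosome == locus.chromosome
        and s.start < locus.end
        and s.end > locus.start
    ]


def call_zygosity(
    profile: SegmentProfile, locus: GeneLocus, variants: Sequence
) -> ZygosityCall:
    """Initial zygosity call for one gene in one sample.

    ``variants`` is the sample's variant list (any genes); only deleterious /
    suspected-deleterious calls in ``locus.gene`` are considered.
    """
    dels = _deleterious(variants, locus.gene)
    sample = profile.sample_id

    # Variant-based biallelic evidence stands even without copy-number data.
    if any(getattr(v, "homozygous", False) for v in dels):
        return ZygosityCall(sample, locus.gene, BIALLELIC, "homozygous-variant")
    if len(dels) >= 2:
        return ZygosityCall(sample, locus.gene, BIALLELIC, "multi-variant")

    if not profile.valid:
        return ZygosityCall(sample, locus.gene, UNKNOWN, "assay-failure")

    over = _overlapping(profile, locus)
    if not over:
        raise ZygosityConfigError(
            f"{locus.gene}: no segments overlap "
            f"{locus.chromosome}:{locus.start}-{locus.end} in {sample}"
        )
    zero = [s.minor_cn == 0 for s in over]
    if all(zero):
        return ZygosityCall(sample, locus.gene, BIALLELIC, "region-LOH")
    if any(zero):
        return ZygosityCall(sample, locus.gene, UNKNOWN, "boundary")
    return ZygosityCall(sample, locus.gene, HETEROZYGOUS, "region-LOH")


def apply_manual_review(
    call: ZygosityCall,
    variants: Sequence,
    profile: SegmentProfile,
    locus: GeneLocus,
) -> ZygosityCall:
    """Correct an initial call the way manual review would: a deleterious
    variant co-occurring with minor-copy-zero evidence over the locus
    upgrades an unknown/heterozygous call to biallelic. Idempotent."""
    if call.status == BIALLELIC:
        return call
    if not _deleterious(variants, call.gene):
        return call
    if not profile.valid:
        return call
    loh_evidence = any(
        s.minor_cn == 0 for s in _overlapping(profile, locus)
    )
    if loh_evidence:
        return replace(call, status=BIALLELIC, basis="manual-correction")
    return call
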