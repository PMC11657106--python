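"""Genomic-instability component scores (LOH, TAI, LST), the combined GIS,
and the three-way HRD classification.

Score definitions
-----------------
LOH   number of loss-of-heterozygosity regions longer than 15 Mb but shorter
      than the whole chromosome. Runs may cross the centromere.
TAI   number of allelic-imbalance regions that extend to one of the
      subtelomeres, do not cross the centromere, and are longer than 11 Mb.
LST   number of breakpoints between copy-number regions longer than 10 Mb,
      after filtering out regions shorter than 3 Mb; computed per arm.
GIS   min(LOH + TAI + LST, cap), reported on a 0-100 scale.

All "longer than" thresholds are strict (>); the 3 Mb filter removes
regions strictly shorter than 3 Mb. Thresholds live in
:class:`ScoringConfig` so the alternative conventions remain one config
edit away.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import yaml

from .genome_model import (
    GenomeSpec,
    Segment,
    SegmentProfile,
    normalize_profile,
    split_by_arm,
)

__all__ = [
    "ScoringConfig",
    "ScarScores",
    "InvalidProfileError",
    "loh_score",
    "tai_score",
    "lst_score",
    "gis",
    "classify_hrd",
]

MB = 1_000_000


class InvalidProfileError(ValueError):
    """Component score requested for an assay-failed (invalid) profile."""


@dataclass(frozen=True)
class ScoringConfig:
    """Length thresholds and score bounds, in base pairs / score units."""

    loh_min_len: int = 15 * MB
    tai_min_len: int = 11 * MB
    lst_min_flank: int = 10 * MB
    lst_filter_len: int = 3 * MB
    gis_cap: int = 100
    hrd_cutoff: int = 42

    def __post_init__(self) -> None:
        for name in ("loh_min_len", "tai_min_len", "lst_min_flank", "lst_filter_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.hrd_cutoff <= self.gis_cap):
            raise ValueError("hrd_cutoff must lie in [0, gis_cap]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoringConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)


@dataclass(frozen=True)
class ScarScores:
    """Per-sample component counts plus the combined score.

    When ``valid`` is False the assay failed and every field except
    ``sample_id`` is None. ``raw_sum`` keeps the uncapped component sum so
    the cap is auditable.
    """

    sample_id: str
    loh: Optional[int]
    tai: Optional[int]
    lst: Optional[int]
    gis: Optional[int]
    valid: bool
    raw_sum: Optional[int] = None

    @classmethod
    def invalid(cls, sample_id: str) -> "ScarScores":
        return cls(sample_id, None, None, None, None, valid=False)


def _runs(segments: list[Segment], predicate) -> list[list[Segment]]:
    """Maximal runs of contiguous (abutting) segments satisfying predicate."""
    runs: list[list[Segment]] = []
    current: list[Segment] = []
    for seg in sorted(segments, key=lambda s: s.start):
        if predicate(seg) and current and seg.start == current[-1].end:
            current.append(seg)
        elif predicate(seg):
            if current:
                runs.append(current)
            current = [seg]
        else:
            if current:
                runs.append(current)
            current = []
    if current:
        runs.append(current)
    return runs


def loh_score(
    profile: SegmentProfile, genome: GenomeSpec, cfg: ScoringConfig = ScoringConfig()
) -> int:
    """Count LOH regions longer than ``loh_min_len`` but shorter than the
    whole chromosome. A region is a maximal run of contiguous segments with
    minor_cn = 0 and major_cn >= 1; runs may span the centromere."""
    if not profile.valid:
        raise InvalidProfileError(profile.sample_id)
    count = 0
    for chrom, segs in profile.by_chromosome().items():
        length = genome[chrom].length
        for run in _runs(segs, lambda s: s.is_loh):
            run_len = run[-1].end - run[0].start
            whole = run[0].start == 0 and run[-1].end == length
            if run_len > cfg.loh_min_len and not whole:
                count += 1
    return count


def tai_score(
    profile: SegmentProfile, genome: GenomeSpec, cfg: ScoringConfig = ScoringConfig()
) -> int:
    """Count allelic-imbalance regions that reach a subtelomere, do not
    overlap the centromere, and are longer than ``tai_min_len``."""
    if not profile.valid:
        raise InvalidProfileError(profile.sample_id)
    count = 0
    for chrom, segs in profile.by_chromosome().items():
        spec = genome[chrom]
        for run in _runs(segs, lambda s: s.is_ai):
            start, end = run[0].start, run[-1].end
            telomeric = start == 0 or end == spec.length
            crosses_cen = start < spec.cen_end and end > spec.cen_start
            if telomeric and not crosses_cen and end - start > cfg.tai_min_len:
                count += 1
    return count


def _smooth_arm(
    segs: list[Segment], filter_len: int
) -> list[Segment]:
    """Iteratively merge equal-state neighbors and drop segments shorter
    than ``filter_len`` until stable. Merging absorbs the coordinates of
    removed slivers so lengths stay representation-independent."""
    cur = sorted(segs, key=lambda s: s.start)
    while True:
        merged: list[Segment] = []
        for seg in cur:
            if merged and merged[-1].state == seg.state:
                merged[-1] = replace(merged[-1], end=seg.end)
            else:
                merged.append(seg)
        kept = [s for s in merged if s.length >= filter_len]
        if kept == cur:
            return kept
        cur = kept


def lst_score(
    profile: SegmentProfile, genome: GenomeSpec, cfg: ScoringConfig = ScoringConfig()
) -> int:
    """Count large-scale state transitions per chromosome arm: junctions
    between consecutive remaining segments, after short-segment filtering,
    where both flanks are longer than ``lst_min_flank`` and their states
    differ. Arms are independent, so no junction spans the centromere."""
    if not profile.valid:
        raise InvalidProfileError(profile.sample_id)
    count = 0
    for _arm, segs in split_by_arm(profile, genome).items():
        smooth = _smooth_arm(segs, cfg.lst_filter_len)
        for left, right in zip(smooth, smooth[1:]):
            if (
                left.state != right.state
                and left.length > cfg.lst_min_flank
                and right.length > cfg.lst_min_flank
            ):
                count += 1
    return count


def gis(
    profile: SegmentProfile, genome: GenomeSpec, cfg: ScoringConfig = ScoringConfig()
) -> ScarScores:
    """All three components plus the combined score, capped at ``gis_cap``.

    Invalidity propagates through the ``valid`` flag rather than raising.
    """
    if not profile.valid:
        return ScarScores.invalid(profile.sample_id)
    prof = normalize_profile(profile) if profile.segments else profile
    loh = loh_score(prof, genome, cfg)
    tai = tai_score(prof, genome, cfg)
    lst = lst_score(prof, genome, cfg)
    raw = loh + tai + lst
    return ScarScores(
        sample_id=profile.sample_id,
        loh=loh,
        tai=tai,
        lst=lst,
        gis=min(raw, cfg.gis_cap),
        valid=True,
        raw_sum=raw,
    )


def classify_hrd(
    scores: ScarScores, tbrcam: bool, cfg: ScoringConfig = ScoringConfig()
) -> str:
    """Three-way HRD status.

    positive  tumor BRCA mutation present, or a valid GIS at/above the cutoff
    negative  no tumor BRCA mutation and a valid GIS below the cutoff
    unknown   no tumor BRCA mutation and no valid GIS (assay failure)
    """
    if tbrcam:
        return "positive"
    if scores.valid:
        return "positive" if scores.gis >= cfg.hrd_cutoff else "negative"
    return "unknown"
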