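"""Genome layout, allele-specific copy-number segments, and segment algebra.

Coordinates are 0-based half-open ``[start, end)`` throughout, so
``length == end - start``. Copy-number states are unphased and stored as an
ordered pair ``(major_cn, minor_cn)`` with ``minor_cn <= major_cn``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ChromosomeSpec",
    "GenomeSpec",
    "Segment",
    "SegmentProfile",
    "SegParseError",
    "load_genome",
    "read_seg",
    "write_seg",
    "normalize_profile",
    "split_by_arm",
]

SEG_COLUMNS = ["sample", "chrom", "start", "end", "major_cn", "minor_cn"]


class SegParseError(ValueError):
    """Malformed SEG input; carries the 1-based line number of the offender."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome: total length and the centromere interval.

    The p arm is ``[0, cen_start)``, the q arm ``[cen_end, length)``.
    """

    name: str
    length: int
    cen_start: int
    cen_end: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: length must be positive")
        if not (0 < self.cen_start < self.cen_end < self.length):
            raise ValueError(
                f"{self.name}: centromere [{self.cen_start}, {self.cen_end}) "
                f"must lie strictly inside [0, {self.length})"
            )


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered collection of chromosomes defining the coordinate system."""

    chromosomes: tuple[ChromosomeSpec, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("chromosome names must be unique")
        object.__setattr__(self, "_by_name", {c.name: c for c in self.chromosomes})

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> ChromosomeSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]


@dataclass(frozen=True)
class Segment:
    """A constant allele-specific copy-number state over ``[start, end)``."""

    chromosome: str
    start: int
    end: int
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty segment [{self.start}, {self.end})")
        if self.start < 0:
            raise ValueError("negative start")
        if self.major_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be >= 0")
        if self.minor_cn > self.major_cn:
            raise ValueError(
                f"minor_cn {self.minor_cn} > major_cn {self.major_cn}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def state(self) -> tuple[int, int]:
        return (self.major_cn, self.minor_cn)

    @property
    def is_loh(self) -> bool:
        """One parental allele entirely absent, the other retained."""
        return self.minor_cn == 0 and self.major_cn >= 1

    @property
    def is_ai(self) -> bool:
        """Allelic imbalance: unequal copies of the two parental alleles."""
        return self.major_cn != self.minor_cn


@dataclass
class SegmentProfile:
    """One tumor's segment landscape. ``valid=False`` models assay failure.

    Invariants (enforced by :meth:`validate`): per chromosome the segments
    are sorted and non-overlapping, and when the profile is valid they tile
    each represented chromosome completely.
    """

    sample_id: str
    segments: list[Segment] = field(default_factory=list)
    valid: bool = True

    def by_chromosome(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for seg in self.segments:
            out.setdefault(seg.chromosome, []).append(seg)
        return out

    def validate(self, genome: GenomeSpec) -> None:
        for chrom, segs in self.by_chromosome().items():
            if chrom not in genome:
                raise ValueError(
                    f"{self.sample_id}: unknown chromosome {chrom!r}"
                )
            length = genome[chrom].length
            segs = sorted(segs, key=lambda s: s.start)
            for prev, cur in zip(segs, segs[1:]):
                if cur.start < prev.end:
                    raise ValueError(
                        f"{self.sample_id}/{chrom}: segments overlap at {cur.start}"
                    )
                if self.valid and cur.start > prev.end:
                    raise ValueError(
                        f"{self.sample_id}/{chrom}: gap at [{prev.end}, {cur.start})"
                    )
            if segs[-1].end > length:
                raise ValueError(
                    f"{self.sample_id}/{chrom}: segment ends at {segs[-1].end} "
                    f"beyond chromosome length {length}"
                )
            if self.valid and (segs[0].start != 0 or segs[-1].end != length):
                raise ValueError(
                    f"{self.sample_id}/{chrom}: valid profile must tile "
                    f"[0, {length})"
                )


def load_genome(source: str | Path) -> GenomeSpec:
    """Load a genome spec from a YAML/JSON file or a packaged preset.

    Presets: ``"toy"`` (3-chromosome test genome) and ``"hg19"``
    (22-autosome hg19-like spec).
    """
    presets = {"toy": "toy_genome.yaml", "hg19": "hg19_autosomes.yaml"}
    if isinstance(source, str) and source in presets:
        ref = importlib.resources.files("hrdscore.data") / presets[source]
        text = ref.read_text()
    else:
        text = Path(source).read_text()
    doc = yaml.safe_load(text)
    chroms = tuple(
        ChromosomeSpec(
            name=str(c["name"]),
            length=int(c["length"]),
            cen_start=int(c["cen_start"]),
            cen_end=int(c["cen_end"]),
        )
        for c in doc["chromosomes"]
    )
    return GenomeSpec(chromosomes=chroms)


def read_seg(path: str | Path, genome: GenomeSpec) -> dict[str, SegmentProfile]:
    """Read a SEG-like TSV into per-sample profiles, validating as we go.

    Expected header: ``sample  chrom  start  end  major_cn  minor_cn``.
    Coordinates are 0-based half-open. Raises :class:`SegParseError` naming
    the offending line for any malformed row, overlap, gap, unknown
    chromosome, or minor > major.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise SegParseError(1, "empty file")
    header = lines[0].rstrip("\n").split("\t")
    if header != SEG_COLUMNS:
        raise SegParseError(1, f"expected header {SEG_COLUMNS}, got {header}")

    rows: dict[str, list[tuple[int, Segment]]] = {}
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != len(SEG_COLUMNS):
            raise SegParseError(lineno, f"expected {len(SEG_COLUMNS)} columns")
        sample, chrom = parts[0], parts[1]
        try:
            start, end = int(parts[2]), int(parts[3])
            major, minor = int(parts[4]), int(parts[5])
        except ValueError:
            raise SegParseError(lineno, f"non-integer field in {parts[2:]}") from None
        if chrom not in genome:
            raise SegParseError(lineno, f"unknown chromosome {chrom!r}")
        try:
            seg = Segment(chrom, start, end, major, minor)
        except ValueError as exc:
            raise SegParseError(lineno, str(exc)) from None
        if seg.end > genome[chrom].length:
            raise SegParseError(
                lineno, f"end {seg.end} beyond {chrom} length {genome[chrom].length}"
            )
        rows.setdefault(sample, []).append((lineno, seg))

    profiles: dict[str, SegmentProfile] = {}
    for sample, tagged in rows.items():
        per_chrom: dict[str, list[tuple[int, Segment]]] = {}
        for lineno, seg in tagged:
            per_chrom.setdefault(seg.chromosome, []).append((lineno, seg))
        ordered: list[Segment] = []
        for chrom in genome.names:
            if chrom not in per_chrom:
                continue
            segs = sorted(per_chrom[chrom], key=lambda t: t[1].start)
            for (_, prev), (lineno, cur) in zip(segs, segs[1:]):
                if cur.start < prev.end:
                    raise SegParseError(
                        lineno, f"{sample}/{chrom}: overlaps previous segment"
                    )
                if cur.start > prev.end:
                    raise SegParseError(
                        lineno,
                        f"{sample}/{chrom}: gap [{prev.end}, {cur.start}) "
                        "before this segment",
                    )
            first_line, first = segs[0]
            last_line, last = segs[-1]
            if first.start != 0:
                raise SegParseError(
                    first_line, f"{sample}/{chrom}: tiling must start at 0"
                )
            if last.end != genome[chrom].length:
                raise SegParseError(
                    last_line,
                    f"{sample}/{chrom}: tiling must end at chromosome length "
                    f"{genome[chrom].length}",
                )
            ordered.extend(seg for _, seg in segs)
        profiles[sample] = SegmentProfile(sample_id=sample, segments=ordered)
    return profiles


def write_seg(
    profiles: Mapping[str, SegmentProfile] | Iterable[SegmentProfile],
    path: str | Path,
    genome: GenomeSpec | None = None,
) -> None:
    """Write profiles to canonical SEG TSV (samples sorted, genome chromosome
    order when a genome is given, starts ascending). Invalid profiles are
    skipped — assay failures carry no segment data."""
    if isinstance(profiles, Mapping):
        items = list(profiles.values())
    else:
        items = list(profiles)
    chrom_rank = (
        {name: i for i, name in enumerate(genome.names)} if genome else None
    )
    out = ["\t".join(SEG_COLUMNS)]
    for prof in sorted(items, key=lambda p: p.sample_id):
        if not prof.valid:
            continue
        segs = prof.segments
        if chrom_rank is not None:
            segs = sorted(
                segs, key=lambda s: (chrom_rank.get(s.chromosome, 1_000), s.start)
            )
        for s in segs:
            out.append(
                f"{prof.sample_id}\t{s.chromosome}\t{s.start}\t{s.end}"
                f"\t{s.major_cn}\t{s.minor_cn}"
            )
    Path(path).write_text("\n".join(out) + "\n")


def normalize_profile(profile: SegmentProfile) -> SegmentProfile:
    """Merge adjacent segments with identical (major, minor) state.

    Idempotent; the output tiles exactly the same intervals.
    """
    merged: list[Segment] = []
    for chrom, segs in profile.by_chromosome().items():
        segs = sorted(segs, key=lambda s: s.start)
        acc = segs[0]
        for cur in segs[1:]:
            if cur.start == acc.end and cur.state == acc.state:
                acc = replace(acc, end=cur.end)
            else:
                merged.append(acc)
                acc = cur
        merged.append(acc)
    return SegmentProfile(
        sample_id=profile.sample_id, segments=merged, valid=profile.valid
    )


def split_by_arm(
    profile: SegmentProfile, genome: GenomeSpec
) -> dict[tuple[str, str], list[Segment]]:
    """Clip segments at the centromere into per-arm lists.

    Returns ``{(chromosome, "p" | "q"): [segments]}``. Segments wholly inside
    the centromere are dropped; no output segment crosses a centromere
    boundary.
    """
    arms: dict[tuple[str, str], list[Segment]] = {}
    for chrom, segs in profile.by_chromosome().items():
        spec = genome[chrom]
        for seg in sorted(segs, key=lambda s: s.start):
            p_end = min(seg.end, spec.cen_start)
            if seg.start < p_end:
                arms.setdefault((chrom, "p"), []).append(
                    replace(seg, start=seg.start, end=p_end)
                )
            q_start = max(seg.start, spec.cen_end)
            if q_start < seg.end:
                arms.setdefault((chrom, "q"), []).append(
                    replace(seg, start=q_start, end=seg.end)
                )
    return arms
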