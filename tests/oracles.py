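"""Independent brute-force score oracles and random profile generators.

The oracles deliberately avoid the package's run/arm machinery: they
enumerate candidate regions exhaustively (O(n^2) maximality checks) over
plain tuples, so agreement with the package is a two-route check.
"""

from __future__ import annotations

import numpy as np

from hrdscore.genome_model import GenomeSpec, Segment, SegmentProfile

MB = 1_000_000


# ---------------------------------------------------------------------------
# brute-force enumerators


def _chrom_rows(profile: SegmentProfile, chrom: str):
    rows = [
        (s.start, s.end, s.major_cn, s.minor_cn)
        for s in profile.segments
        if s.chromosome == chrom
    ]
    return sorted(rows)


def _maximal_regions(rows, good):
    """All maximal intervals of consecutive, abutting rows where good(row)
    holds, found by checking every (i, j) pair exhaustively."""
    n = len(rows)
    regions = []
    for i in range(n):
        for j in range(i, n):
            block = rows[i : j + 1]
            if not all(good(r) for r in block):
                continue
            if any(b[1] != c[0] for b, c in zip(block, block[1:])):
                continue
            left_ext = i > 0 and good(rows[i - 1]) and rows[i - 1][1] == rows[i][0]
            right_ext = (
                j < n - 1 and good(rows[j + 1]) and rows[j][1] == rows[j + 1][0]
            )
            if not left_ext and not right_ext:
                regions.append((rows[i][0], rows[j][1]))
    return regions


def loh_oracle(profile: SegmentProfile, genome: GenomeSpec, min_len=15 * MB) -> int:
    count = 0
    for chrom in {s.chromosome for s in profile.segments}:
        rows = _chrom_rows(profile, chrom)
        length = genome[chrom].length
        for start, end in _maximal_regions(
            rows, lambda r: r[3] == 0 and r[2] >= 1
        ):
            if end - start > min_len and not (start == 0 and end == length):
                count += 1
    return count


def tai_oracle(profile: SegmentProfile, genome: GenomeSpec, min_len=11 * MB) -> int:
    count = 0
    for chrom in {s.chromosome for s in profile.segments}:
        rows = _chrom_rows(profile, chrom)
        spec = genome[chrom]
        for start, end in _maximal_regions(rows, lambda r: r[2] != r[3]):
            reaches_telomere = start == 0 or end == spec.length
            overlaps_cen = start < spec.cen_end and end > spec.cen_start
            if reaches_telomere and not overlaps_cen and end - start > min_len:
                count += 1
    return count


def _filter_merge(regions, filter_len):
    """Recursive batch filter: merge equal-state neighbors, drop every
    region strictly shorter than filter_len, repeat until stable."""
    merged = []
    for start, end, state in regions:
        if merged and merged[-1][2] == state:
            merged[-1] = (merged[-1][0], end, state)
        else:
            merged.append((start, end, state))
    kept = [r for r in merged if r[1] - r[0] >= filter_len]
    if kept == regions:
        return kept
    return _filter_merge(kept, filter_len)


def lst_oracle(
    profile: SegmentProfile,
    genome: GenomeSpec,
    min_flank=10 * MB,
    filter_len=3 * MB,
) -> int:
    count = 0
    for chrom in {s.chromosome for s in profile.segments}:
        spec = genome[chrom]
        rows = _chrom_rows(profile, chrom)
        for lo, hi in ((0, spec.cen_start), (spec.cen_end, spec.length)):
            arm = [
                (max(s, lo), min(e, hi), (maj, mnr))
                for s, e, maj, mnr in rows
                if max(s, lo) < min(e, hi)
            ]
            final = _filter_merge(arm, filter_len)
            for a, b in zip(final, final[1:]):
                if (
                    a[2] != b[2]
                    and a[1] - a[0] > min_flank
                    and b[1] - b[0] > min_flank
                ):
                    count += 1
    return count


# ---------------------------------------------------------------------------
# random profiles


def random_profile(
    rng: np.random.Generator,
    genome: GenomeSpec,
    max_breaks: int = 3,
    sample_id: str = "rand",
) -> SegmentProfile:
    """Random fully tiling profile on the given genome, at most
    (max_breaks + 1) segments per chromosome."""
    segments = []
    for chrom in genome.chromosomes:
        if rng.random() < 0.2 and len(genome.chromosomes) > 1:
            continue  # omitted chromosomes are allowed
        k = int(rng.integers(0, max_breaks + 1))
        cuts = sorted(
            set(int(x) for x in rng.integers(1, chrom.length, size=k))
        )
        bounds = [0, *cuts, chrom.length]
        for lo, hi in zip(bounds, bounds[1:]):
            major = int(rng.integers(0, 4))
            minor = int(rng.integers(0, major + 1))
            segments.append(Segment(chrom.name, lo, hi, major, minor))
    if not segments:  # ensure at least one chromosome
        c = genome.chromosomes[0]
        segments.append(Segment(c.name, 0, c.length, 1, 1))
    return SegmentProfile(sample_id=sample_id, segments=segments)


def split_segments(
    profile: SegmentProfile, rng: np.random.Generator, prob: float = 0.7
) -> SegmentProfile:
    """Equal-state refinement: randomly split segments at interior points.
    Scores must be invariant under this."""
    out = []
    for seg in profile.segments:
        if rng.random() < prob and seg.length > 1:
            cut = int(rng.integers(seg.start + 1, seg.end))
            out.append(Segment(seg.chromosome, seg.start, cut,
                               seg.major_cn, seg.minor_cn))
            out.append(Segment(seg.chromosome, cut, seg.end,
                               seg.major_cn, seg.minor_cn))
        else:
            out.append(seg)
    return SegmentProfile(profile.sample_id, out, valid=profile.valid)
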