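"""Synthetic cohorts with planted, exactly-recoverable ground truth.

Generation is plan-then-construct: per-sample event counts are drawn first
(:class:`SimPlan`), then a deterministic layout engine realizes them as a
segment profile whose LOH/TAI/LST scores equal the planted counts exactly.

Layout strategy (all sizes derived from the scoring thresholds):

* LOH event — an interior minor-copy-zero tract strictly longer than the
  LOH threshold, wrapped in two imbalance *guards* shorter than the LST
  flank minimum. Every junction the structure creates has a sub-threshold
  flank, so it contributes no LST; the guards keep the imbalance run away
  from the subtelomeres, so no TAI.
* TAI event — a chain of guard-length imbalance pieces anchored at a
  telomere, jointly longer than the TAI threshold but individually too
  short to act as LST flanks, and far from the centromere.
* LST event — a run of alternating-state segments (each just above the
  flank minimum) anchored at the centromere edge of an arm, followed by a
  long neutral tract: a chain of k segments yields exactly k junctions and,
  being interior, no TAI and no LOH.

Structures are separated by neutral (1/1) spacers wide enough to survive
the LST short-segment filter, so placements never interact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .classify import DEFAULT_HRR_PANEL, TumorRecord, VariantCall, write_variants
from .genome_model import (
    GenomeSpec,
    Segment,
    SegmentProfile,
    load_genome,
    normalize_profile,
    write_seg,
)
from .scores import MB, ScoringConfig

__all__ = [
    "CountDistribution",
    "MutationSpec",
    "GroupConfig",
    "SimPlan",
    "CapacityError",
    "construct_profile",
    "simulate_cohort",
    "write_cohort",
    "preset",
]

NEUTRAL = (1, 1)


class CapacityError(ValueError):
    """The genome has too little arm space for the planted event counts."""


@dataclass(frozen=True)
class CountDistribution:
    """Discrete count distribution for one scar component.

    Families: ``negbin`` (mean + dispersion r), ``poisson`` (mean),
    ``fixed`` (constant = mean).
    """

    family: str = "negbin"
    mean: float = 5.0
    dispersion: float = 5.0

    def sample(self, rng: np.random.Generator) -> int:
        if self.family == "fixed":
            return int(round(self.mean))
        if self.family == "poisson":
            return int(rng.poisson(self.mean))
        if self.family == "negbin":
            r = self.dispersion
            p = r / (r + self.mean)
            return int(rng.negative_binomial(r, p))
        raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class MutationSpec:
    """How to annotate a group's tumors: gene weights, subtype mix, and the
    germline / homozygous fractions."""

    genes: dict = field(default_factory=dict)  # gene -> weight; empty = none
    subtype_mix: dict = field(
        default_factory=lambda: {"frameshift/indel": 0.5, "nonsense": 0.5}
    )
    germline_fraction: float = 0.0
    homozygous_fraction: float = 0.0


@dataclass(frozen=True)
class GroupConfig:
    name: str
    prevalence: float
    loh: CountDistribution = CountDistribution()
    tai: CountDistribution = CountDistribution()
    lst: CountDistribution = CountDistribution()
    mutation_spec: MutationSpec = MutationSpec()
    biallelic_rate: float = 0.0
    assay_fail_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("prevalence", "biallelic_rate", "assay_fail_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SimPlan:
    """Ground-truth sidecar for one simulated sample."""

    sample_id: str
    group: str
    planted_loh: int
    planted_tai: int
    planted_lst: int
    planted_zygosity: dict = field(default_factory=dict)  # gene -> status
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.planted_loh, self.planted_tai, self.planted_lst) < 0:
            raise ValueError("planted counts must be >= 0")


# ---------------------------------------------------------------------------
# layout engine


@dataclass
class _Arm:
    chrom: str
    arm: str  # "p" | "q"
    start: int
    end: int
    tai: bool = False
    loh: int = 0
    lst: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


class _Layout:
    """Greedy per-arm packer; all sizes in bp, derived from the config."""

    def __init__(self, genome: GenomeSpec, cfg: ScoringConfig,
                 reserved: frozenset):
        self.cfg = cfg
        self.guard = cfg.lst_min_flank - MB
        if self.guard < cfg.lst_filter_len:
            raise ValueError("lst_min_flank too close to lst_filter_len")
        self.sep = max(cfg.lst_filter_len + MB, 4 * MB)
        self.loh_tract = cfg.loh_min_len + 2 * MB
        self.loh_block = self.loh_tract + 2 * self.guard
        n_pieces = int(cfg.tai_min_len // self.guard) + 1
        self.tai_pieces = n_pieces
        self.tai_block = n_pieces * self.guard
        self.lst_seg = cfg.lst_min_flank + MB
        self.lst_trail = cfg.lst_min_flank + 2 * MB
        self.arms = [
            a
            for c in genome.chromosomes
            if c.name not in reserved
            for a in (
                _Arm(c.name, "p", 0, c.cen_start),
                _Arm(c.name, "q", c.cen_end, c.length),
            )
        ]

    def _used(self, arm: _Arm, tai=None, loh=None, lst=None) -> int:
        tai = arm.tai if tai is None else tai
        loh = arm.loh if loh is None else loh
        lst = arm.lst if lst is None else lst
        used = (self.tai_block + self.sep) if tai else self.sep
        used += loh * (self.loh_block + self.sep)
        if lst:
            used += lst * self.lst_seg + self.lst_trail
        return used

    def allocate(self, n_loh: int, n_tai: int, n_lst: int,
                 rng: np.random.Generator) -> None:
        order = list(rng.permutation(len(self.arms)))
        for kind, n in (("tai", n_tai), ("loh", n_loh), ("lst", n_lst)):
            for _ in range(n):
                placed = False
                for idx in order:
                    arm = self.arms[idx]
                    if kind == "tai":
                        if arm.tai:
                            continue
                        ok = self._used(arm, tai=True) <= arm.length
                        if ok:
                            arm.tai = True
                            placed = True
                    elif kind == "loh":
                        if self._used(arm, loh=arm.loh + 1) <= arm.length:
                            arm.loh += 1
                            placed = True
                    else:
                        if self._used(arm, lst=arm.lst + 1) <= arm.length:
                            arm.lst += 1
                            placed = True
                    if placed:
                        break
                if not placed:
                    roomiest = max(
                        self.arms, key=lambda a: a.length - self._used(a)
                    )
                    raise CapacityError(
                        f"no arm can host another {kind} event; roomiest arm "
                        f"{roomiest.chrom}{roomiest.arm} has "
                        f"{roomiest.length - self._used(roomiest)} bp free"
                    )

    def realize(self) -> list[Segment]:
        """Emit structure segments for every arm (neutral gaps added later)."""
        segs: list[Segment] = []
        for arm in self.arms:
            segs.extend(self._realize_arm(arm))
        return segs

    def _realize_arm(self, arm: _Arm) -> list[Segment]:
        # Work in telomere -> centromere order, then map to coordinates.
        out: list[tuple[int, int, int, int]] = []  # (offset, len, major, minor)
        cursor = 0
        if arm.tai:
            for i in range(self.tai_pieces):
                state = (2, 1) if i % 2 == 0 else (3, 1)
                out.append((cursor, self.guard, *state))
                cursor += self.guard
            cursor += self.sep
        else:
            cursor += self.sep
        for _ in range(arm.loh):
            out.append((cursor, self.guard, 2, 1))
            out.append((cursor + self.guard, self.loh_tract, 1, 0))
            out.append((cursor + self.guard + self.loh_tract, self.guard, 2, 1))
            cursor += self.loh_block + self.sep
        if arm.lst:
            chain_start = arm.length - arm.lst * self.lst_seg
            for i in range(arm.lst):
                state = (2, 1) if i % 2 == 0 else (3, 1)
                # order within the chain: nearest the centromere last
                out.append((chain_start + i * self.lst_seg, self.lst_seg, *state))

        segs = []
        for offset, length, major, minor in out:
            if arm.arm == "p":
                # telomere at position 0, centromere at arm.end
                start = offset
            else:
                # telomere at arm.end (chromosome end), centromere at arm.start
                start = arm.end - offset - length
            segs.append(Segment(arm.chrom, start, start + length, major, minor))
        return segs


def construct_profile(
    plan: SimPlan,
    genome: GenomeSpec,
    cfg: ScoringConfig = ScoringConfig(),
    rng_seed: int = 0,
    reserved_chromosomes: Sequence[str] = (),
) -> SegmentProfile:
    """Build a fully tiling profile whose component scores equal the plan's
    planted counts exactly. Deterministic for a given (plan, seed); the seed
    only permutes where events land, never how many there are.

    ``reserved_chromosomes`` stay flat 1/1 (useful to keep gene loci clear
    of planted copy-number structure).
    """
    layout = _Layout(genome, cfg, frozenset(reserved_chromosomes))
    rng = np.random.default_rng(rng_seed)
    layout.allocate(plan.planted_loh, plan.planted_tai, plan.planted_lst, rng)
    structures = layout.realize()

    by_chrom: dict[str, list[Segment]] = {c.name: [] for c in genome.chromosomes}
    for seg in structures:
        by_chrom[seg.chromosome].append(seg)

    segments: list[Segment] = []
    for chrom in genome.names:
        length = genome[chrom].length
        placed = sorted(by_chrom[chrom], key=lambda s: s.start)
        cursor = 0
        for seg in placed:
            if seg.start > cursor:
                segments.append(Segment(chrom, cursor, seg.start, *NEUTRAL))
            segments.append(seg)
            cursor = seg.end
        if cursor < length:
            segments.append(Segment(chrom, cursor, length, *NEUTRAL))
    profile = SegmentProfile(sample_id=plan.sample_id, segments=segments)
    profile.validate(genome)
    return normalize_profile(profile)


# ---------------------------------------------------------------------------
# cohort simulation


def _pick(rng: np.random.Generator, weights: dict):
    keys = sorted(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=w / w.sum()))]


def simulate_cohort(
    groups: Sequence[GroupConfig],
    n: int,
    seed: int,
    genome: Optional[GenomeSpec] = None,
    cfg: ScoringConfig = ScoringConfig(),
    reserved_chromosomes: Sequence[str] = ("chr21", "chr22"),
    max_counts: tuple[int, int, int] = (26, 30, 40),
) -> tuple[list[TumorRecord], list[SimPlan]]:
    """Draw ``n`` samples: multinomial group memberships, per-group event
    counts (clipped to ``max_counts`` so every plan fits the genome), assay
    failures, and variant annotations. Returns records plus the truth
    sidecar. Identical seeds give byte-identical downstream SEG/variant
    output."""
    if n <= 0:
        raise ValueError("cohort size must be positive")
    prev = np.array([g.prevalence for g in groups], dtype=float)
    if not np.isclose(prev.sum(), 1.0):
        raise ValueError(f"group prevalences sum to {prev.sum()}, expected 1")
    if genome is None:
        genome = load_genome("hg19")

    rng = np.random.default_rng(seed)
    records: list[TumorRecord] = []
    plans: list[SimPlan] = []
    for i in range(n):
        grp = groups[int(rng.choice(len(groups), p=prev))]
        counts = [
            min(dist.sample(rng), cap)
            for dist, cap in zip((grp.loh, grp.tai, grp.lst), max_counts)
        ]
        fail = rng.random() < grp.assay_fail_rate
        sample_id = f"S{i:05d}"
        child_seed = int(rng.integers(0, 2**31 - 1))

        variants: list[VariantCall] = []
        planted_zyg: dict[str, str] = {}
        spec = grp.mutation_spec
        if spec.genes:
            gene = _pick(rng, spec.genes)
            biallelic = rng.random() < grp.biallelic_rate
            homozygous = biallelic  # planted biallelic truth rides on the flag
            germline = rng.random() < spec.germline_fraction
            variants.append(
                VariantCall(
                    sample_id=sample_id,
                    gene=gene,
                    classification="deleterious",
                    subtype=_pick(rng, spec.subtype_mix),
                    homozygous=homozygous,
                    germline_test="positive" if germline else "negative",
                )
            )
            planted_zyg[gene] = "biallelic" if biallelic else "heterozygous"

        plan = SimPlan(
            sample_id=sample_id,
            group=grp.name,
            planted_loh=counts[0],
            planted_tai=counts[1],
            planted_lst=counts[2],
            planted_zygosity=planted_zyg,
            seed=child_seed,
        )
        if fail:
            profile = SegmentProfile(sample_id=sample_id, segments=[], valid=False)
        else:
            profile = construct_profile(
                plan, genome, cfg, rng_seed=child_seed,
                reserved_chromosomes=reserved_chromosomes,
            )
        plans.append(plan)
        records.append(
            TumorRecord(sample_id=sample_id, variants=variants, profile=profile)
        )
    return records, plans


def write_cohort(
    records: Sequence[TumorRecord],
    plans: Sequence[SimPlan],
    outdir: str | Path,
    genome: Optional[GenomeSpec] = None,
) -> dict[str, Path]:
    """Emit segments.seg, variants.tsv, and truth.tsv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seg_path = outdir / "segments.seg"
    var_path = outdir / "variants.tsv"
    truth_path = outdir / "truth.tsv"

    write_seg({r.sample_id: r.profile for r in records if r.profile}, seg_path,
              genome=genome)
    write_variants([v for r in records for v in r.variants], var_path)

    lines = ["sample\tgroup\tplanted_loh\tplanted_tai\tplanted_lst\tvalid\tzygosity"]
    valid = {r.sample_id: (r.profile is not None and r.profile.valid)
             for r in records}
    for p in sorted(plans, key=lambda p: p.sample_id):
        zyg = ";".join(f"{g}:{s}" for g, s in sorted(p.planted_zygosity.items()))
        lines.append(
            f"{p.sample_id}\t{p.group}\t{p.planted_loh}\t{p.planted_tai}"
            f"\t{p.planted_lst}\t{str(valid[p.sample_id]).lower()}\t{zyg}"
        )
    truth_path.write_text("\n".join(lines) + "\n")
    return {"seg": seg_path, "variants": var_path, "truth": truth_path}


def preset(name: str) -> list[GroupConfig]:
    """Packaged cohort shapes.

    ``toy``    two clearly separated groups; quick bimodality demos.
    ``study``  three groups whose prevalences and GIS centers/spreads are
               calibrated to a published pooled ovarian-cancer cohort
               (calibration only — the per-component split of the total
               score is an even three-way split, which the source data do
               not constrain).
    """
    if name == "toy":
        return [
            GroupConfig(
                name="low",
                prevalence=0.5,
                loh=CountDistribution("negbin", 4, 8),
                tai=CountDistribution("negbin", 4, 8),
                lst=CountDistribution("negbin", 4, 8),
            ),
            GroupConfig(
                name="high",
                prevalence=0.5,
                loh=CountDistribution("negbin", 20, 20),
                tai=CountDistribution("negbin", 20, 20),
                lst=CountDistribution("negbin", 20, 20),
            ),
        ]
    if name == "study":
        brca = MutationSpec(
            genes={"BRCA1": 0.678, "BRCA2": 0.322},
            germline_fraction=0.81,
        )
        hrr = MutationSpec(
            genes={g: 1.0 for g in sorted(DEFAULT_HRR_PANEL)},
            germline_fraction=0.3,
        )
        other = MutationSpec(
            genes={"TP53": 0.6, "NF1": 0.1, "RB1": 0.05, "PIK3CA": 0.1,
                   "CCNE1": 0.05, "PTEN": 0.1},
            germline_fraction=0.0,
        )
        return [
            GroupConfig(
                name="tBRCAm",
                prevalence=0.476,
                loh=CountDistribution("negbin", 20.7, 15),
                tai=CountDistribution("negbin", 20.7, 15),
                lst=CountDistribution("negbin", 20.7, 15),
                mutation_spec=brca,
                biallelic_rate=0.973,
                assay_fail_rate=0.155,
            ),
            GroupConfig(
                name="non-BRCA-HRRm",
                prevalence=0.056,
                loh=CountDistribution("negbin", 14.0, 2.0),
                tai=CountDistribution("negbin", 14.0, 2.0),
                lst=CountDistribution("negbin", 14.0, 2.0),
                mutation_spec=hrr,
                biallelic_rate=0.9,
                assay_fail_rate=0.116,
            ),
            GroupConfig(
                name="non-HRRm",
                prevalence=0.468,
                loh=CountDistribution("negbin", 10.7, 0.9),
                tai=CountDistribution("negbin", 10.7, 0.9),
                lst=CountDistribution("negbin", 10.7, 0.9),
                mutation_spec=other,
                biallelic_rate=0.5,
                assay_fail_rate=0.136,
            ),
        ]
    raise ValueError(f"unknown preset {name!r}")
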