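"""Domain model for paired diagnosis/relapse somatic variant analysis.

The central objects are per-patient collections of somatic variant calls with
read evidence at two timepoints — initial diagnosis (ID) and relapse (REL) —
plus copy-number segments, whole-chromosome states derived from them, and
patient metadata (age group, time to relapse, TP53 status, fusion flags).

Coordinates are 1-based inclusive throughout (VCF convention). BED-style
input is converted at the reader boundary (see :mod:`clonevo.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import defaultdict

EFFECTS = frozenset({"missense", "nonsense", "frameshift", "splice", "silent", "other"})
NON_SILENT_EFFECTS = EFFECTS - {"silent"}
SEGMENT_STATES = frozenset({"loss_hom", "loss_het", "cnloh", "neutral", "gain"})
WHOLE_CHROM_STATES = frozenset({"loss", "cnloh", "gain", "neutral"})
TIMEPOINTS = ("ID", "REL")

#: segment state -> whole-chromosome state class used when summarizing coverage
_SEGMENT_TO_CHROM_CLASS = {
    "loss_hom": "loss",
    "loss_het": "loss",
    "cnloh": "cnloh",
    "gain": "gain",
}


class ValidationError(ValueError):
    """A record violates a domain invariant (e.g. alt reads exceed depth)."""


class SchemaError(ValueError):
    """An input table does not match the expected schema."""


@dataclass(frozen=True)
class VariantCall:
    """One somatic variant with paired-timepoint read evidence.

    VAFs are derived properties: ``alt/depth`` when depth is positive, else 0.
    An undetected variant at a timepoint is encoded as ``alt == 0`` (the depth
    may still be positive); what counts as "detected" is an analysis decision,
    see :mod:`clonevo.evolution`.
    """

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: str
    alt_id: int
    depth_id: int
    alt_rel: int
    depth_rel: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.effect not in EFFECTS:
            raise ValidationError(f"unknown effect {self.effect!r}")
        for tp, alt, depth in (("ID", self.alt_id, self.depth_id),
                               ("REL", self.alt_rel, self.depth_rel)):
            if alt < 0 or depth < 0:
                raise ValidationError(f"negative read count at {tp}")
            if alt > depth:
                raise ValidationError(
                    f"alt reads exceed depth at {tp}: {alt} > {depth}")

    @property
    def vaf_id(self) -> float:
        return self.alt_id / self.depth_id if self.depth_id > 0 else 0.0

    @property
    def vaf_rel(self) -> float:
        return self.alt_rel / self.depth_rel if self.depth_rel > 0 else 0.0

    @property
    def vid(self) -> str:
        """Stable per-patient variant identifier."""
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def sort_key(self):
        return (self.patient_id, _chrom_sort_key(self.chrom), self.pos,
                self.ref, self.alt)


def _chrom_sort_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


@dataclass(frozen=True)
class CNASegment:
    """A copy-number segment at one timepoint (1-based inclusive)."""

    patient_id: str
    timepoint: str
    chrom: str
    start: int
    end: int
    state: str
    gene_overlaps: tuple = ()

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"timepoint must be ID or REL, got {self.timepoint!r}")
        if self.state not in SEGMENT_STATES:
            raise ValidationError(f"unknown segment state {self.state!r}")
        if self.start > self.end:
            raise ValidationError(
                f"segment start > end: {self.chrom}:{self.start}-{self.end}")
        object.__setattr__(self, "gene_overlaps", tuple(self.gene_overlaps))

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ChromosomeState:
    """Whole-chromosome state at one timepoint after segment summarization."""

    patient_id: str
    timepoint: str
    chrom: str
    whole_chrom_state: str

    def __post_init__(self) -> None:
        if self.whole_chrom_state not in WHOLE_CHROM_STATES:
            raise ValidationError(f"unknown state {self.whole_chrom_state!r}")


@dataclass
class PatientRecord:
    """Metadata plus all molecular observations for one patient."""

    patient_id: str
    age_group: str
    days_to_relapse: float
    tp53_mutated: bool = False
    fusion_flags: frozenset = frozenset()
    variants: list = field(default_factory=list)
    chrom_states: list = field(default_factory=list)
    segments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age_group not in ("pediatric", "adult"):
            raise ValidationError(f"age_group must be pediatric/adult, got {self.age_group!r}")
        if self.days_to_relapse <= 0:
            raise ValidationError("days_to_relapse must be positive")
        self.fusion_flags = frozenset(self.fusion_flags)
        for v in self.variants:
            if v.patient_id != self.patient_id:
                raise ValidationError(
                    f"variant {v.vid} belongs to {v.patient_id}, not {self.patient_id}")


@dataclass
class AnalysisParams:
    """Tunable analysis thresholds.

    vaf_clonal
        VAF at or above which a detected mutation counts as clonal (the
        10% rule used to split clonal from subclonal mutations).
    min_alt_reads
        Minimum alt reads for a mutation to count as detected at a timepoint.
    early_late_cutoff_days
        Days-to-relapse cutoff splitting early from late relapse.
    successor_retention_threshold
        Minimum fraction of diagnostic major-clone mutations retained at
        relapse for the relapse to count as a successor of that clone.
    cluster_link_distance
        Single-linkage merge cutoff in (CCF_ID, CCF_REL) space.
    ancestry_tolerance
        CCF slack when testing whether one cluster dominates another.
    chrom_coverage_fraction
        Fraction of a chromosome a single state class must cover for a
        whole-chromosome call.
    purity
        Tumor purity scalar applied in the CCF transform.
    """

    vaf_clonal: float = 0.10
    min_alt_reads: int = 3
    early_late_cutoff_days: float = 700.0
    successor_retention_threshold: float = 0.75
    cluster_link_distance: float = 0.15
    ancestry_tolerance: float = 0.05
    chrom_coverage_fraction: float = 0.90
    purity: float = 1.0

    def __post_init__(self) -> None:
        for name in ("vaf_clonal", "successor_retention_threshold",
                     "cluster_link_distance", "ancestry_tolerance",
                     "chrom_coverage_fraction", "purity"):
            x = getattr(self, name)
            if not 0.0 < x <= 1.0:
                raise ValidationError(f"{name} must be in (0, 1], got {x}")
        if self.early_late_cutoff_days <= 0:
            raise ValidationError("early_late_cutoff_days must be > 0")
        if self.min_alt_reads < 0:
            raise ValidationError("min_alt_reads must be >= 0")


def _union_coverage(intervals) -> int:
    """Total length covered by a union of 1-based inclusive intervals."""
    covered = 0
    last_end = 0
    for start, end in sorted(intervals):
        start = max(start, last_end + 1)
        if end >= start:
            covered += end - start + 1
            last_end = max(last_end, end)
    return covered


def summarize_chromosomes(segments, chrom_lengths, coverage_fraction: float = 0.90):
    """Summarize segments into one whole-chromosome state per chromosome.

    A chromosome is called ``loss`` / ``cnloh`` / ``gain`` when segments of
    that state class cover at least ``coverage_fraction`` of its length;
    otherwise it is ``neutral``. One state is emitted for every chromosome in
    ``chrom_lengths`` for every (patient, timepoint) pair present in the
    segments. Overlapping segments with contradictory (different non-neutral)
    state classes raise :class:`ValidationError`.
    """
    by_pt = defaultdict(lambda: defaultdict(list))
    for seg in segments:
        if seg.chrom not in chrom_lengths:
            raise SchemaError(f"chromosome {seg.chrom!r} missing from chrom_lengths")
        by_pt[(seg.patient_id, seg.timepoint)][seg.chrom].append(seg)

    out = []
    for (pid, tp) in sorted(by_pt):
        chrom_segs = by_pt[(pid, tp)]
        for chrom in sorted(chrom_lengths, key=_chrom_sort_key):
            segs = [s for s in chrom_segs.get(chrom, ())
                    if s.state != "neutral"]
            _check_contradictions(segs)
            state = "neutral"
            for cls in ("loss", "cnloh", "gain"):
                ivals = [(s.start, s.end) for s in segs
                         if _SEGMENT_TO_CHROM_CLASS[s.state] == cls]
                if not ivals:
                    continue
                if _union_coverage(ivals) / chrom_lengths[chrom] >= coverage_fraction:
                    state = cls
                    break
            out.append(ChromosomeState(pid, tp, chrom, state))
    return out


def _check_contradictions(segs) -> None:
    segs = sorted(segs, key=lambda s: (s.start, s.end))
    for i, a in enumerate(segs):
        for b in segs[i + 1:]:
            if b.start > a.end:
                break
            if _SEGMENT_TO_CHROM_CLASS[a.state] != _SEGMENT_TO_CHROM_CLASS[b.state]:
                raise ValidationError(
                    "contradictory overlapping segments: "
                    f"{a.patient_id} {a.timepoint} {a.chrom}:{a.start}-{a.end} "
                    f"{a.state} overlaps {b.chrom}:{b.start}-{b.end} {b.state}")


def attach_chromosome_states(patients, chrom_lengths,
                             coverage_fraction: float = 0.90) -> None:
    """Compute and attach whole-chromosome states for every patient in place.

    Every patient receives a state for both timepoints and every chromosome
    in ``chrom_lengths`` (all neutral when the patient has no segments).
    """
    for pr in patients:
        states = summarize_chromosomes(pr.segments, chrom_lengths, coverage_fraction)
        covered = {cs.timepoint for cs in states}
        for tp in TIMEPOINTS:
            if tp not in covered:
                states.extend(
                    ChromosomeState(pr.patient_id, tp, chrom, "neutral")
                    for chrom in sorted(chrom_lengths, key=_chrom_sort_key))
        pr.chrom_states = sorted(
            states, key=lambda cs: (cs.timepoint, _chrom_sort_key(cs.chrom)))
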