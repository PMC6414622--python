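"""Mutation and patient-level clonal evolution classification.

Each mutation is assigned one of five evolution categories from its paired
VAFs (stable, ID-only, REL-only, dropped to subclonal, expanded from
subclonal); mutations subclonal at both timepoints are excluded from the
five-category denominator. Each patient's relapse is classified as a
successor of the diagnostic major clone, a precursor-derived relapse (major
clone lost, minor clone maintained), or a novel leukemia sharing no
mutations with diagnosis. Relapse timing is dichotomized at 700 days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .core import AnalysisParams, PatientRecord, VariantCall

#: the five categories of the mutation-evolution bar plot, in display order
CATEGORIES = ("stable", "id_only", "rel_only", "dropped_subclonal",
              "expanded_subclonal")
EXCLUDED_CATEGORY = "excluded_subclonal_only"
EVOLUTION_CLASSES = ("successor", "precursor", "novel")


def detected(v: VariantCall, timepoint: str, params: AnalysisParams) -> bool:
    """A mutation is detected when it has enough alt reads and non-zero VAF."""
    alt = v.alt_id if timepoint == "ID" else v.alt_rel
    vaf = v.vaf_id if timepoint == "ID" else v.vaf_rel
    return alt >= params.min_alt_reads and vaf > 0


def clonal(v: VariantCall, timepoint: str, params: AnalysisParams) -> bool:
    """Detected at or above the clonal VAF threshold (boundary is clonal)."""
    vaf = v.vaf_id if timepoint == "ID" else v.vaf_rel
    return detected(v, timepoint, params) and vaf >= params.vaf_clonal


def subclonal(v: VariantCall, timepoint: str, params: AnalysisParams) -> bool:
    vaf = v.vaf_id if timepoint == "ID" else v.vaf_rel
    return detected(v, timepoint, params) and vaf < params.vaf_clonal


def classify_mutation(v: VariantCall, params: AnalysisParams | None = None) -> str:
    """Assign one evolution category to a mutation from its paired VAFs."""
    p = params or AnalysisParams()
    clonal_id, clonal_rel = clonal(v, "ID", p), clonal(v, "REL", p)
    det_id, det_rel = detected(v, "ID", p), detected(v, "REL", p)
    if clonal_id and clonal_rel:
        return "stable"
    if clonal_id and not det_rel:
        return "id_only"
    if not det_id and clonal_rel:
        return "rel_only"
    if clonal_id and subclonal(v, "REL", p):
        return "dropped_subclonal"
    if subclonal(v, "ID", p) and clonal_rel:
        return "expanded_subclonal"
    return EXCLUDED_CATEGORY


@dataclass
class CategorySummary:
    """Counts and fractions over the five evolution categories.

    Fractions are over the five-category denominator only; the
    subclonal-only exclusion bucket is reported separately.
    """

    counts: dict = field(default_factory=dict)
    fractions: dict = field(default_factory=dict)
    n_classified: int = 0
    n_excluded: int = 0

    @property
    def empty(self) -> bool:
        return self.n_classified == 0


def summarize_categories(cohort, params: AnalysisParams | None = None) -> CategorySummary:
    """Tally mutation categories over a cohort of patient records."""
    p = params or AnalysisParams()
    counts = {c: 0 for c in CATEGORIES}
    excluded = 0
    for pr in cohort:
        for v in pr.variants:
            cat = classify_mutation(v, p)
            if cat == EXCLUDED_CATEGORY:
                excluded += 1
            else:
                counts[cat] += 1
    total = sum(counts.values())
    if total == 0:
        warnings.warn("no mutations in the five-category denominator; "
                      "empty summary returned", stacklevel=2)
        return CategorySummary(counts=counts, fractions={c: 0.0 for c in CATEGORIES},
                               n_classified=0, n_excluded=excluded)
    fractions = {c: counts[c] / total for c in CATEGORIES}
    return CategorySummary(counts=counts, fractions=fractions,
                           n_classified=total, n_excluded=excluded)


@dataclass(frozen=True)
class EvolutionCall:
    """Patient-level relapse origin call."""

    patient_id: str
    label: str                 # successor | precursor | novel
    retention_fraction: float  # ID major-clone mutations still detected at REL
    major_cluster_id: int | None
    n_shared: int              # mutations detected at both timepoints


def classify_patient_evolution(pr: PatientRecord, tree,
                               params: AnalysisParams | None = None) -> EvolutionCall:
    """Classify a patient's relapse as successor, precursor or novel.

    The diagnostic major clone is the clone cluster with the highest mean
    ID-CCF (ties broken by larger size, then lexicographically smallest
    member). The relapse is a successor when at least
    ``successor_retention_threshold`` of the major clone's mutations are
    still detected at relapse, a precursor-derived relapse otherwise, and a
    novel leukemia when no mutation is shared between the timepoints at all.
    """
    p = params or AnalysisParams()
    id_detected = [v for v in pr.variants if detected(v, "ID", p)]
    if not id_detected:
        raise ValueError(f"patient {pr.patient_id}: no diagnostic clone "
                         "(no mutation detected at ID)")
    by_vid = {v.vid: v for v in pr.variants}
    shared = [v for v in pr.variants
              if detected(v, "ID", p) and detected(v, "REL", p)]

    major = max(tree.clusters,
                key=lambda c: (c.ccf_id, len(c.members), _neg_str(min(c.members))))
    members = [by_vid[m] for m in major.members if m in by_vid]
    retained = sum(1 for v in members if detected(v, "REL", p))
    r = retained / len(members) if members else 0.0

    if not shared:
        label = "novel"
    elif r >= p.successor_retention_threshold:
        label = "successor"
    else:
        label = "precursor"
    return EvolutionCall(patient_id=pr.patient_id, label=label,
                         retention_fraction=r,
                         major_cluster_id=major.cluster_id, n_shared=len(shared))


class _neg_str(str):
    """Inverts string comparison so max() prefers the smallest identifier."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):  # pragma: no cover - trivial
        return str.__lt__(self, other)


def dichotomize_timing(pr: PatientRecord, params: AnalysisParams | None = None) -> str:
    """Early relapse strictly below the cutoff; at the cutoff counts as late."""
    p = params or AnalysisParams()
    if pr.days_to_relapse <= 0:
        raise ValueError("days_to_relapse must be positive")
    return "early" if pr.days_to_relapse < p.early_late_cutoff_days else "late"
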