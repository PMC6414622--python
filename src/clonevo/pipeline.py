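"""Stage chaining used by the command-line interface and reports."""

from __future__ import annotations

import pandas as pd

from .clonal import build_clone_tree, build_cooccurrence
from .core import AnalysisParams, attach_chromosome_states
from .evolution import (classify_mutation, classify_patient_evolution,
                        dichotomize_timing, summarize_categories)
from .simulate import CHROM_LENGTHS_GRCH37
from .subtypes import SubtypeConfig, call_subtype, check_stability


def classify_cohort(patients, params: AnalysisParams | None = None):
    """Per-variant categories, per-patient clone trees and evolution calls.

    Returns ``(variant_df, patient_df, trees)`` where the frames carry the
    variant table plus its category column and the per-patient evolution,
    retention and timing calls.
    """
    p = params or AnalysisParams()
    trees = {pr.patient_id: build_clone_tree(pr, p) for pr in patients}
    vrows, prows = [], []
    for pr in patients:
        for v in pr.variants:
            vrows.append({"patient_id": pr.patient_id, "vid": v.vid,
                          "gene": v.gene, "vaf_id": v.vaf_id,
                          "vaf_rel": v.vaf_rel,
                          "category": classify_mutation(v, p)})
        call = classify_patient_evolution(pr, trees[pr.patient_id], p)
        prows.append({"patient_id": pr.patient_id,
                      "evolution_class": call.label,
                      "retention_fraction": call.retention_fraction,
                      "n_shared": call.n_shared,
                      "timing_class": dichotomize_timing(pr, p)})
    return pd.DataFrame(vrows), pd.DataFrame(prows), trees


def subtype_cohort(patients, chrom_lengths=None,
                   params: AnalysisParams | None = None,
                   config: SubtypeConfig | None = None):
    """Call subtypes at both timepoints and the ID/REL stability fraction."""
    p = params or AnalysisParams()
    lengths = chrom_lengths or dict(CHROM_LENGTHS_GRCH37)
    if any(not pr.chrom_states for pr in patients):
        attach_chromosome_states(patients, lengths, p.chrom_coverage_fraction)
    calls = [call_subtype(pr, tp, p, config)
             for pr in patients for tp in ("ID", "REL")]
    return calls, check_stability(calls)


def cohort_report(patients, chrom_lengths=None,
                  params: AnalysisParams | None = None) -> dict:
    """Summary dictionary mirroring the headline cohort statistics."""
    p = params or AnalysisParams()
    variant_df, patient_df, trees = classify_cohort(patients, p)
    summary = summarize_categories(patients, p)
    calls, stability = subtype_cohort(patients, chrom_lengths, p)
    network = build_cooccurrence(patients, trees, p)
    n = len(patients)
    return {
        "n_patients": n,
        "n_variants": int(len(variant_df)),
        "category_counts": summary.counts,
        "category_fractions": summary.fractions,
        "n_excluded_subclonal_only": summary.n_excluded,
        "evolution_fractions": {
            label: float((patient_df["evolution_class"] == label).mean())
            for label in ("successor", "precursor", "novel")},
        "timing_fractions": {
            label: float((patient_df["timing_class"] == label).mean())
            for label in ("early", "late")},
        "subtype_stability_fraction": stability.fraction_stable,
        "n_network_genes": len(network.nodes),
        "n_network_edges": len(network.edges),
    }
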