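"""Truth-vs-inference comparison helpers for simulated cohorts."""

from __future__ import annotations


def clustering_labels(truth_patient: dict, tree):
    """Aligned (true, inferred) clone labels over variants present in both.

    Variants undetected at both timepoints are absent from the inferred tree
    and are skipped. Suitable input for an adjusted-Rand comparison.
    """
    inferred = {m: c.cluster_id for c in tree.clusters for m in c.members}
    true_labels, inf_labels = [], []
    for vid, info in sorted(truth_patient["variants"].items()):
        if vid in inferred:
            true_labels.append(info["clone"])
            inf_labels.append(inferred[vid])
    return true_labels, inf_labels


def _true_ancestor_pairs(clones: dict):
    """All (ancestor, descendant) clone-name pairs, transitively."""
    pairs = set()
    for name, info in clones.items():
        parent = info.get("parent")
        while parent is not None:
            if parent in clones:
                pairs.add((parent, name))
            parent = clones.get(parent, {}).get("parent")
    return pairs


def ancestor_pair_recovery(truth_patient: dict, tree):
    """Fraction of true ancestor clone pairs recovered as ancestor pairs.

    Each true clone maps to the inferred cluster holding the majority of its
    variants; a pair counts as recovered when the mapped clusters differ and
    the ancestor's cluster dominates the descendant's in the inferred
    forest. Returns ``(n_recovered, n_pairs)``.
    """
    inferred = {m: c.cluster_id for c in tree.clusters for m in c.members}
    votes = {}
    for vid, info in truth_patient["variants"].items():
        if vid in inferred:
            votes.setdefault(info["clone"], []).append(inferred[vid])
    mapped = {}
    for clone, cluster_ids in votes.items():
        counts = sorted(((cluster_ids.count(c), -c) for c in set(cluster_ids)),
                        reverse=True)
        mapped[clone] = -counts[0][1]
    pairs = [(a, b) for a, b in _true_ancestor_pairs(truth_patient["clones"])
             if a in mapped and b in mapped]
    recovered = sum(
        1 for a, b in pairs
        if mapped[a] != mapped[b] and mapped[b] in tree.descendants(mapped[a]))
    return recovered, len(pairs)


def scenario_recovery(truth, evolution_calls) -> float:
    """Fraction of patients assigned their generating relapse scenario."""
    calls = {c.patient_id: c.label for c in evolution_calls}
    hits = total = 0
    for pid, info in truth.patients.items():
        if pid in calls:
            total += 1
            hits += calls[pid] == info["scenario"]
    return hits / total if total else float("nan")


def subtype_recovery(truth, subtype_calls) -> float:
    """Fraction of (patient, timepoint) calls matching the generated subtype."""
    hits = total = 0
    for c in subtype_calls:
        info = truth.patients.get(c.patient_id)
        if info is not None:
            total += 1
            hits += c.label == info["subtype"]
    return hits / total if total else float("nan")
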