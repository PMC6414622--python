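"""Deterministic clone clustering, ancestry ordering and co-occurrence.

Variants detected at either timepoint are mapped to cancer cell fractions
(CCFs) and clustered by single-linkage agglomeration in the
(CCF_ID, CCF_REL) plane. Ancestry between clusters follows a dominance rule:
a cluster can only descend from a cluster whose CCF is at least as high at
both timepoints (within a tolerance), and each cluster attaches to its
closest dominating cluster. The procedure is fully deterministic — merge
candidates are ordered by (distance, smallest member id) — so shuffling the
input order never changes the result.

The cohort-level co-occurrence network counts, per ordered gene pair (a, b),
the number of patients in which a mutation of b lies in the same clone as a
mutation of a or in one of its descendant clones.
"""

from __future__ import annotations

import itertools
import json
from collections import defaultdict
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np

from .core import AnalysisParams, PatientRecord
from .evolution import detected

#: CCF multiplier by segment state at the variant's locus: VAF * factor,
#: clamped to 1. Diploid heterozygous sites double the VAF; a het loss leaves
#: one copy (factor 1); a gain is modeled as three copies with mutation
#: multiplicity 1. cnloh / hom-loss carry no prescribed factor and are
#: treated as copy-number 2.
_CCF_FACTOR = {"neutral": 2.0, "loss_het": 1.0, "gain": 3.0,
               "cnloh": 2.0, "loss_hom": 2.0}


def ccf(v, segments=(), params: AnalysisParams | None = None):
    """CCF pair for one variant, given the patient's CNA segments."""
    p = params or AnalysisParams()
    out = []
    for tp, vaf in (("ID", v.vaf_id), ("REL", v.vaf_rel)):
        state = "neutral"
        for s in segments:
            if (s.timepoint == tp and s.chrom == v.chrom
                    and s.start <= v.pos <= s.end and s.state != "neutral"):
                state = s.state
                break
        out.append(min(1.0, _CCF_FACTOR[state] * vaf / p.purity))
    return tuple(out)


@dataclass(frozen=True)
class Cluster:
    cluster_id: int
    members: tuple          # variant ids, sorted
    ccf_id: float           # mean CCF at diagnosis
    ccf_rel: float          # mean CCF at relapse


@dataclass
class CloneTree:
    """Per-patient clone clusters with ancestry edges (a forest)."""

    patient_id: str
    clusters: list = field(default_factory=list)
    edges: list = field(default_factory=list)       # (parent_id, child_id)
    siblings: list = field(default_factory=list)    # crossing-CCF pairs
    violations: list = field(default_factory=list)  # pigeonhole warnings

    def cluster_of(self, vid: str) -> int:
        for c in self.clusters:
            if vid in c.members:
                return c.cluster_id
        raise KeyError(vid)

    def children(self, cluster_id: int):
        return [b for a, b in self.edges if a == cluster_id]

    def descendants(self, cluster_id: int):
        out, stack = set(), [cluster_id]
        while stack:
            for child in self.children(stack.pop()):
                if child not in out:
                    out.add(child)
                    stack.append(child)
        return out

    def to_dict(self) -> dict:
        return {"patient_id": self.patient_id,
                "clusters": [asdict(c) for c in self.clusters],
                "edges": [list(e) for e in self.edges],
                "siblings": [list(s) for s in self.siblings],
                "violations": list(self.violations)}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def cluster_variants(ccf_pairs: dict, params: AnalysisParams | None = None):
    """Single-linkage clustering of variants in (CCF_ID, CCF_REL) space.

    ``ccf_pairs`` maps variant id -> (ccf_id, ccf_rel). Merging continues
    while the minimum inter-cluster distance is at most
    ``cluster_link_distance``; candidate merges are ordered by
    (distance, smallest member ids) for determinism. Final cluster ids are
    assigned from 1 by descending mean ID-CCF (ties: larger cluster, then
    smallest member id).
    """
    p = params or AnalysisParams()
    vids = sorted(ccf_pairs)
    if not vids:
        return []
    points = np.array([ccf_pairs[v] for v in vids], dtype=float)
    clusters = [[i] for i in range(len(vids))]
    # pairwise distances between variants (fixed; single linkage uses mins)
    diff = points[:, None, :] - points[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))

    while len(clusters) > 1:
        best = None
        for (ia, ca), (ib, cb) in itertools.combinations(enumerate(clusters), 2):
            d = dist[np.ix_(ca, cb)].min()
            key = (d, vids[min(ca)], vids[min(cb)])
            if best is None or key < best[0]:
                best = (key, ia, ib)
        (d, _, _), ia, ib = best
        if d > p.cluster_link_distance:
            break
        clusters[ia] = sorted(clusters[ia] + clusters[ib])
        del clusters[ib]

    summaries = []
    for members in clusters:
        mvids = tuple(sorted(vids[i] for i in members))
        mean = points[members].mean(axis=0)
        summaries.append((mvids, float(mean[0]), float(mean[1])))
    summaries.sort(key=lambda s: (-s[1], -len(s[0]), s[0][0]))
    return [Cluster(cluster_id=i + 1, members=m, ccf_id=ci, ccf_rel=cr)
            for i, (m, ci, cr) in enumerate(summaries)]


def order_ancestry(clusters, params: AnalysisParams | None = None):
    """Derive parent edges, sibling annotations and pigeonhole violations.

    Cluster A is an ancestor candidate of B when its mean CCF is at least
    B's minus ``ancestry_tolerance`` at both timepoints and A strictly
    precedes B in the (total CCF, id) order — the strict order guarantees an
    acyclic forest. Each cluster attaches to its lowest-CCF (closest)
    candidate. Pairs with crossing CCFs beyond tolerance are annotated as
    siblings. For each parent, the summed child CCF may not exceed the
    parent's by more than the tolerance per timepoint; violations are
    reported, not fatal.
    """
    p = params or AnalysisParams()
    tol = p.ancestry_tolerance
    edges, siblings, violations = [], [], []

    def order_key(c):
        return (-(c.ccf_id + c.ccf_rel), c.cluster_id)

    for b in clusters:
        candidates = [a for a in clusters
                      if a.cluster_id != b.cluster_id
                      and a.ccf_id >= b.ccf_id - tol
                      and a.ccf_rel >= b.ccf_rel - tol
                      and order_key(a) < order_key(b)]
        if candidates:
            parent = min(candidates,
                         key=lambda a: (a.ccf_id + a.ccf_rel, a.cluster_id))
            edges.append((parent.cluster_id, b.cluster_id))

    for a, b in itertools.combinations(clusters, 2):
        crossing = ((a.ccf_id > b.ccf_id + tol and b.ccf_rel > a.ccf_rel + tol)
                    or (b.ccf_id > a.ccf_id + tol and a.ccf_rel > b.ccf_rel + tol))
        if crossing:
            siblings.append((a.cluster_id, b.cluster_id))

    by_id = {c.cluster_id: c for c in clusters}
    children = defaultdict(list)
    for parent, child in edges:
        children[parent].append(child)
    for parent_id, kids in sorted(children.items()):
        parent = by_id[parent_id]
        for attr in ("ccf_id", "ccf_rel"):
            total = sum(getattr(by_id[k], attr) for k in kids)
            if total > getattr(parent, attr) + tol:
                violations.append(
                    f"cluster {parent_id}: child {attr} sum {total:.3f} exceeds "
                    f"parent {getattr(parent, attr):.3f} + tolerance")
    return edges, siblings, violations


def build_clone_tree(pr: PatientRecord,
                     params: AnalysisParams | None = None) -> CloneTree:
    """Cluster a patient's detected variants and order their ancestry."""
    p = params or AnalysisParams()
    usable = [v for v in pr.variants
              if detected(v, "ID", p) or detected(v, "REL", p)]
    pairs = {v.vid: ccf(v, pr.segments, p) for v in usable}
    clusters = cluster_variants(pairs, p)
    edges, siblings, violations = order_ancestry(clusters, p)
    return CloneTree(patient_id=pr.patient_id, clusters=clusters,
                     edges=edges, siblings=siblings, violations=violations)


@dataclass
class CooccurrenceNetwork:
    """Gene co-occurrence over same-or-descendant clones, cohort-wide.

    ``nodes`` maps gene -> cohort mutation count; ``edges`` maps
    (gene_a, gene_b) -> number of patients in which a gene_b mutation lies in
    the same cluster as a gene_a mutation or in one of its descendants.
    Same-cluster pairs contribute to both directions.
    """

    nodes: dict = field(default_factory=dict)
    edges: dict = field(default_factory=dict)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for gene, count in self.nodes.items():
            g.add_node(gene, count=count)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g


def build_cooccurrence(patients, trees: dict,
                       params: AnalysisParams | None = None,
                       panel=None) -> CooccurrenceNetwork:
    """Build the cohort co-occurrence network from per-patient clone trees.

    ``trees`` maps patient_id -> :class:`CloneTree`. ``panel`` optionally
    restricts genes. Each patient contributes at most 1 to each directed
    gene pair.
    """
    p = params or AnalysisParams()
    nodes = defaultdict(int)
    edges = defaultdict(int)
    for pr in patients:
        tree = trees[pr.patient_id]
        in_tree = {m for c in tree.clusters for m in c.members}
        genes_by_cluster = defaultdict(set)
        for v in pr.variants:
            if v.vid not in in_tree:
                continue
            if panel is not None and v.gene not in panel:
                continue
            nodes[v.gene] += 1
            genes_by_cluster[tree.cluster_of(v.vid)].add(v.gene)
        seen_pairs = set()
        for cid, genes_a in genes_by_cluster.items():
            reach = {cid} | tree.descendants(cid)
            genes_b = set().union(*(genes_by_cluster[c] for c in reach
                                    if c in genes_by_cluster))
            for a in genes_a:
                for b in genes_b:
                    if a != b:
                        seen_pairs.add((a, b))
        for pair in seen_pairs:
            edges[pair] += 1
    return CooccurrenceNetwork(nodes=dict(nodes), edges=dict(edges))
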