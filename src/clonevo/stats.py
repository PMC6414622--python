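"""Alteration matrices and subgroup enrichment statistics.

Patient x gene alteration matrices aggregate non-silent mutations and
copy-number losses over diagnosis and/or relapse ("double hit" when both hit
the same gene in a patient). Subgroup contrasts use the exact two-sided
Fisher test computed directly from the hypergeometric PMF — all tables with
the observed margins whose point probability does not exceed the observed
one (with a small relative slack against floating-point equality) are
summed; no asymptotic approximation is used. Paired mutation burdens are
compared with a Wilcoxon signed-rank test whose null distribution is
enumerated exactly for small samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import AnalysisParams, NON_SILENT_EFFECTS
from .evolution import classify_mutation, detected

CELL_VALUES = ("none", "mutation", "deletion", "double_hit")
LOSS_STATES = ("loss_hom", "loss_het")
RELAPSE_SPECIFIC_CATEGORIES = ("rel_only", "expanded_subclonal")

#: curated relapse-alteration panel, gene -> functional category
DEFAULT_RELAPSE_PANEL = {
    "FPGS": "metabolism", "AGBL1": "metabolism", "NT5C2": "metabolism",
    "PRPS1": "metabolism",
    "CREBBP": "chromatin_modifier", "KMT2D": "chromatin_modifier",
    "EZH2": "chromatin_modifier", "SETD2": "chromatin_modifier",
    "ATRX": "chromatin_modifier",
    "TP53": "tp53_others", "RB1": "tp53_others", "NR3C1": "tp53_others",
    "IKZF1": "tp53_others", "CDKN2A": "tp53_others", "CDKN2B": "tp53_others",
    "PTPRD": "tp53_others",
}


@dataclass
class AlterationMatrix:
    """Patient x gene matrix of alteration classes (oncoprint-style)."""

    df: pd.DataFrame  # index: patient ids; columns: genes; values: CELL_VALUES

    def altered(self, gene: str) -> pd.Series:
        return self.df[gene] != "none"

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="patient_id")


def _mutated_genes(pr, timepoints, relapse_specific, params):
    genes = set()
    for v in pr.variants:
        if v.effect not in NON_SILENT_EFFECTS:
            continue
        if relapse_specific:
            if classify_mutation(v, params) in RELAPSE_SPECIFIC_CATEGORIES:
                genes.add(v.gene)
        elif any(detected(v, tp, params) for tp in timepoints):
            genes.add(v.gene)
    return genes


def _deleted_genes(pr, timepoints, relapse_specific):
    loss_by_tp = {"ID": set(), "REL": set()}
    for s in pr.segments:
        if s.state in LOSS_STATES:
            loss_by_tp[s.timepoint].update(s.gene_overlaps)
    if relapse_specific:
        return loss_by_tp["REL"] - loss_by_tp["ID"]
    return set().union(*(loss_by_tp[tp] for tp in timepoints))


def build_matrix(cohort, panel, timepoints=("ID", "REL"),
                 relapse_specific: bool = False,
                 params: AnalysisParams | None = None) -> AlterationMatrix:
    """Aggregate mutations and losses into a patient x gene matrix.

    A cell is ``double_hit`` when a patient carries both mutation and
    deletion evidence for the gene, else the single class, else ``none``.
    With ``relapse_specific=True``, mutations are restricted to the
    relapse-specific evolution categories and losses to relapse segments
    with no diagnostic counterpart.
    """
    p = params or AnalysisParams()
    panel = list(panel)
    if not panel:
        raise ValueError("gene panel must be non-empty")
    timepoints = tuple(timepoints)
    rows = {}
    seen_anywhere = set()
    for pr in cohort:
        muts = _mutated_genes(pr, timepoints, relapse_specific, p)
        dels = _deleted_genes(pr, timepoints, relapse_specific)
        seen_anywhere |= {v.gene for v in pr.variants}
        seen_anywhere |= {g for s in pr.segments for g in s.gene_overlaps}
        row = {}
        for gene in panel:
            if gene in muts and gene in dels:
                row[gene] = "double_hit"
            elif gene in muts:
                row[gene] = "mutation"
            elif gene in dels:
                row[gene] = "deletion"
            else:
                row[gene] = "none"
        rows[pr.patient_id] = row
    for gene in panel:
        if gene not in seen_anywhere:
            warnings.warn(f"panel gene {gene!r} never observed in the cohort; "
                          "column is all none", stacklevel=2)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=panel)
    return AlterationMatrix(df=df.sort_index())


def fisher_exact_two_sided(a: int, b: int, c: int, d: int,
                           rel_tol: float = 1e-7) -> float:
    """Exact two-sided Fisher p for the 2x2 table [[a, b], [c, d]].

    Sums the hypergeometric point probabilities of every table with the
    observed margins whose probability is at most the observed table's times
    ``(1 + rel_tol)``; the slack guards against floating-point equality
    failures. Any empty margin yields p = 1 by convention.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be non-negative integers")
    n1, n2, k = a + b, c + d, a + c
    n = n1 + n2
    if n1 == 0 or n2 == 0 or k == 0 or (b + d) == 0:
        return 1.0
    support = np.arange(max(0, k - n2), min(k, n1) + 1)
    pmf = sps.hypergeom.pmf(support, n, k, n1)
    p_obs = pmf[np.searchsorted(support, a)]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + rel_tol)].sum()))


@dataclass(frozen=True)
class ContingencyResult:
    """One gene's 2x2 enrichment contrast between two patient groups."""

    gene: str
    group1: str
    group2: str
    a: int  # altered, group1
    b: int  # not altered, group1
    c: int  # altered, group2
    d: int  # not altered, group2
    odds_ratio: float
    p: float
    q: float = float("nan")  # Benjamini-Hochberg, informational only


def enrich(matrix: AlterationMatrix, grouping: dict, panel=None):
    """Fisher-test every panel gene between the two groups in ``grouping``.

    ``grouping`` maps patient id -> group label; exactly two groups are
    required and every matrix patient must be grouped. Results are sorted by
    ascending p. The odds ratio is (a*d)/(b*c) with division by zero giving
    infinity. A BH-adjusted q column is attached for convenience; raw p
    values are the primary output.
    """
    missing = [pid for pid in matrix.df.index if pid not in grouping]
    if missing:
        raise ValueError(f"patients without a group: {missing[:5]}")
    groups = sorted({grouping[pid] for pid in matrix.df.index})
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    g1, g2 = groups
    in_g1 = pd.Series([grouping[pid] == g1 for pid in matrix.df.index],
                      index=matrix.df.index)
    panel = list(panel) if panel is not None else list(matrix.df.columns)
    results = []
    for gene in panel:
        alt = matrix.altered(gene)
        a = int((alt & in_g1).sum())
        b = int((~alt & in_g1).sum())
        c = int((alt & ~in_g1).sum())
        d = int((~alt & ~in_g1).sum())
        if b * c == 0:
            odds = float("inf") if a * d > 0 else float("nan")
        else:
            odds = (a * d) / (b * c)
        results.append((gene, a, b, c, d, odds,
                        fisher_exact_two_sided(a, b, c, d)))
    pvals = np.array([r[-1] for r in results])
    qvals = sps.false_discovery_control(pvals) if len(pvals) else pvals
    out = [ContingencyResult(gene=g, group1=g1, group2=g2, a=a, b=b, c=c, d=d,
                             odds_ratio=odds, p=p, q=float(q))
           for (g, a, b, c, d, odds, p), q in zip(results, qvals)]
    return sorted(out, key=lambda r: (r.p, r.gene))


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def _wilcoxon_exact(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p via subset-sum enumeration.

    Ranks of |d| use mid-ranks for ties; doubling makes them integers, so
    the null distribution of W+ over all 2^n sign assignments is built by
    exact polynomial convolution.
    """
    ranks = sps.rankdata(np.abs(diffs))
    r2 = np.rint(2 * ranks).astype(int)
    w_obs = int(r2[diffs > 0].sum())
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted if r else 2 * counts
    cdf = np.cumsum(counts) / counts.sum()
    p_le = cdf[w_obs]
    p_ge = 1.0 - (cdf[w_obs - 1] if w_obs > 0 else 0.0)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _wilcoxon_approx(x, y) -> float:
    """Normal approximation with tie correction and continuity correction."""
    res = sps.wilcoxon(x, y, zero_method="wilcox", correction=True,
                       alternative="two-sided", method="approx")
    return float(res.pvalue)


def wilcoxon_signed_rank_paired(x, y, exact_max_n: int = 25) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped; tied absolute differences get mid-ranks.
    The null is enumerated exactly for up to ``exact_max_n`` non-zero
    differences, and approximated normally (with tie and continuity
    corrections) beyond that. All differences zero gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    diffs = y - x
    diffs = diffs[diffs != 0]
    if len(diffs) == 0:
        return 1.0
    if len(diffs) <= exact_max_n:
        return _wilcoxon_exact(diffs)
    return _wilcoxon_approx(x, y)


@dataclass
class RelapseSpecificSummary:
    """Per-patient relapse-specific alteration flags over a curated panel."""

    per_patient: dict            # patient_id -> bool
    fraction_flagged: float
    category_counts: dict = field(default_factory=dict)  # category -> n patients
    n_patients: int = 0


def relapse_specific_summary(cohort, panel: dict | None = None,
                             params: AnalysisParams | None = None
                             ) -> RelapseSpecificSummary:
    """Flag patients with a relapse-specific lesion in a categorized panel.

    A patient is flagged when at least one panel gene carries a
    relapse-specific non-silent mutation (REL-only or expanded from
    subclonal) or a relapse-specific copy-number loss (a REL loss segment
    with no ID counterpart). ``panel`` maps gene -> functional category.
    """
    p = params or AnalysisParams()
    panel = DEFAULT_RELAPSE_PANEL if panel is None else dict(panel)
    if not panel:
        raise ValueError("panel must be non-empty")
    per_patient = {}
    category_hits = {cat: set() for cat in sorted(set(panel.values()))}
    for pr in cohort:
        hit_genes = (_mutated_genes(pr, ("REL",), True, p)
                     | _deleted_genes(pr, ("REL",), True)) & set(panel)
        per_patient[pr.patient_id] = bool(hit_genes)
        for gene in hit_genes:
            category_hits[panel[gene]].add(pr.patient_id)
    n = len(per_patient)
    frac = sum(per_patient.values()) / n if n else float("nan")
    return RelapseSpecificSummary(
        per_patient=per_patient, fraction_flagged=frac,
        category_counts={cat: len(pids) for cat, pids in category_hits.items()},
        n_patients=n)
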