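"""Rule-based molecular subtype calls from genetic and karyotype evidence.

The calls approximate the expression/methylation-defined BCP-ALL subtypes
with a deterministic genetic proxy: a DUX4-IGH fusion defines DUX4; a
TP53-mutated multi-chromosome-LOH karyotype with chr1/chr22 gains defines
masked low-hypodiploid (LH); a whole-chromosome gain pattern including
chr4/14/21 defines masked near-haploid / high-hyperdiploid (NH-HeH); three
or more whole chromosomes with LOH defines other aneuploidies; CRLF2 or
kinase-pathway lesions define Ph-like; remaining known fusions and PAX5
lesions define their own groups. The first matching rule in this fixed
priority order wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import yaml

from .core import AnalysisParams, PatientRecord
from .evolution import detected

SUBTYPE_LABELS = ("DUX4", "LH", "NH_HeH", "aneuploid_other", "Ph_like",
                  "PAX5_driven", "unclassified")  # plus known_fusion:<name>


@dataclass
class SubtypeConfig:
    """Panels and flags consulted by the rule caller."""

    dux4_fusion: str = "DUX4-IGH"
    kinase_genes: tuple = ("CRLF2", "JAK2", "IL7R")
    kinase_fusion_flags: tuple = ("P2RY8-CRLF2", "IGH-CRLF2", "EBF1-PDGFRB")
    known_fusions: tuple = ("BCL2-IGH", "EP300-ZNF384", "MEF2D-PYGO2",
                            "KMT2A-MLLT3")
    pax5_gene: str = "PAX5"
    min_aneuploid_chroms: int = 3
    lh_gain_chroms: tuple = ("1", "22")
    nh_heh_gain_chroms: tuple = ("4", "14", "21")

    @classmethod
    def from_yaml(cls, path) -> "SubtypeConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**{k: tuple(v) if isinstance(v, list) else v
                      for k, v in data.items()})


@dataclass(frozen=True)
class SubtypeCall:
    patient_id: str
    timepoint: str
    label: str
    evidence: tuple = ()


def _norm_chrom(chrom: str) -> str:
    return chrom.removeprefix("chr")


def call_subtype(pr: PatientRecord, timepoint: str,
                 params: AnalysisParams | None = None,
                 config: SubtypeConfig | None = None) -> SubtypeCall:
    """Assign the first matching subtype rule for one patient/timepoint."""
    p = params or AnalysisParams()
    cfg = config or SubtypeConfig()
    states = {_norm_chrom(cs.chrom): cs.whole_chrom_state
              for cs in pr.chrom_states if cs.timepoint == timepoint}
    if not states:
        raise ValueError(
            f"patient {pr.patient_id}: no chromosome states for {timepoint}; "
            "run summarize_chromosomes first")

    loh = {c for c, s in states.items() if s in ("loss", "cnloh")}
    gains = {c for c, s in states.items() if s == "gain"}
    nonneutral = {c for c, s in states.items() if s != "neutral"}
    muts = {v.gene for v in pr.variants
            if detected(v, timepoint, p) and v.effect != "silent"}

    def call(label, evidence):
        return SubtypeCall(pr.patient_id, timepoint, label, tuple(evidence))

    # 1. DUX4-IGH fusion is definitional
    if cfg.dux4_fusion in pr.fusion_flags:
        return call("DUX4", [f"fusion:{cfg.dux4_fusion}"])
    # 2. masked low-hypodiploid: TP53 + multi-chromosome LOH + chr1/22 gains
    if (pr.tp53_mutated and len(loh) >= cfg.min_aneuploid_chroms
            and all(c in gains for c in cfg.lh_gain_chroms)):
        return call("LH", ["TP53_mutated",
                           f"LOH_chroms:{','.join(sorted(loh, key=_csort))}",
                           f"gains:{','.join(cfg.lh_gain_chroms)}"])
    # 3. masked near-haploid / high-hyperdiploid: gain pattern incl. 4/14/21
    if (len(nonneutral) >= cfg.min_aneuploid_chroms
            and all(c in gains for c in cfg.nh_heh_gain_chroms)):
        return call("NH_HeH", [f"gains:{','.join(sorted(gains, key=_csort))}"])
    # 4. other aneuploidies: 3+ whole chromosomes with LOH
    if len(loh) >= cfg.min_aneuploid_chroms:
        return call("aneuploid_other",
                    [f"LOH_chroms:{','.join(sorted(loh, key=_csort))}"])
    # 5. Ph-like: CRLF2/kinase mutation or kinase-class fusion
    kinase_muts = sorted(set(cfg.kinase_genes) & muts)
    kinase_fusions = sorted(set(cfg.kinase_fusion_flags) & pr.fusion_flags)
    if kinase_muts or kinase_fusions:
        return call("Ph_like", [f"mutation:{g}" for g in kinase_muts]
                    + [f"fusion:{f}" for f in kinase_fusions])
    # 6. remaining known fusions
    for fusion in cfg.known_fusions:
        if fusion in pr.fusion_flags:
            return call(f"known_fusion:{fusion}", [f"fusion:{fusion}"])
    # 7. PAX5-driven: PAX5 mutation or any PAX5 fusion
    pax5_fusions = sorted(f for f in pr.fusion_flags
                          if cfg.pax5_gene in f.split("-"))
    if cfg.pax5_gene in muts or pax5_fusions:
        ev = ([f"mutation:{cfg.pax5_gene}"] if cfg.pax5_gene in muts else []) \
            + [f"fusion:{f}" for f in pax5_fusions]
        return call("PAX5_driven", ev)
    return call("unclassified", [])


def _csort(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


@dataclass
class StabilityResult:
    per_patient: dict            # patient_id -> bool (labels equal at ID/REL)
    fraction_stable: float
    n_evaluated: int


def check_stability(calls) -> StabilityResult:
    """Compare subtype labels between ID and REL for each patient.

    ``calls`` is an iterable of :class:`SubtypeCall` covering both
    timepoints. Patients missing a timepoint are skipped with a warning.
    """
    by_patient = {}
    for c in calls:
        by_patient.setdefault(c.patient_id, {})[c.timepoint] = c
    per_patient = {}
    for pid, tps in sorted(by_patient.items()):
        if "ID" not in tps or "REL" not in tps:
            warnings.warn(f"patient {pid}: missing a timepoint, skipped",
                          stacklevel=2)
            continue
        per_patient[pid] = tps["ID"].label == tps["REL"].label
    n = len(per_patient)
    frac = sum(per_patient.values()) / n if n else float("nan")
    return StabilityResult(per_patient=per_patient, fraction_stable=frac,
                           n_evaluated=n)
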