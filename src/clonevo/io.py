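"""Readers and writers for the plain-text interchange formats.

TSV is the canonical interchange format; VCF (two-sample, AD-style depths) is
supported as a reader dialect only. All writers emit a deterministic column
order and a stable row sort, and round-trip losslessly through the readers.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .core import (CNASegment, ChromosomeState, PatientRecord, SchemaError,
                   ValidationError, VariantCall, _chrom_sort_key)

VARIANT_COLUMNS = ["patient_id", "chrom", "pos", "ref", "alt", "gene", "effect",
                   "alt_id", "depth_id", "alt_rel", "depth_rel"]
SEGMENT_COLUMNS = ["patient_id", "timepoint", "chrom", "start", "end", "state",
                   "gene_overlaps"]
METADATA_COLUMNS = ["patient_id", "age_group", "days_to_relapse",
                    "tp53_mutated", "fusion_flags"]

VARIANT_FILE = "variants.tsv"
SEGMENT_FILE = "segments.tsv"
METADATA_FILE = "metadata.tsv"
CHROM_LENGTH_FILE = "chrom_lengths.tsv"


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_variant_table(path, dialect: str = "tsv", patient_id: str | None = None):
    """Read paired-timepoint variant calls from a TSV or two-sample VCF.

    VAFs are always recomputed from the read counts; any vaf columns present
    in a TSV are ignored. Returns a list of validated :class:`VariantCall`.
    """
    if dialect == "tsv":
        return _read_variant_tsv(path)
    if dialect == "vcf":
        return _read_variant_vcf(path, patient_id=patient_id)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_variant_tsv(path):
    df = _read_tsv(path)
    _require_columns(df, VARIANT_COLUMNS, path)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(VariantCall(
                patient_id=row.patient_id, chrom=row.chrom, pos=int(row.pos),
                ref=row.ref, alt=row.alt, gene=row.gene, effect=row.effect,
                alt_id=int(row.alt_id), depth_id=int(row.depth_id),
                alt_rel=int(row.alt_rel), depth_rel=int(row.depth_rel)))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def _read_variant_vcf(path, patient_id=None):
    from cyvcf2 import VCF  # optional dependency, only for this dialect

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(samples) != 2:
        raise SchemaError(
            f"{path}: VCF dialect requires exactly two samples (ID, REL), "
            f"found {samples}")
    # samples named ID/REL are honored; otherwise first=ID, second=REL
    if set(samples) == {"ID", "REL"}:
        idx_id, idx_rel = samples.index("ID"), samples.index("REL")
    else:
        idx_id, idx_rel = 0, 1
    records = []
    for i, rec in enumerate(vcf, start=1):
        ad = rec.format("AD")
        if ad is None:
            raise SchemaError(f"{path}: record {i}: missing AD format field")
        pid = rec.INFO.get("PATIENT", patient_id)
        if pid is None:
            raise SchemaError(
                f"{path}: record {i}: no PATIENT INFO field and no patient_id given")
        ref_id, alt_id = int(ad[idx_id][0]), int(ad[idx_id][1])
        ref_rel, alt_rel = int(ad[idx_rel][0]), int(ad[idx_rel][1])
        try:
            records.append(VariantCall(
                patient_id=pid, chrom=rec.CHROM, pos=rec.POS,
                ref=rec.REF, alt=rec.ALT[0],
                gene=rec.INFO.get("GENE", ""),
                effect=rec.INFO.get("EFFECT", "other"),
                alt_id=alt_id, depth_id=ref_id + alt_id,
                alt_rel=alt_rel, depth_rel=ref_rel + alt_rel))
        except ValidationError as exc:
            raise ValidationError(f"{path}: record {i}: {exc}") from exc
    return records


def write_variant_table(records, path) -> None:
    """Write variant calls as TSV, sorted by (patient, chrom, pos, ref, alt).

    Derived VAF columns are included for readability; readers recompute them.
    """
    rows = [{**{c: getattr(v, c) for c in VARIANT_COLUMNS},
             "vaf_id": f"{v.vaf_id:.6g}", "vaf_rel": f"{v.vaf_rel:.6g}"}
            for v in sorted(records, key=lambda v: v.sort_key())]
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS + ["vaf_id", "vaf_rel"])
    df.to_csv(path, sep="\t", index=False)


#: write_calls is the generic entry point for analysis outputs
write_calls = write_variant_table


def read_segment_table(path, zero_based: bool = False):
    """Read CNA segments; ``zero_based=True`` converts BED half-open starts."""
    df = _read_tsv(path)
    _require_columns(df, SEGMENT_COLUMNS, path)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start = int(row.start) + (1 if zero_based else 0)
            genes = tuple(g for g in row.gene_overlaps.split(";") if g)
            records.append(CNASegment(
                patient_id=row.patient_id, timepoint=row.timepoint,
                chrom=row.chrom, start=start, end=int(row.end),
                state=row.state, gene_overlaps=genes))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def write_segment_table(segments, path) -> None:
    rows = [{"patient_id": s.patient_id, "timepoint": s.timepoint,
             "chrom": s.chrom, "start": s.start, "end": s.end, "state": s.state,
             "gene_overlaps": ";".join(s.gene_overlaps)}
            for s in sorted(segments, key=lambda s: (
                s.patient_id, s.timepoint, _chrom_sort_key(s.chrom), s.start, s.end))]
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_metadata_table(path):
    """Read patient metadata; returns patients with empty molecular payloads."""
    df = _read_tsv(path)
    _require_columns(df, METADATA_COLUMNS, path)
    patients = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            patients.append(PatientRecord(
                patient_id=row.patient_id, age_group=row.age_group,
                days_to_relapse=float(row.days_to_relapse),
                tp53_mutated=row.tp53_mutated.lower() in ("true", "1", "yes"),
                fusion_flags=frozenset(
                    f for f in row.fusion_flags.split(";") if f)))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return patients


def write_metadata_table(patients, path) -> None:
    rows = [{"patient_id": p.patient_id, "age_group": p.age_group,
             "days_to_relapse": f"{p.days_to_relapse:.6g}",
             "tp53_mutated": str(p.tp53_mutated).lower(),
             "fusion_flags": ";".join(sorted(p.fusion_flags))}
            for p in sorted(patients, key=lambda p: p.patient_id)]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def read_chromosome_lengths(path) -> dict:
    df = _read_tsv(path)
    _require_columns(df, ["chrom", "length"], path)
    return {row.chrom: int(row.length) for row in df.itertuples(index=False)}


def write_chromosome_lengths(chrom_lengths: dict, path) -> None:
    rows = [{"chrom": c, "length": chrom_lengths[c]}
            for c in sorted(chrom_lengths, key=_chrom_sort_key)]
    pd.DataFrame(rows, columns=["chrom", "length"]).to_csv(path, sep="\t", index=False)


def load_cohort(directory):
    """Load a cohort directory into patient records.

    Expects ``metadata.tsv`` and ``variants.tsv``; ``segments.tsv`` and
    ``chrom_lengths.tsv`` are optional. Returns ``(patients, chrom_lengths)``
    with variants and segments attached to their patients.
    """
    directory = Path(directory)
    patients = read_metadata_table(directory / METADATA_FILE)
    by_id = {p.patient_id: p for p in patients}

    vpath = directory / VARIANT_FILE
    if vpath.exists():
        for v in read_variant_table(vpath):
            if v.patient_id not in by_id:
                raise SchemaError(
                    f"{vpath}: variant for unknown patient {v.patient_id!r}")
            by_id[v.patient_id].variants.append(v)

    spath = directory / SEGMENT_FILE
    if spath.exists():
        for s in read_segment_table(spath):
            if s.patient_id not in by_id:
                raise SchemaError(
                    f"{spath}: segment for unknown patient {s.patient_id!r}")
            by_id[s.patient_id].segments.append(s)

    lpath = directory / CHROM_LENGTH_FILE
    chrom_lengths = read_chromosome_lengths(lpath) if lpath.exists() else {}
    return patients, chrom_lengths


def write_cohort(patients, chrom_lengths, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_metadata_table(patients, directory / METADATA_FILE)
    write_variant_table(
        [v for p in patients for v in p.variants], directory / VARIANT_FILE)
    write_segment_table(
        [s for p in patients for s in p.segments], directory / SEGMENT_FILE)
    if chrom_lengths:
        write_chromosome_lengths(chrom_lengths, directory / CHROM_LENGTH_FILE)
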