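"""Readers and writers for the pipeline's file formats.

VCF (via pysam) for SV callsets and the nonredundant genotype matrix,
BED for masks/annotation tracks, PAF for assembly-to-reference alignments,
TSV for pedigree / read-support / truth tables, and a bedMethyl-style BED
for per-CpG haplotype methylation.

All VCF positions are 1-based on disk and on :class:`~svsieve.types.SVRecord`;
interval arithmetic elsewhere is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import pysam

from svsieve.types import (
    ExclusionMask,
    Genotype,
    MergeParams,
    Pedigree,
    PedigreeEntry,
    SVRecord,
    expected_ploidy,
    is_sex_chrom,
)

logger = logging.getLogger("svsieve")

DEFAULT_CONTIG_LEN = 1 << 29

_VCF_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type (DEL or INS)">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length; negative for DEL">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="1-based inclusive end">',
    '##INFO=<ID=SEQ,Number=1,Type=String,Description="Inserted (INS) or deleted (DEL) sequence">',
    '##INFO=<ID=CALLERS,Number=.,Type=String,Description="Callers reporting this allele">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def _build_header(samples: Sequence[str], contigs: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for line in _VCF_HEADER_LINES:
        header.add_line(line)
    for chrom, length in contigs.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    for s in samples:
        header.add_sample(s)
    return header


def _contigs_from_records(records: Sequence[SVRecord]) -> dict[str, int]:
    contigs: dict[str, int] = {}
    for r in records:
        contigs[r.chrom] = max(contigs.get(r.chrom, 0), r.end + 1000)
    return {c: max(n, DEFAULT_CONTIG_LEN) for c, n in contigs.items()} or {}


def write_sv_vcf(
    path: str | Path,
    records: Sequence[SVRecord],
    genotypes: Optional[dict[str, dict[str, Genotype]]] = None,
    samples: Sequence[str] = (),
    contigs: Optional[dict[str, int]] = None,
) -> None:
    """Write SV records (and optional per-sample genotypes) as VCF.

    ``genotypes`` maps record id -> {sample -> Genotype}; samples without an
    entry are written as missing.  Hemizygous genotypes are written with a
    single allele (``1`` rather than ``1/1``).
    """
    samples = list(samples)
    if genotypes is not None and not samples:
        raise ValueError("samples must be given when genotypes are written")
    contigs = contigs or _contigs_from_records(records)
    header = _build_header(samples, contigs)
    recs = sorted(records, key=lambda r: (r.chrom, r.pos, r.id))
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in recs:
            rec = vf.new_record()
            rec.chrom = r.chrom
            rec.pos = r.pos
            rec.id = r.id
            rec.ref = "N"
            rec.alts = (f"<{r.svtype}>",)
            rec.qual = float(r.qual)
            rec.info["SVTYPE"] = r.svtype
            rec.info["SVLEN"] = -r.svlen if r.svtype == "DEL" else r.svlen
            rec.stop = r.end  # pysam writes INFO/END
            if r.seq is not None:
                rec.info["SEQ"] = r.seq
            if r.callers:
                rec.info["CALLERS"] = tuple(sorted(r.callers))
            gts = (genotypes or {}).get(r.id, {})
            for s in samples:
                gt = gts.get(s)
                if gt is None:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = tuple(gt.alleles)
                    rec.samples[s].phased = gt.phased
            vf.write(rec)


def _info_get(rec, key, default=None):
    # pysam raises on INFO keys that the header does not declare
    try:
        return rec.info.get(key, default)
    except (KeyError, ValueError):
        return default


def _parse_alt(rec, alt: str, svlen_info) -> tuple[str, int, Optional[str]]:
    """Return (svtype, svlen, seq) for one ALT allele."""
    if alt.startswith("<"):
        svtype = alt.strip("<>")
        if svtype not in ("DEL", "INS"):
            raise ValueError(f"unsupported ALT {alt}")
        if svlen_info is None:
            raise ValueError("symbolic ALT without SVLEN")
        svlen = abs(int(svlen_info))
        seq = _info_get(rec, "SEQ")
        if isinstance(seq, tuple):
            seq = seq[0]
        return svtype, svlen, seq
    # sequence-resolved ALT
    ref = rec.ref
    if len(alt) > len(ref):
        return "INS", len(alt) - len(ref), alt[len(ref):]
    if len(ref) > len(alt):
        return "DEL", len(ref) - len(alt), ref[len(alt):]
    raise ValueError(f"ALT {alt!r} is not an SV allele")


def read_sv_vcf(
    path: str | Path,
    sample_sex: Optional[dict[str, str]] = None,
    params: Optional[MergeParams] = None,
    mask: Optional[ExclusionMask] = None,
) -> tuple[list[SVRecord], dict[str, dict[str, Genotype]]]:
    """Read a (possibly multi-sample) SV VCF.

    Multi-allelic records are split into one :class:`SVRecord` per ALT.
    Records outside ``[sizemin, sizemax]`` are dropped; non-DEL/INS alleles
    are rejected with a warning.  For male samples, diploid genotypes on
    non-PAR chrX / chrY are coerced to hemizygous (with a warning).
    Malformed records are logged with their line number and skipped, except
    that a symbolic ALT without SVLEN raises.
    """
    sample_sex = sample_sex or {}
    records: list[SVRecord] = []
    genotypes: dict[str, dict[str, Genotype]] = {}
    with pysam.VariantFile(str(path)) as vf:
        vcf_samples = list(vf.header.samples)
        for lineno, rec in enumerate(vf, start=1):
            alts = rec.alts or ()
            svlen_info = _info_get(rec, "SVLEN")
            if isinstance(svlen_info, tuple):
                svlens = list(svlen_info)
            else:
                svlens = [svlen_info] * len(alts)
            for ai, alt in enumerate(alts):
                try:
                    svtype, svlen, seq = _parse_alt(rec, alt, svlens[ai])
                except ValueError as exc:
                    if "without SVLEN" in str(exc):
                        raise ValueError(f"{path} record {lineno}: {exc}") from exc
                    logger.warning("%s record %d: %s -- skipped", path, lineno, exc)
                    continue
                if params is not None and not (params.sizemin <= svlen <= params.sizemax):
                    continue
                rid = rec.id or f"{rec.chrom}_{rec.pos}_{svtype}_{svlen}"
                if len(alts) > 1:
                    rid = f"{rid}.{ai}"
                callers = _info_get(rec, "CALLERS", ())
                if isinstance(callers, str):
                    callers = (callers,)
                try:
                    sv = SVRecord(
                        id=rid,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        svtype=svtype,
                        svlen=svlen,
                        qual=float(rec.qual) if rec.qual is not None else 0.0,
                        seq=seq or None,
                        callers=frozenset(callers),
                    )
                except ValueError as exc:
                    logger.warning("%s record %d: %s -- skipped", path, lineno, exc)
                    continue
                records.append(sv)
                gts: dict[str, Genotype] = {}
                for s in vcf_samples:
                    raw = rec.samples[s].get("GT")
                    if raw is None:
                        raw = (None,)
                    alleles = tuple(None if a is None else (1 if a == ai + 1 else 0) for a in raw)
                    phased = bool(rec.samples[s].phased)
                    gt = Genotype(alleles, phased=phased)
                    sex = sample_sex.get(s)
                    if (
                        sex == "male"
                        and is_sex_chrom(sv.chrom)
                        and gt.ploidy == 2
                        and expected_ploidy(sv.chrom, "male", mask, sv.pos) == 1
                    ):
                        logger.warning(
                            "coercing diploid %s genotype %s to hemizygous for male %s at %s:%d",
                            sv.chrom, gt, s, sv.chrom, sv.pos,
                        )
                        gt = Genotype((1,) if gt.has_alt else ((0,) if not gt.is_missing else (None,)))
                    gts[s] = gt
                genotypes[rid] = gts
    return records, genotypes


def apply_mask(records: Sequence[SVRecord], mask: ExclusionMask) -> list[SVRecord]:
    """Drop SVs whose footprint overlaps a masked region by >= 1 bp."""
    kept = []
    for r in records:
        s, e = r.interval0()
        if not mask.overlaps(r.chrom, s, e):
            kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# pedigree TSV

PED_COLUMNS = ["sample_id", "family_id", "role", "sex", "affected", "superpop"]


def write_pedigree(path: str | Path, ped: Pedigree) -> None:
    rows = [
        {
            "sample_id": e.sample_id,
            "family_id": e.family_id,
            "role": e.role,
            "sex": e.sex,
            "affected": int(e.affected),
            "superpop": e.superpop,
        }
        for e in ped.entries
    ]
    pd.DataFrame(rows, columns=PED_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    entries = [
        PedigreeEntry(
            sample_id=row.sample_id,
            family_id=row.family_id,
            role=row.role,
            sex=row.sex,
            affected=bool(int(row.affected)),
            superpop=row.superpop,
        )
        for row in df.itertuples()
    ]
    return Pedigree(entries)


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file; columns chrom/start/end plus optional name/score."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name", "score"][: df.shape[1]]
    df.columns = cols + [f"extra{i}" for i in range(df.shape[1] - len(cols))]
    return df


def write_bed(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def mask_from_bed(path: str | Path, par_names: Sequence[str] = ("PAR1", "PAR2")) -> ExclusionMask:
    """Build an exclusion mask from a named BED (4th column = region name).

    Intervals named PAR* populate the PAR lookup as well as the mask.
    """
    df = read_bed(path)
    intervals: dict[str, list[tuple[int, int]]] = {}
    par: dict[str, list[tuple[int, int]]] = {}
    for row in df.itertuples():
        intervals.setdefault(row.chrom, []).append((int(row.start), int(row.end)))
        name = getattr(row, "name", "")
        if isinstance(name, str) and any(name.startswith(p) for p in ("PAR",)):
            par.setdefault(row.chrom, []).append((int(row.start), int(row.end)))
    return ExclusionMask(intervals, par)


# ---------------------------------------------------------------------------
# PAF

@dataclass(frozen=True)
class PafRecord:
    """One alignment block in minimap2 PAF format (0-based half-open)."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int = 0
    alen: int = 0
    mapq: int = 60


def read_paf(path: str | Path) -> list[PafRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                PafRecord(
                    qname=f[0], qlen=int(f[1]), qstart=int(f[2]), qend=int(f[3]),
                    strand=f[4], tname=f[5], tlen=int(f[6]), tstart=int(f[7]),
                    tend=int(f[8]), nmatch=int(f[9]), alen=int(f[10]), mapq=int(f[11]),
                )
            )
    return out


def write_paf(path: str | Path, records: Sequence[PafRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.qname, r.qlen, r.qstart, r.qend, r.strand,
                        r.tname, r.tlen, r.tstart, r.tend, r.nmatch, r.alen, r.mapq,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# bedMethyl-style methylation pileups

METHYL_COLUMNS = ["chrom", "start", "end", "name", "coverage", "frac"]


def read_methyl_bed(path: str | Path) -> pd.DataFrame:
    """Per-CpG methylated fraction: chrom, start, end, name, coverage, frac."""
    df = pd.read_csv(path, sep="\t", header=None, names=METHYL_COLUMNS)
    if not ((df["frac"] >= 0) & (df["frac"] <= 1)).all():
        raise ValueError(f"{path}: methylation fractions must lie in [0, 1]")
    return df


def write_methyl_bed(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=METHYL_COLUMNS, float_format="%.4f")


# ---------------------------------------------------------------------------
# read-support table

SUPPORT_COLUMNS = ["sv_id", "sample", "n_reads", "mean_mapq", "frac_clipped"]


def read_support_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SUPPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing read-support columns {sorted(missing)}")
    return df


def write_support_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
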