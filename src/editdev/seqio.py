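"""Readers and writers for the standard formats the pipeline touches.

SAM is read through :mod:`pysam`; VCF through ``pysam.VariantFile``; FASTA /
FASTQ through ``pysam.FastxFile``.  Editing
matrices round-trip through TSV bit-exactly (floats serialised with ``repr``).

Strandedness convention: for a ``forward`` protocol the sequenced read maps to
the transcript strand, so a reverse-flag alignment comes from a minus-strand
transcript; ``reverse`` is the opposite; ``unstranded`` leaves the transcript
strand undetermined and downstream stages fall back on gene annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam

from . import _seq

log = logging.getLogger("editdev")

PROTOCOLS = ("forward", "reverse", "unstranded")


@dataclass
class AlignedRead:
    """One mapped read, ungapped-or-gapped, in 0-based coordinates."""

    qname: str
    chrom: str
    qpos: np.ndarray        # query offsets of aligned (matched) bases
    rpos: np.ndarray        # reference positions of those bases
    seq: np.ndarray         # full query sequence, uint8 codes
    qual: np.ndarray        # full query Phred scores
    mapq: int
    is_reverse: bool        # alignment orientation on the reference
    read_len: int

    def transcript_strand(self, protocol: str) -> str | None:
        if protocol == "forward":
            return "-" if self.is_reverse else "+"
        if protocol == "reverse":
            return "+" if self.is_reverse else "-"
        return None


def read_alignments(path: str | Path, protocol: str = "forward") -> Iterator[AlignedRead]:
    """Stream mapped reads from a SAM file.

    Reads without a quality string are rejected (a count is logged); the
    protocol flag is validated here so that downstream strand handling can
    trust it.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"protocol must be one of {PROTOCOLS}")
    n_rejected = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for idx, rec in enumerate(sam):
            if rec.is_unmapped:
                continue
            if rec.query_qualities is None or rec.query_sequence is None:
                n_rejected += 1
                continue
            pairs = rec.get_aligned_pairs(matches_only=True)
            if not pairs:
                raise ValueError(f"record {idx} ({rec.query_name}): no aligned bases")
            qpos = np.fromiter((q for q, _ in pairs), dtype=np.int64)
            rpos = np.fromiter((r for _, r in pairs), dtype=np.int64)
            yield AlignedRead(
                qname=rec.query_name,
                chrom=rec.reference_name,
                qpos=qpos,
                rpos=rpos,
                seq=_seq.encode(rec.query_sequence),
                qual=np.asarray(rec.query_qualities, dtype=np.int16),
                mapq=rec.mapping_quality,
                is_reverse=rec.is_reverse,
                read_len=rec.query_length,
            )
    if n_rejected:
        log.warning("rejected %d reads lacking base qualities", n_rejected)


def write_sam(path: str | Path, chrom_lengths: dict[str, int],
              reads: Iterable[tuple[str, str, int, bool, str, str]]) -> None:
    """Write an ungapped SAM file.

    ``reads`` yields ``(qname, chrom, start0, is_reverse, seq, qual_str)``;
    CIGAR is all-match.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for qname, chrom, start0, is_rev, seq, qual in reads:
            flag = 16 if is_rev else 0
            fh.write(f"{qname}\t{flag}\t{chrom}\t{start0 + 1}\t60\t{len(seq)}M\t*\t0\t0\t{seq}\t{qual}\n")


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    with pysam.FastxFile(str(path)) as fx:
        return {rec.name: rec.sequence.upper() for rec in fx}


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, np.ndarray]]:
    """Yield (name, sequence, Phred array)."""
    with pysam.FastxFile(str(path)) as fx:
        for rec in fx:
            yield rec.name, rec.sequence.upper(), np.asarray(
                rec.get_quality_array(), dtype=np.int16)


def phred_to_string(q: np.ndarray) -> str:
    return (np.asarray(q, dtype=np.uint8) + 33).tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# editing-matrix TSV round trip


def write_matrix(levels: pd.DataFrame, path: str | Path) -> None:
    """Write a sites x samples editing-level matrix; missing cells stay empty.

    Values must be finite or NaN; the site index must be unique.  Floats are
    serialised with ``repr`` so the round trip is bit-exact.
    """
    if levels.index.has_duplicates:
        dupes = levels.index[levels.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate site ids: {dupes[:3]}")
    vals = levels.to_numpy(dtype=float)
    if np.isinf(vals).any():
        raise ValueError("non-finite editing levels cannot be written")
    with open(path, "w") as fh:
        fh.write("site_id\t" + "\t".join(map(str, levels.columns)) + "\n")
        for site_id, row in zip(levels.index, vals):
            cells = ["" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(str(site_id) + "\t" + "\t".join(cells) + "\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    out = df.apply(lambda col: col.map(lambda v: np.nan if pd.isna(v) or v == "" else float(v)))
    if out.index.has_duplicates:
        raise ValueError("duplicate site ids in matrix file")
    out.index.name = None
    return out.astype(float)


# ---------------------------------------------------------------------------
# VCF


def write_vcf(path: str | Path, sample_ids: list[str],
              variants: Iterable[tuple[str, int, str, str, str, np.ndarray]],
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal VCF v4.2 with GT fields.

    ``variants`` yields ``(chrom, pos0, variant_id, ref, alt, genotypes)``
    where genotypes are 0/1/2 alt-allele dosages (−1 for missing).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for chrom, pos0, vid, ref, alt, geno in variants:
            gts = "\t".join(gt_str[int(g)] for g in geno)
            fh.write(f"{chrom}\t{pos0 + 1}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf_dosages(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF into (variant table, dosage matrix).

    Returns a table with columns chrom/pos0/ref/alt indexed by variant id, and
    a variants x samples DataFrame of alt-allele dosages (NaN = missing).
    Multi-allelic records are rejected.
    """
    rows, dosages, ids = [], [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise ValueError(f"non-biallelic record at {rec.chrom}:{rec.pos}")
            vid = rec.id or f"{rec.chrom}:{rec.pos}"
            ids.append(vid)
            rows.append((rec.chrom, rec.pos - 1, rec.ref, rec.alts[0]))
            dose = []
            for s in samples:
                gt = rec.samples[s]["GT"]
                if gt is None or any(a is None for a in gt):
                    dose.append(np.nan)
                else:
                    dose.append(float(sum(gt)))
            dosages.append(dose)
    table = pd.DataFrame(rows, columns=["chrom", "pos0", "ref", "alt"], index=ids)
    mat = pd.DataFrame(dosages, index=ids, columns=samples, dtype=float)
    return table, mat


# ---------------------------------------------------------------------------
# site ids


def site_id(chrom: str, pos0: int, strand: str) -> str:
    """Site identifier ``chrom:pos1:strand`` (1-based, as in site tables)."""
    return f"{chrom}:{pos0 + 1}:{strand}"


def parse_site_id(sid: str) -> tuple[str, int, str]:
    chrom, pos1, strand = sid.rsplit(":", 2)
    return chrom, int(pos1) - 1, strand
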