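"""Genomic intervals and annotation tracks.

Internally every coordinate is 0-based half-open; 1-based coordinates occur
only at the VCF / pileup / site-table boundaries.  Annotation tracks (gene
models, repeats, known-site catalog, variant mask, blacklist, splice
junctions) are indexed with interval trees for point lookup.

Genic labels resolve by the precedence ``CDS > UTR > ncRNA > intron``;
positions outside every gene are ``intergenic``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")
GENIC_LABELS = ("CDS", "5'UTR", "3'UTR", "intron", "ncRNA")
# lookup precedence when labels overlap at one base
_PRECEDENCE = {"CDS": 0, "5'UTR": 1, "3'UTR": 1, "ncRNA": 2, "intron": 3}
REPEAT_CLASSES = ("Alu", "repetitive non-Alu")


class ParseError(ValueError):
    """Malformed annotation input; message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def to_1based(pos0: int) -> int:
    return pos0 + 1


def to_0based(pos1: int) -> int:
    return pos1 - 1


@dataclass
class GeneModel:
    gene_id: str
    strand: str
    parts: list[tuple[GenomicInterval, str]] = field(default_factory=list)

    @property
    def span(self) -> GenomicInterval:
        chrom = self.parts[0][0].chrom
        return GenomicInterval(chrom, min(p.start for p, _ in self.parts),
                               max(p.end for p, _ in self.parts), self.strand)


@dataclass
class AnnotationSet:
    """All annotation tracks consumed by the pipeline, point-indexed."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    repeats: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    known_sites: set[tuple[str, int, str]] = field(default_factory=set)  # (chrom, pos0, strand)
    variant_maf: dict[tuple[str, int], float] = field(default_factory=dict)  # pos0 -> MAF
    blacklist: list[GenomicInterval] = field(default_factory=list)
    splice_junctions: set[tuple[str, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._gene_trees: dict[str, IntervalTree] = {}
        self._repeat_trees: dict[str, IntervalTree] = {}
        self._blacklist_trees: dict[str, IntervalTree] = {}
        self.reindex()

    def reindex(self) -> None:
        self._gene_trees = {}
        for gene in self.genes.values():
            for iv, label in gene.parts:
                self._gene_trees.setdefault(iv.chrom, IntervalTree()).addi(
                    iv.start, iv.end, (gene.gene_id, label, gene.strand))
        self._repeat_trees = {}
        for iv, family in self.repeats:
            self._repeat_trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, (family, iv.strand))
        self._blacklist_trees = {}
        for iv in self.blacklist:
            self._blacklist_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        # introns imply junctions at both boundaries
        for gene in self.genes.values():
            for iv, label in gene.parts:
                if label == "intron":
                    self.splice_junctions.add((iv.chrom, iv.start))
                    self.splice_junctions.add((iv.chrom, iv.end))

    # -- point lookups -------------------------------------------------------

    def genic_region(self, chrom: str, pos0: int, strand: str | None = None) -> str:
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return "intergenic"
        hits = [h.data for h in tree.at(pos0)]
        if strand is not None and strand in "+-":
            hits = [h for h in hits if h[2] == strand] or hits
        if not hits:
            return "intergenic"
        return min(hits, key=lambda h: _PRECEDENCE[h[1]])[1]

    def gene_at(self, chrom: str, pos0: int) -> list[tuple[str, str]]:
        """(gene_id, strand) of every gene covering a position."""
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return []
        seen: dict[str, str] = {}
        for h in tree.at(pos0):
            seen[h.data[0]] = h.data[2]
        return sorted(seen.items())

    def strand_at(self, chrom: str, pos0: int) -> str | None:
        """Transcript strand from gene annotation; None if absent/ambiguous."""
        strands = {s for _, s in self.gene_at(chrom, pos0)}
        if len(strands) == 1:
            return strands.pop()
        return None

    def repeat_class(self, chrom: str, pos0: int) -> str:
        tree = self._repeat_trees.get(chrom)
        if tree is None:
            return "nonrepetitive"
        hits = [h.data[0] for h in tree.at(pos0)]
        if "Alu" in hits:
            return "Alu"
        if hits:
            return "repetitive non-Alu"
        return "nonrepetitive"

    def in_blacklist(self, chrom: str, pos0: int) -> bool:
        tree = self._blacklist_trees.get(chrom)
        return bool(tree and tree.at(pos0))

    def is_masked_variant(self, chrom: str, pos0: int, maf_threshold: float) -> bool:
        maf = self.variant_maf.get((chrom, pos0))
        return maf is not None and maf > maf_threshold

    def near_junction(self, chrom: str, pos0: int, within_bp: int) -> bool:
        return any((chrom, j) in self.splice_junctions
                   for j in range(pos0 - within_bp, pos0 + within_bp + 1))


# ---------------------------------------------------------------------------
# loaders


def _bed_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        yield lineno, line.split("\t") if "\t" in line else line.split()


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED (>=3 columns, 0-based half-open) into intervals."""
    out = []
    for lineno, f in _bed_lines(path):
        try:
            start, end = int(f[1]), int(f[2])
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], start, end, strand))
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Iterable[str] | None = None) -> None:
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"region_{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Gene models from BED6 whose name field is ``gene_id:label``."""
    genes: dict[str, GeneModel] = {}
    for lineno, f in _bed_lines(path):
        try:
            chrom, start, end = f[0], int(f[1]), int(f[2])
            gene_id, label = f[3].split(":", 1)
            strand = f[5]
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if label not in GENIC_LABELS:
            raise ParseError(f"{path}:{lineno}: unknown genic label {label!r}")
        iv = GenomicInterval(chrom, start, end, strand)
        gene = genes.setdefault(gene_id, GeneModel(gene_id, strand))
        if gene.strand != strand:
            raise ParseError(f"{path}:{lineno}: strand conflict for {gene_id}")
        gene.parts.append((iv, label))
    return genes


def read_repeats(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Repeat BED6 with name in {Alu, repetitive non-Alu} (underscores allowed)."""
    out = []
    for lineno, f in _bed_lines(path):
        try:
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), f[5] if len(f) > 5 else ".")
            family = f[3].replace("_", " ")
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if family not in REPEAT_CLASSES:
            raise ParseError(f"{path}:{lineno}: unknown repeat class {f[3]!r}")
        out.append((iv, family))
    return out


def read_known_sites(path: str | Path) -> set[tuple[str, int, str]]:
    """Known-site catalog TSV: chrom, pos (1-based), strand."""
    sites = set()
    for lineno, f in _bed_lines(path):
        try:
            chrom, pos1, strand = f[0], int(f[1]), f[2]
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if strand not in "+-":
            raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
        sites.add((chrom, to_0based(pos1), strand))
    return sites


def read_variant_mask(path: str | Path) -> dict[tuple[str, int], float]:
    """Population-variant mask TSV: chrom, pos (1-based), minor-allele freq."""
    mask = {}
    for lineno, f in _bed_lines(path):
        try:
            mask[(f[0], to_0based(int(f[1])))] = float(f[2])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return mask


def load_annotations(gene_models: str | Path | None = None,
                     repeats: str | Path | None = None,
                     known_sites: str | Path | None = None,
                     variant_mask: str | Path | None = None,
                     blacklist: str | Path | None = None) -> AnnotationSet:
    """Assemble an :class:`AnnotationSet` from on-disk tracks (all optional)."""
    return AnnotationSet(
        genes=read_gene_models(gene_models) if gene_models else {},
        repeats=read_repeats(repeats) if repeats else [],
        known_sites=read_known_sites(known_sites) if known_sites else set(),
        variant_maf=read_variant_mask(variant_mask) if variant_mask else {},
        blacklist=read_bed(blacklist) if blacklist else [],
    )
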