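"""Per-sample Alu editing index (AEI).

The AEI is 100 x (A-to-G mismatch read-bases) / (total read-bases at
reference adenosines), restricted to annotated Alu intervals on their
transcript strand.  The denominator is depth-weighted (read-bases, not
positions), masked common variants are excluded, and only uniquely mapped
reads (MAPQ above a configurable cutoff) contribute.  For non-primate
genomes the repeat family is a parameter (e.g. B1/B2 SINEs in mouse);
other substitution types can be indexed for noise diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from . import _seq
from .config import FilterConfig
from .intervals import AnnotationSet
from .seqio import AlignedRead


@dataclass
class AEIResult:
    sample_id: str
    numerator: int        # edited (mismatch) read-bases
    denominator: int      # all read-bases at reference target positions
    index: float          # 100 * numerator / denominator

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError("AEI denominator must be positive")


def _target_arrays(reference: Mapping[str, np.ndarray], annotation: AnnotationSet,
                   cfg: FilterConfig, repeat_families: tuple[str, ...],
                   ref_base: int) -> dict[str, np.ndarray]:
    """Per-chrom flags: 1 = target base on + repeat, 2 = on - repeat."""
    flags = {chrom: np.zeros(arr.size, dtype=np.int8)
             for chrom, arr in reference.items()}
    comp_base = int(_seq._COMP[ref_base])
    for iv, family in annotation.repeats:
        if family not in repeat_families or iv.strand not in "+-":
            continue
        arr = reference[iv.chrom]
        window = arr[iv.start:iv.end]
        want = ref_base if iv.strand == "+" else comp_base
        pos = iv.start + np.flatnonzero(window == want)
        flags[iv.chrom][pos] = 1 if iv.strand == "+" else 2
    for (chrom, pos0), maf in annotation.variant_maf.items():
        if maf > cfg.maf_mask and chrom in flags and pos0 < flags[chrom].size:
            flags[chrom][pos0] = 0
    return flags


def compute_aei(reads: Iterable[AlignedRead], reference: Mapping[str, np.ndarray],
                annotation: AnnotationSet, cfg: FilterConfig,
                sample_id: str = "sample",
                repeat_families: tuple[str, ...] = ("Alu",),
                substitution: tuple[str, str] = ("A", "G")) -> AEIResult:
    """Editing index over repeat intervals for one alignment stream.

    ``substitution`` is (reference base, edited base) on the transcript
    strand; (A, G) gives the AEI proper, other pairs give noise indices.
    """
    ref_b = int(_seq.encode(substitution[0])[0])
    alt_b = int(_seq.encode(substitution[1])[0])
    alt_comp = int(_seq._COMP[alt_b])
    flags = _target_arrays(reference, annotation, cfg, repeat_families, ref_b)
    num = 0
    den = 0
    for read in reads:
        if read.mapq < cfg.min_mapq:
            continue
        fl = flags.get(read.chrom)
        if fl is None:
            continue
        keep = read.qual[read.qpos] >= cfg.min_base_phred
        rpos = read.rpos[keep]
        bases = read.seq[read.qpos[keep]]
        f = fl[rpos]
        plus = (f == 1) & (bases < 4)
        minus = (f == 2) & (bases < 4)
        den += int(plus.sum()) + int(minus.sum())
        num += int((bases[plus] == alt_b).sum()) + int((bases[minus] == alt_comp).sum())
    return AEIResult(sample_id, num, den, 100.0 * num / den if den else float("nan"))
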