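"""Hyper-editing detection from unaligned reads via base-transformed realignment.

Densely edited reads fail ordinary alignment because their many A-to-G
mismatches exceed aligner tolerances.  The detector therefore (1) prescreens
unmapped reads on quality and composition, (2) collapses the edited base pair
in sequence space (every A becomes G) in both read and reference, (3) places
reads with an exact-seed + ungapped-extension aligner in transformed space,
(4) resolves multi-placements by requiring the A-to-G fraction of mismatches
to exceed every alternative by a margin, (5) recovers true adenosines and
screens each read on edit count, mismatch fraction, density, read-end
position and composition, (6) extends and merges per-read clusters, and
(7) normalizes per-sample site counts by uniquely mapped bases.

Antisense hyper-editing (A-to-G on the minus strand, T-to-C on the reference
plus strand) is found by aligning the reverse complement of each read under
the complementary transform.  All twelve substitution types can be screened
by re-running with the corresponding base pair; only A-to-G feeds the
downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import _seq
from .config import FilterConfig
from .intervals import AnnotationSet, GenomicInterval

MAX_REFERENCE_BP = 50_000_000

FAIL_REASONS = ("phred", "composition", "frac_len", "frac_mismatch",
                "density", "read_end", "mono_nt", "multimap")


@dataclass
class HyperRead:
    read_id: str
    chrom: str
    start: int                   # 0-based placement on the reference
    strand: str                  # transcript strand of the recovered edits
    edit_gpos: np.ndarray        # genomic positions of recovered A-to-G edits
    edit_qpos: np.ndarray        # read offsets of those edits
    n_mismatch: int              # all mismatches at the placement
    passed: bool
    fail_reason: str | None = None


@dataclass
class HyperCluster:
    interval: GenomicInterval
    sites: np.ndarray            # genomic positions, sorted
    mean_spacing: float
    read_support: int

    @property
    def n_sites(self) -> int:
        return int(self.sites.size)


@dataclass
class HyperSignal:
    sample_id: str
    n_sites: int
    mapped_bases: int
    signal: float                # 1e6 * sites / bases


# ---------------------------------------------------------------------------
# prescreen


def _mono_fraction(codes: np.ndarray) -> tuple[float, float, float]:
    """(max base fraction, min base fraction, N fraction) over the read."""
    n_frac = float((codes == _seq.N).mean())
    acgt = codes[codes < 4]
    if acgt.size == 0:
        return 1.0, 0.0, n_frac
    counts = np.bincount(acgt, minlength=4)
    return float(counts.max() / acgt.size), float(counts.min() / acgt.size), n_frac


def _is_simple_repeat(codes: np.ndarray, max_motif: int = 3, min_copies: int = 5,
                      min_cover: float = 0.5) -> bool:
    """>= 5 tandem copies of a 1-3 bp motif covering > half the read."""
    s = codes.tobytes()
    L = len(s)
    for m in range(1, max_motif + 1):
        need = int(min_cover * L)
        for i in range(0, L - m * min_copies + 1):
            motif = s[i:i + m]
            j = i + m
            run = m
            while j + m <= L and s[j:j + m] == motif:
                run += m
                j += m
            if run >= m * min_copies and run > need:
                return True
    return False


def prescreen_reads(records: Iterable[tuple[str, str, np.ndarray]],
                    cfg: FilterConfig,
                    max_n_frac: float = 0.10,
                    min_nt_frac: float = 0.10) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Quality/composition prescreen of the unmapped-read pool.

    Drops reads with mean Phred < 25, simple tandem-repeat structure, N
    content above ``max_n_frac``, or any single-nucleotide fraction above
    ``cfg.mono_nt_frac`` (60%) or below ``min_nt_frac`` (10%).
    Returns (read id, base codes, Phred) for survivors.
    """
    kept = []
    for name, seq, qual in records:
        if float(np.mean(qual)) < cfg.hyper_read_phred:
            continue
        codes = _seq.encode(seq)
        mx, mn, n_frac = _mono_fraction(codes)
        if n_frac > max_n_frac or mx > cfg.mono_nt_frac or mn < min_nt_frac:
            continue
        if _is_simple_repeat(codes):
            continue
        kept.append((name, codes, qual))
    return kept


# ---------------------------------------------------------------------------
# transform + seed index


def transform_space(codes: np.ndarray, from_base: int = _seq.A,
                    to_base: int = _seq.G) -> np.ndarray:
    """Collapse one base pair: every ``from_base`` becomes ``to_base``."""
    out = codes.copy()
    out[out == from_base] = to_base
    return out


def transform_str(seq: str, from_base: str = "A", to_base: str = "G") -> str:
    codes = transform_space(_seq.encode(seq), int(_seq.encode(from_base)[0]),
                            int(_seq.encode(to_base)[0]))
    return _seq.decode(codes)


class SeedIndex:
    """Exact k-mer index of a (transformed) reference built on a rolling 2-bit encode."""

    def __init__(self, codes: np.ndarray, k: int):
        if codes.size > MAX_REFERENCE_BP:
            raise ValueError("reference exceeds the desk-scale cap")
        self.k = k
        self.L = codes.size
        valid = codes < 4
        safe = np.where(valid, codes, 0).astype(np.int64)
        n_win = self.L - k + 1
        h = np.zeros(n_win, dtype=np.int64)
        ok = np.ones(n_win, dtype=bool)
        for j in range(k):
            h += safe[j:j + n_win] << (2 * j)
            ok &= valid[j:j + n_win]
        self._hashes = h[ok]
        self._positions = np.flatnonzero(ok).astype(np.int64)
        order = np.argsort(self._hashes, kind="stable")
        self._hashes = self._hashes[order]
        self._positions = self._positions[order]

    def hash_read_seeds(self, codes: np.ndarray, stride: int | None = None
                        ) -> list[tuple[int, int]]:
        """(offset, hash) for non-overlapping seeds along the read."""
        k = self.k
        stride = stride or k
        out = []
        for off in range(0, codes.size - k + 1, stride):
            window = codes[off:off + k]
            if (window >= 4).any():
                continue
            h = int(np.sum(window.astype(np.int64) << (2 * np.arange(k))))
            out.append((off, h))
        return out

    def lookup(self, h: int) -> np.ndarray:
        lo = np.searchsorted(self._hashes, h, side="left")
        hi = np.searchsorted(self._hashes, h, side="right")
        return self._positions[lo:hi]


@dataclass
class _Placement:
    start: int
    strand: str                   # transcript strand of the edits
    edit_gpos: np.ndarray
    edit_qpos: np.ndarray
    n_mismatch: int
    ag_frac: float


class TransformedAligner:
    """Both-strand exact-seed + ungapped-extension aligner in transformed space.

    For substitution X->Y on the transcript strand the sense pass compares the
    X->Y-transformed read with the X->Y-transformed reference; the antisense
    pass compares the transformed reverse complement with the reference under
    the complementary transform comp(X)->comp(Y).
    """

    def __init__(self, reference: Mapping[str, np.ndarray], cfg: FilterConfig,
                 from_base: str = "A", to_base: str = "G"):
        if len(reference) != 1:
            raise ValueError("desk-scale aligner handles a single contig")
        self.chrom, self.ref = next(iter(reference.items()))
        self.cfg = cfg
        self.fb = int(_seq.encode(from_base)[0])
        self.tb = int(_seq.encode(to_base)[0])
        self.fb_c = int(_seq._COMP[self.fb])
        self.tb_c = int(_seq._COMP[self.tb])
        self.ref_fwd_t = transform_space(self.ref, self.fb, self.tb)
        self.ref_rev_t = transform_space(self.ref, self.fb_c, self.tb_c)
        self.idx_fwd = SeedIndex(self.ref_fwd_t, cfg.seed_len)
        self.idx_rev = SeedIndex(self.ref_rev_t, cfg.seed_len)

    def _extend(self, read_t: np.ndarray, read_orig: np.ndarray,
                start: int, strand: str, flipped: bool,
                ref_t: np.ndarray) -> _Placement | None:
        L = read_t.size
        if start < 0 or start + L > self.ref.size:
            return None
        ref_slice_t = ref_t[start:start + L]
        mm_t = int((ref_slice_t != read_t).sum())
        if mm_t > self.cfg.aligner_max_mismatch_frac * L:
            return None
        ref_slice = self.ref[start:start + L]
        mismatch = ref_slice != read_orig
        if strand == "+":
            edits = mismatch & (ref_slice == self.fb) & (read_orig == self.tb)
        else:
            edits = mismatch & (ref_slice == self.fb_c) & (read_orig == self.tb_c)
        n_mm = int(mismatch.sum())
        n_edit = int(edits.sum())
        ag_frac = (n_edit / n_mm) if n_mm else 1.0
        offs = np.flatnonzero(edits)
        gpos = start + offs
        # read offsets in sequencing orientation, kept paired with gpos
        qpos = (L - 1 - offs) if flipped else offs
        return _Placement(start, strand, gpos, qpos, n_mm, ag_frac)

    def place_read(self, read_id: str, codes: np.ndarray, qual: np.ndarray
                   ) -> HyperRead | None:
        """Best placement of one read, or None when no seed anchors it.

        Reads may arrive in either sequencing orientation from either
        transcript strand, so four combinations are tried: the read and its
        reverse complement, each under the sense transform (X->Y, plus-strand
        edits) and the antisense transform (comp(X)->comp(Y), minus-strand
        edits).  Returns a failed :class:`HyperRead` with reason ``multimap``
        when competing placements sit within the edited-fraction margin.
        """
        cand: dict[tuple[int, str, bool], _Placement] = {}
        rc = _seq.revcomp(codes)
        variants = []
        for orig, flipped in ((codes, False), (rc, True)):
            variants.append((orig, flipped, "+",
                             transform_space(orig, self.fb, self.tb),
                             self.idx_fwd, self.ref_fwd_t))
            variants.append((orig, flipped, "-",
                             transform_space(orig, self.fb_c, self.tb_c),
                             self.idx_rev, self.ref_rev_t))
        for orig, flipped, strand, read_t, idx, ref_t in variants:
            for off, h in idx.hash_read_seeds(read_t):
                for pos in idx.lookup(h):
                    start = int(pos) - off
                    if (start, strand, flipped) in cand:
                        continue
                    pl = self._extend(read_t, orig, start, strand, flipped, ref_t)
                    if pl is not None:
                        cand[(start, strand, flipped)] = pl
        if not cand:
            return None
        placements = sorted(cand.values(), key=lambda p: (-p.ag_frac, p.start, p.strand))
        best = placements[0]
        if len(placements) > 1:
            runner = placements[1]
            if best.ag_frac - runner.ag_frac < self.cfg.multimap_margin:
                return HyperRead(read_id, self.chrom, best.start, best.strand,
                                 np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
                                 best.n_mismatch, False, "multimap")
        return HyperRead(read_id, self.chrom, best.start, best.strand,
                         best.edit_gpos, best.edit_qpos, best.n_mismatch, True)


# ---------------------------------------------------------------------------
# per-read screen


def screen_hyper_read(read: HyperRead, codes: np.ndarray, qual: np.ndarray,
                      cfg: FilterConfig) -> HyperRead:
    """Screening thresholds applied to one placed read.

    High-quality (Phred >= ``cfg.hyper_site_phred``) A-to-G edits must number
    at least 5% of the read length and strictly exceed 60% of all mismatches
    (80% for reads <= 60 bp); the edit span must not exceed 90% of the read
    length; edits confined to the first or last 20% of the read fail; any
    nucleotide above 60% of the read fails.
    """
    if not read.passed:
        return read
    L = codes.size
    hq = qual[read.edit_qpos] >= cfg.hyper_site_phred
    gpos = read.edit_gpos[hq]
    qpos = read.edit_qpos[hq]
    n_edit = int(hq.sum())

    def fail(reason: str) -> HyperRead:
        return HyperRead(read.read_id, read.chrom, read.start, read.strand,
                         gpos, qpos, read.n_mismatch, False, reason)

    if n_edit < cfg.hyper_frac_read_len * L:
        return fail("frac_len")
    frac_needed = (cfg.hyper_frac_mismatch_short if L <= cfg.short_read_len
                   else cfg.hyper_frac_mismatch)
    if read.n_mismatch == 0 or n_edit / read.n_mismatch <= frac_needed:
        return fail("frac_mismatch")
    span = int(qpos.max() - qpos.min() + 1)
    if span > cfg.hyper_density * L:
        return fail("density")
    end_bp = cfg.read_end_frac * L
    if qpos.max() < end_bp or qpos.min() >= L - end_bp:
        return fail("read_end")
    mx, _, _ = _mono_fraction(codes)
    if mx > cfg.mono_nt_frac:
        return fail("mono_nt")
    return HyperRead(read.read_id, read.chrom, read.start, read.strand,
                     gpos, qpos, read.n_mismatch, True)


def detect_hyper_reads(records: Iterable[tuple[str, str, np.ndarray]],
                       reference: Mapping[str, np.ndarray], cfg: FilterConfig,
                       substitution: tuple[str, str] = ("A", "G"),
                       aligner: TransformedAligner | None = None) -> list[HyperRead]:
    """Prescreen, place and screen an unmapped-read pool; returns all placed reads."""
    if aligner is None:
        aligner = TransformedAligner(reference, cfg, *substitution)
    out = []
    for read_id, codes, qual in prescreen_reads(records, cfg):
        placed = aligner.place_read(read_id, codes, qual)
        if placed is None:
            continue
        out.append(screen_hyper_read(placed, codes, qual, cfg))
    return out


# ---------------------------------------------------------------------------
# clusters


def merge_hyper_clusters(reads: Iterable[HyperRead],
                         annotation: AnnotationSet | None = None,
                         cfg: FilterConfig | None = None,
                         sample_variant_positions: set[tuple[str, int]] | None = None,
                         ) -> tuple[list[HyperCluster], set[tuple[str, int, str]]]:
    """Extend per-read clusters by their mean inter-site spacing and merge.

    Single-site clusters extend by zero; the extension is the floor of the
    mean spacing.  Sites at masked population variants (MAF > ``cfg.maf_mask``)
    or at private genomic calls are removed from the merged site set.
    """
    cfg = cfg or FilterConfig()
    sample_variant_positions = sample_variant_positions or set()
    raw: list[tuple[str, str, int, int, np.ndarray]] = []
    for read in reads:
        if not read.passed or read.edit_gpos.size == 0:
            continue
        sites = np.sort(read.edit_gpos)
        ext = int(np.floor(np.mean(np.diff(sites)))) if sites.size > 1 else 0
        raw.append((read.chrom, read.strand, int(sites[0] - ext),
                    int(sites[-1] + ext + 1), sites))
    clusters: list[HyperCluster] = []
    site_set: set[tuple[str, int, str]] = set()
    for (chrom, strand) in sorted({(c, s) for c, s, *_ in raw}):
        group = sorted((r for r in raw if r[0] == chrom and r[1] == strand),
                       key=lambda r: r[2])
        merged: list[list] = []
        for _, _, start, end, sites in group:
            if merged and start < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
                merged[-1][2].append(sites)
                merged[-1][3] += 1
            else:
                merged.append([start, end, [sites], 1])
        for start, end, site_lists, support in merged:
            sites = np.unique(np.concatenate(site_lists))
            keep = np.ones(sites.size, dtype=bool)
            for i, p in enumerate(sites):
                if annotation is not None and annotation.is_masked_variant(
                        chrom, int(p), cfg.maf_mask):
                    keep[i] = False
                elif (chrom, int(p)) in sample_variant_positions:
                    keep[i] = False
            sites = sites[keep]
            if sites.size == 0:
                continue
            spacing = float(np.mean(np.diff(sites))) if sites.size > 1 else 0.0
            clusters.append(HyperCluster(
                GenomicInterval(chrom, max(0, start), end, strand),
                sites, spacing, support))
            site_set.update((chrom, int(p), strand) for p in sites)
    return clusters, site_set


def normalized_hyper_signal(n_sites: int, mapped_bases: int,
                            sample_id: str = "sample") -> HyperSignal:
    """Sites per million uniquely mapped bases."""
    if mapped_bases <= 0:
        raise ValueError("mapped base count must be positive")
    return HyperSignal(sample_id, n_sites, mapped_bases,
                       1e6 * n_sites / mapped_bases)


# ---------------------------------------------------------------------------
# gene-level differential hyper-editing


def gene_hyper_enrichment(counts: pd.DataFrame, cohort: pd.DataFrame,
                          covariates: list[str], cfg: FilterConfig,
                          gene_lengths: pd.Series | None = None,
                          min_detect_frac: float = 0.4) -> pd.DataFrame:
    """Per-gene linear model of hyper-editing site counts on epoch.

    Genes must carry >= 1 site in at least ``min_detect_frac`` of samples
    (missing counts are zero).  When gene lengths are supplied, counts are
    first residualized on log gene length.  Returns per-gene beta (postnatal
    effect), t, p and BH-adjusted p; degenerate genes are flagged and skipped.
    """
    from .stats import bh_adjust, build_design, ols_ttest

    counts = counts.reindex(columns=cohort.index).fillna(0.0)
    detected = (counts > 0).mean(axis=1) >= min_detect_frac
    counts = counts.loc[detected]
    Y = counts.to_numpy(dtype=float)
    if gene_lengths is not None:
        lg = np.log(gene_lengths.reindex(counts.index).to_numpy(dtype=float))
        # residualize each gene's count profile on its own log length is
        # degenerate per-gene; instead remove the across-gene length trend
        X_len = np.column_stack([np.ones(lg.size), lg])
        beta, *_ = np.linalg.lstsq(X_len, Y, rcond=None)
        Y = Y - X_len @ beta

    X, _ = build_design(cohort, covariates, main="epoch")
    rows = []
    keepers = []
    for g, y in zip(counts.index, Y):
        if np.allclose(y, y[0]):
            rows.append((g, np.nan, np.nan, np.nan, True))
            continue
        keepers.append((g, y))
    if keepers:
        Yk = np.vstack([y for _, y in keepers])
        beta, se, t, p = ols_ttest(Yk, X, coef=1)
        for (g, _), b, tt, pp in zip(keepers, beta, t, p):
            rows.append((g, b, tt, pp, False))
    df = pd.DataFrame(rows, columns=["gene", "beta_postnatal", "t", "p", "skipped"]
                      ).set_index("gene").reindex(counts.index)
    ok = ~df["skipped"].astype(bool)
    adj = np.full(len(df), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = bh_adjust(df.loc[ok, "p"].to_numpy())
    df["p_adj"] = adj
    return df
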