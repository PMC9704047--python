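"""Selective editing-site detection: pileup, filter ledger, grouping, matrix.

Detection follows the consensus protocol: de novo candidates must satisfy
coverage >= 10, edited reads >= 3 and editing ratio >= 1% and be called by at
least two callers; supervised (known-site) queries require coverage >= 5 and
edited reads >= 3.  Shared removal filters: multi-allelic events, homopolymer
or blacklisted positions, masked population variants (MAF > 0.05), and
positions with a non-reference genomic call in the matched sample.  Surviving
sites are annotated with genic region, repeat class and known-site status,
grouped by temporal detection pattern, and assembled into a sites x samples
editing-level matrix with donor-based imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import _seq, seqio
from .config import FilterConfig
from .intervals import AnnotationSet
from .seqio import AlignedRead

log = logging.getLogger("editdev")

SiteKey = tuple[str, int, str]  # (chrom, pos0, transcript strand)


@dataclass
class SiteCall:
    """Per-sample base counts at one transcript-strand adenosine."""

    chrom: str
    pos0: int
    strand: str
    ref_base: str                      # on the transcript strand
    counts: np.ndarray                 # A,C,G,T read counts on the transcript strand
    source: str = "denovo"             # or "supervised"
    caller_support: int = 1

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos0, self.strand)

    @property
    def coverage(self) -> int:
        return int(self.counts.sum())

    @property
    def edited(self) -> int:
        return int(self.counts[_seq.G])

    @property
    def level(self) -> float:
        denom = int(self.counts[_seq.A]) + self.edited
        return self.edited / denom if denom else 0.0


@dataclass
class EditingSite:
    call: SiteCall
    region: str = "intergenic"
    repeat_class: str = "nonrepetitive"
    known: bool = False
    group: str | None = None

    @property
    def key(self) -> SiteKey:
        return self.call.key

    @property
    def site_id(self) -> str:
        return seqio.site_id(*self.call.key)


@dataclass
class EditingMatrix:
    """Imputed editing-level matrix with its pre-imputation missingness mask."""

    levels: pd.DataFrame               # sites x samples, no missing cells
    observed: pd.DataFrame             # bool mask: True where a value was measured
    dropped_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.levels.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("imputed matrix must have no missing cells")
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("editing levels must lie in [0, 1]")


# ---------------------------------------------------------------------------
# pileup


def pileup_counts(reads: Iterable[AlignedRead], reference: Mapping[str, np.ndarray],
                  cfg: FilterConfig, protocol: str = "forward",
                  annotation: AnnotationSet | None = None,
                  exclude_read_ends: bool = True) -> dict[SiteKey, np.ndarray]:
    """Strand-resolved base counts per covered position.

    Base calls below ``cfg.min_base_phred`` and reads below ``cfg.min_mapq``
    are excluded; with ``exclude_read_ends`` the first/last ``cfg.read_end_bp``
    bases of every read are ignored.  For unstranded libraries the transcript
    strand comes from overlapping gene annotation; positions covered by genes
    on both strands (or none) are discarded and counted in the log.  Input
    must be coordinate-sorted.
    """
    buf: dict[tuple[str, str], list[tuple[np.ndarray, np.ndarray]]] = {}
    last: dict[str, int] = {}
    n_ambiguous = 0
    for read in reads:
        if read.mapq < cfg.min_mapq:
            continue
        start = int(read.rpos[0])
        if last.get(read.chrom, -1) > start:
            raise ValueError("alignment stream is not coordinate-sorted")
        last[read.chrom] = start
        keep = read.qual[read.qpos] >= cfg.min_base_phred
        if exclude_read_ends:
            keep &= ((read.qpos >= cfg.read_end_bp)
                     & (read.qpos < read.read_len - cfg.read_end_bp))
        qpos = read.qpos[keep]
        rpos = read.rpos[keep]
        bases = read.seq[qpos]
        strand = read.transcript_strand(protocol)
        if strand is not None:
            groups = [(strand, rpos, bases)]
        else:
            if annotation is None:
                raise ValueError("unstranded protocol requires annotation for strand")
            groups = []
            resolved = np.array([annotation.strand_at(read.chrom, int(p)) or "?"
                                 for p in rpos])
            n_ambiguous += int((resolved == "?").sum())
            for s in ("+", "-"):
                m = resolved == s
                if m.any():
                    groups.append((s, rpos[m], bases[m]))
        for s, rp, bs in groups:
            if s == "-":
                bs = _seq.complement(bs)
            ok = bs < 4
            buf.setdefault((read.chrom, s), []).append((rp[ok], bs[ok]))
    if n_ambiguous:
        log.info("discarded %d base calls with ambiguous transcript strand", n_ambiguous)
    out: dict[SiteKey, np.ndarray] = {}
    for (chrom, strand), chunks in buf.items():
        L = reference[chrom].size
        counts = np.zeros((4, L), dtype=np.int64)
        rp = np.concatenate([c[0] for c in chunks])
        bs = np.concatenate([c[1] for c in chunks])
        np.add.at(counts, (bs, rp), 1)
        covered = np.flatnonzero(counts.sum(axis=0) > 0)
        for pos0 in covered:
            out[(chrom, int(pos0), strand)] = counts[:, pos0].copy()
    return out


def _ref_base_on_strand(reference: Mapping[str, np.ndarray], chrom: str,
                        pos0: int, strand: str) -> int:
    b = int(reference[chrom][pos0])
    return int(_seq._COMP[b]) if strand == "-" else b


def calls_from_pileup(pile: dict[SiteKey, np.ndarray],
                      reference: Mapping[str, np.ndarray],
                      source: str = "denovo") -> dict[SiteKey, SiteCall]:
    """SiteCalls at every transcript-strand adenosine with any G support."""
    calls = {}
    for (chrom, pos0, strand), counts in pile.items():
        if _ref_base_on_strand(reference, chrom, pos0, strand) != _seq.A:
            continue
        if counts[_seq.G] == 0 and source == "denovo":
            continue
        calls[(chrom, pos0, strand)] = SiteCall(chrom, pos0, strand, "A",
                                                counts.copy(), source=source)
    return calls


# ---------------------------------------------------------------------------
# calling


def call_denovo_sites(calls: Mapping[SiteKey, SiteCall], cfg: FilterConfig,
                      annotation: AnnotationSet | None = None) -> dict[SiteKey, SiteCall]:
    """De novo candidates: coverage >= 10, edited >= 3, ratio >= 1%.

    Sites adjacent to splice junctions (within ``cfg.splice_adj_bp``) are
    excluded; read-end-adjacent mismatches were already dropped at pileup.
    """
    out = {}
    for key, call in calls.items():
        if call.coverage < cfg.denovo_min_coverage:
            continue
        if call.edited < cfg.denovo_min_edited:
            continue
        if call.level < cfg.denovo_min_ratio:
            continue
        if annotation is not None and annotation.near_junction(
                call.chrom, call.pos0, cfg.splice_adj_bp):
            continue
        out[key] = call
    return out


def call_supervised_sites(calls: Mapping[SiteKey, SiteCall],
                          catalog: set[SiteKey], cfg: FilterConfig) -> dict[SiteKey, SiteCall]:
    """Known-site queries: coverage >= 5 and edited reads >= 3."""
    out = {}
    for key in catalog:
        call = calls.get(key)
        if call is None:
            continue
        if call.coverage < cfg.supervised_min_coverage:
            continue
        if call.edited < cfg.supervised_min_edited:
            continue
        c = SiteCall(call.chrom, call.pos0, call.strand, call.ref_base,
                     call.counts, source="supervised",
                     caller_support=call.caller_support)
        out[key] = c
    return out


def intersect_call_sets(denovo_sets: list[Mapping[SiteKey, SiteCall]],
                        supervised: Mapping[SiteKey, SiteCall] | None = None,
                        ) -> dict[SiteKey, SiteCall]:
    """Consensus: de novo sites must be called by >= 2 callers; supervised bypass.

    With fewer than two de novo sets the consensus requirement is skipped
    (logged) and the single set is passed through.
    """
    out: dict[SiteKey, SiteCall] = {}
    if len(denovo_sets) < 2:
        log.warning("fewer than two de novo call sets; consensus rule skipped")
        for s in denovo_sets:
            out.update({k: v for k, v in s.items()})
    else:
        support: dict[SiteKey, int] = {}
        for s in denovo_sets:
            for k in s:
                support[k] = support.get(k, 0) + 1
        for k, n in support.items():
            if n >= 2:
                call = next(s[k] for s in denovo_sets if k in s)
                call.caller_support = n
                out[k] = call
    if supervised:
        for k, v in supervised.items():
            if k not in out:
                out[k] = v
    return out


# ---------------------------------------------------------------------------
# filter ledger (i)-(iv)


def is_multiallelic(call: SiteCall, min_alt_reads: int = 2) -> bool:
    """>= 2 distinct non-reference alleles each supported by >= 2 reads."""
    alts = [b for b in range(4) if b != _seq.A and call.counts[b] >= min_alt_reads]
    return len(alts) >= 2


def in_homopolymer(reference: Mapping[str, np.ndarray], chrom: str, pos0: int,
                   run: int) -> bool:
    """Site sits inside a reference run of >= ``run`` identical bases."""
    ref = reference[chrom]
    base = ref[pos0]
    left = pos0
    while left > 0 and ref[left - 1] == base:
        left -= 1
    right = pos0
    while right + 1 < ref.size and ref[right + 1] == base:
        right += 1
    return (right - left + 1) >= run


def apply_site_filters(candidates: Mapping[SiteKey, SiteCall],
                       annotation: AnnotationSet,
                       reference: Mapping[str, np.ndarray],
                       cfg: FilterConfig,
                       sample_variant_positions: set[tuple[str, int]] | None = None,
                       ) -> dict[SiteKey, EditingSite]:
    """Removal filters (independent, hence order-free) plus annotation.

    Removes multi-allelic events, homopolymer/blacklist positions, masked
    population variants and positions carrying a het / hom-alt genomic call in
    the matched sample; survivors get genic region, repeat class and known
    flag.
    """
    sample_variant_positions = sample_variant_positions or set()
    out = {}
    for key, call in candidates.items():
        chrom, pos0, strand = key
        if is_multiallelic(call):
            continue
        if in_homopolymer(reference, chrom, pos0, cfg.homopolymer_run):
            continue
        if annotation.in_blacklist(chrom, pos0):
            continue
        if annotation.is_masked_variant(chrom, pos0, cfg.maf_mask):
            continue
        if (chrom, pos0) in sample_variant_positions:
            continue
        out[key] = EditingSite(
            call,
            region=annotation.genic_region(chrom, pos0, strand),
            repeat_class=annotation.repeat_class(chrom, pos0),
            known=key in annotation.known_sites,
        )
    return out


# ---------------------------------------------------------------------------
# temporal detection groups


def classify_detection_groups(per_sample_sites: Mapping[str, set[SiteKey]],
                              cohort: pd.DataFrame, cfg: FilterConfig,
                              within_epoch_rate: bool = True,
                              ) -> tuple[dict[SiteKey, str], pd.DataFrame]:
    """Group sites by temporal detection pattern and build the Jaccard matrix.

    prenatal-predominant: detected only in prenatal samples, at a detection
    rate >= ``cfg.detection_rate`` within the prenatal epoch (the rate applies
    globally instead when ``within_epoch_rate`` is False); symmetrically for
    postnatal.  common: detection rate >= threshold across all samples.  The
    Jaccard matrix J(i,j) = |Si n Sj| / |Si u Sj| is ordered by age.
    """
    pre = [s for s in per_sample_sites if cohort.loc[s, "epoch"] == "prenatal"]
    post = [s for s in per_sample_sites if cohort.loc[s, "epoch"] == "postnatal"]
    if not pre or not post:
        raise ValueError("both epochs need at least one sample")
    all_samples = pre + post
    universe: set[SiteKey] = set().union(*per_sample_sites.values())

    groups: dict[SiteKey, str] = {}
    for site in universe:
        n_pre = sum(site in per_sample_sites[s] for s in pre)
        n_post = sum(site in per_sample_sites[s] for s in post)
        rate_all = (n_pre + n_post) / len(all_samples)
        rate_pre = n_pre / len(pre)
        rate_post = n_post / len(post)
        if rate_all >= cfg.detection_rate:
            groups[site] = "common"
        elif n_post == 0 and (rate_pre if within_epoch_rate else rate_all) >= cfg.detection_rate:
            groups[site] = "prenatal-predominant"
        elif n_pre == 0 and (rate_post if within_epoch_rate else rate_all) >= cfg.detection_rate:
            groups[site] = "postnatal-predominant"
        else:
            groups[site] = "unclassified"

    ordered = cohort.loc[list(per_sample_sites)].sort_values("age_days").index
    n = len(ordered)
    jac = np.ones((n, n))
    sets = [per_sample_sites[s] for s in ordered]
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            jac[i, j] = jac[j, i] = (len(sets[i] & sets[j]) / union) if union else 0.0
    return groups, pd.DataFrame(jac, index=ordered, columns=ordered)


# ---------------------------------------------------------------------------
# matrix construction


def build_editing_matrix(levels: pd.DataFrame, cfg: FilterConfig,
                         seed: int = 0) -> EditingMatrix:
    """Detection-rate/mean-level row filters, sample missingness filter, and
    deterministic k-donor imputation.

    Samples with more than ``cfg.max_sample_missing`` missing cells are
    removed first; rows are kept when observed in >= ``cfg.detection_rate`` of
    the retained samples with mean level >= ``cfg.min_mean_level``.  Each
    remaining gap is filled with an observed value for that site donated by
    one of the ``cfg.impute_k`` samples closest (mean squared difference over
    co-observed sites) to the recipient, the donor drawn by seeded choice —
    a donor-matching analogue of predictive mean matching.
    """
    vals = levels.to_numpy(dtype=float)
    miss_frac = np.isnan(vals).mean(axis=0)
    keep_samples = miss_frac <= cfg.max_sample_missing
    dropped = [s for s, k in zip(levels.columns, keep_samples) if not k]
    if not keep_samples.any():
        raise ValueError("all samples exceed the missingness threshold")
    levels = levels.loc[:, keep_samples]
    vals = levels.to_numpy(dtype=float)

    observed = ~np.isnan(vals)
    det = observed.mean(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(np.where(observed, vals, np.nan), axis=1)
    keep_rows = (det >= cfg.detection_rate) & (means >= cfg.min_mean_level)
    levels = levels.loc[keep_rows]
    vals = levels.to_numpy(dtype=float)
    observed = ~np.isnan(vals)

    n_sites, n_samp = vals.shape
    if n_sites and np.isnan(vals).any():
        # nan-aware pairwise distances: mean squared difference over co-observed sites
        dist = np.zeros((n_samp, n_samp))
        for a in range(n_samp):
            for b in range(a + 1, n_samp):
                both = observed[:, a] & observed[:, b]
                if both.any():
                    d = float(np.mean((vals[both, a] - vals[both, b]) ** 2))
                else:
                    d = np.inf
                dist[a, b] = dist[b, a] = d
        rng = np.random.default_rng(seed)
        filled = vals.copy()
        for i in range(n_sites):
            for j in np.flatnonzero(~observed[i]):
                donors = np.flatnonzero(observed[i])
                if donors.size == 0:
                    raise ValueError(f"site {levels.index[i]} observed in no retained sample")
                order = donors[np.argsort(dist[j, donors], kind="stable")]
                pool = order[:cfg.impute_k]
                filled[i, j] = vals[i, int(rng.choice(pool))]
        vals = filled

    return EditingMatrix(
        levels=pd.DataFrame(vals, index=levels.index, columns=levels.columns),
        observed=pd.DataFrame(observed, index=levels.index, columns=levels.columns),
        dropped_samples=dropped,
    )


# ---------------------------------------------------------------------------
# sequence context


def sequence_context_profile(site_keys: Iterable[SiteKey],
                             reference: Mapping[str, np.ndarray],
                             offsets: tuple[int, ...] = (-1, 1)) -> pd.DataFrame:
    """Base frequencies at the given transcript-strand offsets around sites.

    The editing motif shows guanosine depleted at -1 and enriched at +1
    relative to the target adenosine.  Sites whose offset falls off the
    contig are skipped for that offset.
    """
    counts = {off: np.zeros(4, dtype=np.int64) for off in offsets}
    skipped = 0
    for chrom, pos0, strand in site_keys:
        ref = reference[chrom]
        for off in offsets:
            gpos = pos0 + off if strand == "+" else pos0 - off
            if not 0 <= gpos < ref.size:
                skipped += 1
                continue
            b = int(ref[gpos])
            if strand == "-":
                b = int(_seq._COMP[b])
            if b < 4:
                counts[off][b] += 1
    if skipped:
        log.info("sequence context: %d offsets beyond contig boundary skipped", skipped)
    freq = {}
    for off, c in counts.items():
        total = c.sum()
        freq[off] = c / total if total else np.zeros(4)
    return pd.DataFrame(freq, index=list("ACGT")).T
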