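"""Synthetic study generator: reference, cohort, planted truth, genotypes, reads.

The generator emulates the statistical structure of a developmental brain
RNA-editing study so that every downstream stage can be scored against planted
ground truth:

* an Alu-repeat-bearing reference with gene models (CDS / UTR / intron) and
  inverted repeat copies inside introns and 3'UTRs;
* a 12-period prenatal/postnatal cohort (periods 1-7 prenatal by default)
  with rising neuronal fraction and ADAR2, falling ADAR1;
* per-site logistic age trajectories of editing level (postnatal-biased,
  prenatal-biased, or flat null sites);
* optional cis-acting variants with additive, epoch-restricted effects on the
  logit editing level, drawn under Hardy-Weinberg equilibrium;
* binomially sampled edited reads at Poisson coverage with uniform sequencing
  error, plus densely hyper-edited reads emitted into the unaligned pool.

Everything is deterministic under a fixed seed (one integer RNG stream per
component, spawned from the master seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import _seq, seqio
from .intervals import AnnotationSet, GeneModel, GenomicInterval

BIRTH_AGE_DAYS = 266.0           # conception -> birth
MIN_AGE_DAYS = 50.0
MAX_AGE_DAYS = 7300.0            # ~20 years
N_PERIODS = 12

# fixed Alu-like consensus (~300 bp incl. poly-A tail) and a shorter non-Alu
# repeat consensus; generated once from a frozen stream so every run agrees
_consensus_rng = np.random.default_rng(987654321)
ALU_CONSENSUS = _seq.decode(
    _consensus_rng.choice(4, size=280, p=[0.30, 0.24, 0.24, 0.22]).astype(np.uint8)
) + "A" * 20
NONALU_CONSENSUS = _seq.decode(
    _consensus_rng.choice(4, size=150, p=[0.25, 0.25, 0.25, 0.25]).astype(np.uint8))
del _consensus_rng


def period_boundaries(prenatal_max_period: int = 7) -> np.ndarray:
    """Age (days post-conception) edges of the 12 developmental periods.

    Geometric spacing from 50 days to 20 years with birth placed between
    periods ``prenatal_max_period`` and ``prenatal_max_period + 1``.
    """
    pre = np.geomspace(MIN_AGE_DAYS, BIRTH_AGE_DAYS, prenatal_max_period + 1)
    post = np.geomspace(BIRTH_AGE_DAYS, MAX_AGE_DAYS, N_PERIODS - prenatal_max_period + 1)
    return np.concatenate([pre, post[1:]])


# ---------------------------------------------------------------------------
# reference


@dataclass
class SyntheticReference:
    chrom: str
    seq: str
    annotation: AnnotationSet
    mirnas: dict[str, str]

    @property
    def codes(self) -> np.ndarray:
        return _seq.encode(self.seq)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        seqio.write_fasta(out / "reference.fa", [(self.chrom, self.seq)])
        seqio.write_fasta(out / "mirnas.fa", sorted(self.mirnas.items()))
        rows = []
        for gene in self.annotation.genes.values():
            for iv, label in gene.parts:
                rows.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gene.gene_id}:{label}\t0\t{gene.strand}")
        (out / "genes.bed").write_text("\n".join(rows) + "\n")
        rows = [f"{iv.chrom}\t{iv.start}\t{iv.end}\t{fam.replace(' ', '_')}\t0\t{iv.strand}"
                for iv, fam in self.annotation.repeats]
        (out / "repeats.bed").write_text("\n".join(rows) + "\n" if rows else "")


def simulate_reference(length: int = 100_000, n_repeats: int = 30, n_genes: int = 8,
                       seed: int = 0, n_mirnas: int = 10,
                       divergence: float = 0.05, inverted_frac: float = 0.4,
                       n_nonalu: int = 4) -> SyntheticReference:
    """Build a gene- and repeat-bearing reference chromosome.

    Repeat copies diverge from the consensus by ``divergence`` substitutions
    per base and a fraction are inverted relative to the host gene, the
    configuration that forms the double-stranded editing substrate.
    """
    if length < 10_000:
        raise ValueError("reference length must be at least 10 kb")
    rng = np.random.default_rng(seed)
    seq = rng.choice(4, size=length, p=[0.28, 0.22, 0.22, 0.28]).astype(np.uint8)

    # -- gene models: evenly spaced slots with 5'UTR / CDS exons / introns / 3'UTR
    min_gene = 6_000
    slot = length // n_genes
    if slot < min_gene + 500:
        raise ValueError(f"{n_genes} genes do not fit in {length} bp")
    genes: dict[str, GeneModel] = {}
    chrom = "chr1"
    intron_pool: list[tuple[GenomicInterval, str]] = []  # (interval, gene strand)
    utr3_pool: list[tuple[GenomicInterval, str]] = []
    for g in range(n_genes):
        g_start = g * slot + 200
        g_len = slot - 400
        strand = "+" if g % 2 == 0 else "-"
        utr5, cds_len, n_ex = 150, 300, 3
        intron_total = g_len - utr5 - n_ex * cds_len - 1_200
        intron_len = intron_total // (n_ex - 1)
        utr3 = g_len - utr5 - n_ex * cds_len - (n_ex - 1) * intron_len
        # transcript-order segments, laid out left->right then mirrored for '-'
        segs = [("5'UTR", utr5)]
        for e in range(n_ex):
            segs.append(("CDS", cds_len))
            if e < n_ex - 1:
                segs.append(("intron", intron_len))
        segs.append(("3'UTR", utr3))
        if strand == "-":
            segs = segs[::-1]
        gene = GeneModel(f"gene{g + 1}", strand)
        pos = g_start
        for label, seg_len in segs:
            iv = GenomicInterval(chrom, pos, pos + seg_len, strand)
            gene.parts.append((iv, label))
            if label == "intron":
                intron_pool.append((iv, strand))
            elif label == "3'UTR":
                utr3_pool.append((iv, strand))
            pos += seg_len
        genes[gene.gene_id] = gene

    # -- repeat placement inside introns and 3'UTRs
    occupied: list[tuple[int, int]] = []

    def _plant(consensus: str, n: int, family: str) -> list[tuple[GenomicInterval, str]]:
        placed: list[tuple[GenomicInterval, str]] = []
        pool = intron_pool + utr3_pool
        rep = _seq.encode(consensus)
        attempts = 0
        while len(placed) < n:
            attempts += 1
            if attempts > 200 * n:
                raise ValueError("requested repeats exceed genome capacity")
            iv, gstrand = pool[rng.integers(len(pool))]
            if len(iv) < len(rep) + 20:
                continue
            start = int(rng.integers(iv.start, iv.end - len(rep)))
            if any(s < start + len(rep) and start < e for s, e in occupied):
                continue
            copy = rep.copy()
            nmut = rng.binomial(len(copy), divergence)
            if nmut:
                at = rng.choice(len(copy), size=nmut, replace=False)
                copy[at] = (copy[at] + rng.integers(1, 4, size=nmut)) % 4
            inverted = rng.random() < inverted_frac
            rep_strand = gstrand
            if inverted:
                copy = _seq.revcomp(copy)
                rep_strand = "-" if gstrand == "+" else "+"
            seq[start:start + len(copy)] = copy
            occupied.append((start, start + len(copy)))
            placed.append((GenomicInterval(chrom, start, start + len(copy), rep_strand), family))
        return placed

    repeats = _plant(ALU_CONSENSUS, n_repeats, "Alu")
    repeats += _plant(NONALU_CONSENSUS, n_nonalu, "repetitive non-Alu")

    mirnas = {}
    for m in range(n_mirnas):
        mlen = int(rng.integers(21, 23))
        mirnas[f"mir-{m + 1}"] = _seq.decode(rng.integers(0, 4, size=mlen).astype(np.uint8))

    annotation = AnnotationSet(genes=genes, repeats=repeats)
    return SyntheticReference(chrom, _seq.decode(seq), annotation, mirnas)


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(n_prenatal: int = 116, n_postnatal: int = 60, seed: int = 0,
                    prenatal_max_period: int = 7) -> pd.DataFrame:
    """Sample metadata table: ages, periods, covariates, enzyme expression.

    Ages are log-uniform within their period; neuronal fraction rises as a
    logistic of log-age; ADAR2 rises and ADAR1 falls with log-age, with
    lognormal-ish noise, matching the developmental biases the analysis
    expects to adjust for.
    """
    if n_prenatal < 2 or n_postnatal < 2:
        raise ValueError("need at least two samples per epoch")
    rng = np.random.default_rng(seed)
    edges = period_boundaries(prenatal_max_period)
    rows = []
    for epoch, n, periods in (
        ("prenatal", n_prenatal, range(1, prenatal_max_period + 1)),
        ("postnatal", n_postnatal, range(prenatal_max_period + 1, N_PERIODS + 1)),
    ):
        periods = list(periods)
        assignment = [periods[i % len(periods)] for i in range(n)]
        for k, period in enumerate(assignment):
            lo, hi = edges[period - 1], edges[period]
            age = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            rows.append((f"s{epoch[:3]}{k + 1:03d}", age, period, epoch))
    df = pd.DataFrame(rows, columns=["sample_id", "age_days", "period", "epoch"])
    la = np.log(df["age_days"].to_numpy())
    la0 = np.log(BIRTH_AGE_DAYS)
    n_tot = len(df)
    df["sex"] = rng.choice(["F", "M"], size=n_tot)
    for i in range(1, 6):
        df[f"ancestry{i}"] = rng.normal(0.0, 1.0, size=n_tot)
    df["adar1"] = 7.0 - 0.9 * expit(1.2 * (la - la0)) * 2 + rng.normal(0, 0.25, n_tot)
    df["adar2"] = 4.0 + 2.2 * expit(1.2 * (la - la0)) + rng.normal(0, 0.25, n_tot)
    nf = 0.15 + 0.72 * expit(1.5 * (la - la0)) + rng.normal(0, 0.03, n_tot)
    df["neuronal_fraction"] = np.clip(nf, 0.01, 0.99)
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# planted truth


@dataclass
class TruthTable:
    """Planted ground truth: per-site trajectories, edQTL effects, hyper regions."""

    sites: pd.DataFrame          # indexed by site_id
    hyper_regions: pd.DataFrame  # chrom,start,end,strand,p_edit
    variants: pd.DataFrame = field(default_factory=pd.DataFrame)  # edQTL variants

    def level(self, site_row: pd.Series, age_days: float, dosage: float = 0.0,
              epoch: str | None = None) -> float:
        """True editing level of one site at an age (and optional genotype)."""
        base, asym = site_row["baseline"], site_row["asymptote"]
        slope, mid = site_row["slope"], site_row["midpoint_days"]
        lev = base + (asym - base) * expit(slope * (math.log(age_days) - math.log(mid)))
        beta = site_row.get("edqtl_beta", 0.0)
        if beta and dosage:
            active = site_row["edqtl_epoch"]
            if active == "both" or active == epoch:
                lev = float(expit(logit(np.clip(lev, 1e-4, 1 - 1e-4)) + beta * dosage))
        return float(np.clip(lev, 0.0, 1.0))

    def expected_levels(self, cohort: pd.DataFrame,
                        dosages: pd.DataFrame | None = None) -> pd.DataFrame:
        """Sites x samples matrix of true levels for a cohort."""
        out = np.zeros((len(self.sites), len(cohort)))
        for i, (sid, row) in enumerate(self.sites.iterrows()):
            vid = row.get("edqtl_variant")
            for j, (samp, meta) in enumerate(cohort.iterrows()):
                dose = 0.0
                if isinstance(vid, str) and dosages is not None:
                    dose = float(dosages.loc[vid, samp])
                out[i, j] = self.level(row, meta["age_days"], dose, meta["epoch"])
        return pd.DataFrame(out, index=self.sites.index, columns=cohort.index)


def _transcript_a_positions(ref_codes: np.ndarray, iv: GenomicInterval, strand: str) -> np.ndarray:
    """Genomic positions that read A on the transcript strand within iv."""
    window = ref_codes[iv.start:iv.end]
    want = _seq.A if strand == "+" else _seq.T
    return iv.start + np.flatnonzero(window == want)


def simulate_truth(reference: SyntheticReference, n_sites: int = 300,
                   fraction_biased: float = 0.4, postnatal_share: float = 0.7,
                   edqtl_spec: dict | None = None, hyper_spec: dict | None = None,
                   known_fraction: float = 0.7, seed: int = 0) -> TruthTable:
    """Plant selective sites, optional edQTL effects and hyper regions.

    Sites land preferentially in 3'UTRs, introns and Alu repeats.  Biased
    sites follow logistic trajectories with midpoints near birth; the rest
    are flat nulls.  ``edqtl_spec`` keys: n_loci, maf, beta, epochs (list of
    {prenatal, postnatal, both}).  ``hyper_spec`` keys: n_regions, p_edit.
    """
    rng = np.random.default_rng(seed)
    ann = reference.annotation
    codes = reference.codes

    region_w = {"3'UTR": 3.0, "intron": 2.0, "CDS": 0.3, "5'UTR": 0.5, "ncRNA": 1.0}
    cand_pos, cand_strand, cand_w = [], [], []
    for gene in ann.genes.values():
        for iv, label in gene.parts:
            pos = _transcript_a_positions(codes, iv, gene.strand)
            if pos.size == 0:
                continue
            w = np.full(pos.size, region_w[label])
            rc = np.array([ann.repeat_class(iv.chrom, int(p)) for p in pos])
            w[rc == "Alu"] *= 3.0
            cand_pos.append(pos)
            cand_strand.extend([gene.strand] * pos.size)
            cand_w.append(w)
    pos_all = np.concatenate(cand_pos)
    strand_all = np.array(cand_strand)
    w_all = np.concatenate(cand_w)
    # dedupe genomic positions (overlapping annotations)
    _, first = np.unique(pos_all, return_index=True)
    pos_all, strand_all, w_all = pos_all[first], strand_all[first], w_all[first]
    if n_sites > pos_all.size:
        raise ValueError(f"only {pos_all.size} adenosines available for {n_sites} sites")
    pick = rng.choice(pos_all.size, size=n_sites, replace=False,
                      p=w_all / w_all.sum())
    pick = pick[np.argsort(pos_all[pick])]

    n_biased = int(round(fraction_biased * n_sites))
    n_post = int(round(postnatal_share * n_biased))
    classes = (["postnatal-biased"] * n_post
               + ["prenatal-biased"] * (n_biased - n_post)
               + ["null"] * (n_sites - n_biased))
    rng.shuffle(classes)

    chrom = reference.chrom
    rows = []
    for idx, cls in zip(pick, classes):
        p0, strand = int(pos_all[idx]), str(strand_all[idx])
        mid = float(BIRTH_AGE_DAYS * np.exp(rng.normal(0, 0.15)))
        slope = float(rng.uniform(2.0, 4.0))
        if cls == "postnatal-biased":
            base = float(rng.uniform(0.03, 0.15))
            asym = base + float(rng.uniform(0.15, 0.35))
        elif cls == "prenatal-biased":
            asym = float(rng.uniform(0.03, 0.15))
            base = asym + float(rng.uniform(0.15, 0.35))
        else:
            base = asym = float(rng.uniform(0.05, 0.45))
            slope = 0.0
        rows.append({
            "site_id": seqio.site_id(chrom, p0, strand),
            "chrom": chrom, "pos0": p0, "strand": strand,
            "region": ann.genic_region(chrom, p0, strand),
            "repeat_class": ann.repeat_class(chrom, p0),
            "known": bool(rng.random() < known_fraction),
            "traj_class": cls, "baseline": base, "asymptote": asym,
            "midpoint_days": mid, "slope": slope,
            "edqtl_variant": None, "edqtl_pos0": -1, "edqtl_maf": np.nan,
            "edqtl_beta": 0.0, "edqtl_epoch": "",
        })
    sites = pd.DataFrame(rows).set_index("site_id")

    variants = pd.DataFrame()
    if edqtl_spec:
        n_loci = edqtl_spec.get("n_loci", 20)
        maf = edqtl_spec.get("maf", 0.3)
        beta = edqtl_spec.get("beta", 0.5)
        epochs = edqtl_spec.get("epochs", ["both"])
        if not 0.0 < maf <= 0.5:
            raise ValueError("edQTL MAF must lie in (0, 0.5]")
        loci = rng.choice(n_sites, size=min(n_loci, n_sites), replace=False)
        vrows = []
        L = len(reference.seq)
        window = edqtl_spec.get("cis_offset", 50_000)
        for k, si in enumerate(sorted(loci)):
            srow = sites.iloc[si]
            vpos = int(np.clip(srow["pos0"] + rng.integers(-window, window + 1), 0, L - 1))
            vid = f"var{k + 1}"
            epoch = epochs[k % len(epochs)]
            sites.iloc[si, sites.columns.get_loc("edqtl_variant")] = vid
            sites.iloc[si, sites.columns.get_loc("edqtl_pos0")] = vpos
            sites.iloc[si, sites.columns.get_loc("edqtl_maf")] = maf
            sites.iloc[si, sites.columns.get_loc("edqtl_beta")] = beta
            sites.iloc[si, sites.columns.get_loc("edqtl_epoch")] = epoch
            vrows.append({"variant_id": vid, "chrom": chrom, "pos0": vpos,
                          "maf": maf, "site_id": srow.name})
        variants = pd.DataFrame(vrows).set_index("variant_id")

    hyper_rows = []
    if hyper_spec:
        n_regions = hyper_spec.get("n_regions", 5)
        p_edit = hyper_spec.get("p_edit", 0.8)
        alu = [(iv, fam) for iv, fam in ann.repeats if fam == "Alu"]
        if n_regions > len(alu):
            raise ValueError("more hyper regions requested than Alu repeats")
        for ri in rng.choice(len(alu), size=n_regions, replace=False):
            iv, _ = alu[int(ri)]
            hyper_rows.append({"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                               "strand": iv.strand, "p_edit": p_edit})
    hyper = pd.DataFrame(hyper_rows, columns=["chrom", "start", "end", "strand", "p_edit"])

    # planted known sites enter the catalog
    for sid, row in sites[sites["known"]].iterrows():
        ann.known_sites.add((row["chrom"], int(row["pos0"]), row["strand"]))
    return TruthTable(sites=sites, hyper_regions=hyper, variants=variants)


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(truth: TruthTable, cohort: pd.DataFrame, seed: int = 0,
                       path: str | Path | None = None,
                       contig_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Hardy-Weinberg genotypes for every planted edQTL variant.

    Returns a variants x samples dosage DataFrame; writes a VCF when ``path``
    is given.
    """
    rng = np.random.default_rng(seed)
    n = len(cohort)
    rows = []
    for vid, vrow in truth.variants.iterrows():
        maf = float(vrow["maf"])
        if not 0.0 < maf <= 0.5:
            raise ValueError("MAF must lie in (0, 0.5]")
        rows.append(rng.binomial(2, maf, size=n))
    dosages = pd.DataFrame(rows, index=truth.variants.index, columns=cohort.index,
                           dtype=float)
    if path is not None:
        recs = []
        order = truth.variants.sort_values("pos0").index
        for vid in order:
            vrow = truth.variants.loc[vid]
            recs.append((vrow["chrom"], int(vrow["pos0"]), vid, "A", "G",
                         dosages.loc[vid].to_numpy().astype(int)))
        seqio.write_vcf(path, list(cohort.index), recs, contig_lengths)
    return dosages


# ---------------------------------------------------------------------------
# reads


@dataclass
class ReadSimResult:
    sam_paths: dict[str, Path]
    fastq_paths: dict[str, Path]
    hyper_read_truth: pd.DataFrame  # read_id, sample_id, chrom, start, strand, n_edits


def _positions_with_levels(reference: SyntheticReference, truth: TruthTable,
                           meta: pd.Series, dosages: pd.DataFrame | None,
                           alu_edit_prob: float | None,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Per-position edit probability and target base for one sample."""
    L = len(reference.seq)
    p_edit = np.zeros(L, dtype=np.float64)
    to_base = np.zeros(L, dtype=np.uint8)
    if alu_edit_prob:
        codes = reference.codes
        for iv, fam in reference.annotation.repeats:
            if fam != "Alu" or iv.strand not in "+-":
                continue
            pos = _transcript_a_positions(codes, iv, iv.strand)
            p_edit[pos] = alu_edit_prob
            to_base[pos] = _seq.G if iv.strand == "+" else _seq.C
    for sid, row in truth.sites.iterrows():
        dose = 0.0
        vid = row.get("edqtl_variant")
        if isinstance(vid, str) and dosages is not None:
            dose = float(dosages.loc[vid, meta.name])
        lev = truth.level(row, meta["age_days"], dose, meta["epoch"])
        p0 = int(row["pos0"])
        p_edit[p0] = lev
        to_base[p0] = _seq.G if row["strand"] == "+" else _seq.C
    return p_edit, to_base


def simulate_reads(reference: SyntheticReference, truth: TruthTable,
                   cohort: pd.DataFrame, out_dir: str | Path,
                   coverage: float = 30.0, read_len: int = 100,
                   error: float = 0.002, protocol: str = "forward",
                   seed: int = 0, dosages: pd.DataFrame | None = None,
                   alu_edit_prob: float | Mapping[str, float] | None = None,
                   hyper_coverage: float = 4.0, base_qual: int = 37) -> ReadSimResult:
    """Per-sample SAM (selectively edited reads) and FASTQ (hyper reads).

    Selectively edited reads carry G at a planted site with the site's true
    level for that sample; hyper-region reads edit every transcript-strand
    adenosine independently at the region's ``p_edit`` and appear only in the
    unaligned FASTQ pool.  Sequencing errors are uniform at rate ``error``.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0.0 <= error <= 0.05:
        raise ValueError("error rate must lie in [0, 0.05]")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    codes = reference.codes
    L = codes.size
    chrom = reference.chrom

    # transcript strand per position (for read orientation): 0='+',1='-',2=intergenic
    strand_code = np.full(L, 2, dtype=np.uint8)
    for gene in reference.annotation.genes.values():
        s = 0 if gene.strand == "+" else 1
        for iv, _ in gene.parts:
            strand_code[iv.start:iv.end] = s

    qual_str = seqio.phred_to_string(np.full(read_len, base_qual))
    sam_paths: dict[str, Path] = {}
    fastq_paths: dict[str, Path] = {}
    hyper_truth_rows = []

    for samp, meta in cohort.iterrows():
        alu_p = (alu_edit_prob.get(samp) if isinstance(alu_edit_prob, Mapping)
                 else alu_edit_prob)
        p_edit, to_base = _positions_with_levels(reference, truth, meta, dosages,
                                                 alu_p)
        n_reads = int(round(coverage * L / read_len))
        starts = np.sort(rng.integers(0, L - read_len + 1, size=n_reads))
        block = starts[:, None] + np.arange(read_len)[None, :]
        reads = codes[block].copy()
        # editing before sequencing error
        edit_mask = rng.random(block.shape) < p_edit[block]
        reads[edit_mask] = to_base[block][edit_mask]
        if error > 0:
            err = rng.random(block.shape) < error
            shift = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
            reads[err] = (reads[err] + shift) % 4
        mid_strand = strand_code[starts + read_len // 2]
        if protocol == "unstranded":
            is_rev = rng.random(n_reads) < 0.5
        else:
            is_rev = mid_strand == 1
            inter = mid_strand == 2
            is_rev = np.where(inter, rng.random(n_reads) < 0.5, is_rev)
            if protocol == "reverse":
                is_rev = ~is_rev
        sam_path = out / f"{samp}.sam"
        seqio.write_sam(
            sam_path, {chrom: L},
            ((f"{samp}_r{i}", chrom, int(starts[i]), bool(is_rev[i]),
              _seq.decode(reads[i]), qual_str) for i in range(n_reads)))
        sam_paths[samp] = sam_path

        # hyper reads -> FASTQ only
        fq_records = []
        for hi, hrow in truth.hyper_regions.iterrows():
            span = int(hrow["end"] - hrow["start"])
            n_h = rng.poisson(hyper_coverage * span / read_len)
            for k in range(n_h):
                lo = max(0, int(hrow["start"]) - read_len // 2)
                hi_start = min(L - read_len, int(hrow["end"]) - read_len // 2)
                if hi_start <= lo:
                    continue
                start = int(rng.integers(lo, hi_start + 1))
                r = codes[start:start + read_len].copy()
                want = _seq.A if hrow["strand"] == "+" else _seq.T
                to = _seq.G if hrow["strand"] == "+" else _seq.C
                inreg = np.zeros(read_len, dtype=bool)
                a = max(int(hrow["start"]) - start, 0)
                b = min(int(hrow["end"]) - start, read_len)
                inreg[a:b] = True
                editable = (r == want) & inreg
                hits = editable & (rng.random(read_len) < hrow["p_edit"])
                r[hits] = to
                if error > 0:
                    err = rng.random(read_len) < error
                    r[err] = (r[err] + rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)) % 4
                emit = r if hrow["strand"] == "+" else _seq.revcomp(r)
                rid = f"{samp}_h{hi}_{k}"
                fq_records.append((rid, _seq.decode(emit), qual_str))
                hyper_truth_rows.append({"read_id": rid, "sample_id": samp,
                                         "chrom": chrom, "start": start,
                                         "strand": hrow["strand"],
                                         "n_edits": int(hits.sum())})
        fq_path = out / f"{samp}.unmapped.fastq"
        seqio.write_fastq(fq_path, fq_records)
        fastq_paths[samp] = fq_path

    hyper_truth = pd.DataFrame(
        hyper_truth_rows,
        columns=["read_id", "sample_id", "chrom", "start", "strand", "n_edits"])
    return ReadSimResult(sam_paths, fastq_paths, hyper_truth)


def planted_matrix_truth(n_postnatal_biased: int = 0, n_prenatal_biased: int = 0,
                         n_null: int = 0, delta: float = 0.15,
                         baseline_range: tuple[float, float] = (0.10, 0.35),
                         slope: float = 1000.0, seed: int = 0,
                         spacing: int = 2000,
                         edqtl_spec: dict | None = None) -> TruthTable:
    """Truth table for matrix-level simulations, without a reference genome.

    Biased sites follow a near-step trajectory at birth with an exact planted
    level difference ``delta`` between epochs; null sites are flat.
    ``edqtl_spec`` (keys n_loci, maf, beta, epochs) attaches cis variants to
    the first null sites, ``spacing``/2 bp away from each site.
    """
    rng = np.random.default_rng(seed)
    classes = (["postnatal-biased"] * n_postnatal_biased
               + ["prenatal-biased"] * n_prenatal_biased
               + ["null"] * n_null)
    rows = []
    for i, cls in enumerate(classes):
        pos0 = 1000 + i * spacing
        base = float(rng.uniform(*baseline_range))
        if cls == "postnatal-biased":
            asym = base + delta
        elif cls == "prenatal-biased":
            asym = base - delta
        else:
            asym = base
        rows.append({
            "site_id": seqio.site_id("chr1", pos0, "+"),
            "chrom": "chr1", "pos0": pos0, "strand": "+",
            "region": "3'UTR", "repeat_class": "Alu", "known": True,
            "traj_class": cls, "baseline": base, "asymptote": asym,
            "midpoint_days": BIRTH_AGE_DAYS, "slope": slope if cls != "null" else 0.0,
            "edqtl_variant": None, "edqtl_pos0": -1, "edqtl_maf": np.nan,
            "edqtl_beta": 0.0, "edqtl_epoch": "",
        })
    columns = ["site_id", "chrom", "pos0", "strand", "region", "repeat_class",
               "known", "traj_class", "baseline", "asymptote", "midpoint_days",
               "slope", "edqtl_variant", "edqtl_pos0", "edqtl_maf",
               "edqtl_beta", "edqtl_epoch"]
    sites = pd.DataFrame(rows, columns=columns).set_index("site_id")
    variants = pd.DataFrame()
    if edqtl_spec:
        n_loci = edqtl_spec["n_loci"]
        maf = edqtl_spec.get("maf", 0.3)
        beta = edqtl_spec.get("beta", 0.5)
        epochs = edqtl_spec.get("epochs", ["both"])
        null_idx = [i for i, c in enumerate(classes) if c == "null"]
        if n_loci > len(null_idx):
            raise ValueError("not enough null sites to host the requested loci")
        vrows = []
        for k, si in enumerate(null_idx[:n_loci]):
            srow = sites.iloc[si]
            vid = f"var{k + 1}"
            vpos = int(srow["pos0"]) + spacing // 2
            sites.iloc[si, sites.columns.get_loc("edqtl_variant")] = vid
            sites.iloc[si, sites.columns.get_loc("edqtl_pos0")] = vpos
            sites.iloc[si, sites.columns.get_loc("edqtl_maf")] = maf
            sites.iloc[si, sites.columns.get_loc("edqtl_beta")] = beta
            sites.iloc[si, sites.columns.get_loc("edqtl_epoch")] = epochs[k % len(epochs)]
            vrows.append({"variant_id": vid, "chrom": "chr1", "pos0": vpos,
                          "maf": maf, "site_id": srow.name})
        variants = pd.DataFrame(vrows).set_index("variant_id")
    hyper = pd.DataFrame(columns=["chrom", "start", "end", "strand", "p_edit"])
    return TruthTable(sites=sites, hyper_regions=hyper, variants=variants)


# ---------------------------------------------------------------------------
# matrix-level simulation (no reads)


def simulate_editing_matrix(truth: TruthTable, cohort: pd.DataFrame,
                            coverage: float = 30.0, seed: int = 0,
                            dosages: pd.DataFrame | None = None,
                            missing_rate: float = 0.0) -> pd.DataFrame:
    """Observed editing levels sampled directly: Binomial(depth, level) / depth.

    Depth is Poisson(``coverage``) per cell; zero-depth or dropped-out cells
    are missing.  This is the read-free route to a sites x samples matrix for
    the statistical stages.
    """
    rng = np.random.default_rng(seed)
    true_lv = truth.expected_levels(cohort, dosages).to_numpy()
    depth = rng.poisson(coverage, size=true_lv.shape)
    edited = rng.binomial(np.maximum(depth, 1), true_lv)
    with np.errstate(invalid="ignore", divide="ignore"):
        obs = np.where(depth > 0, edited / np.maximum(depth, 1), np.nan)
    if missing_rate > 0:
        drop = rng.random(true_lv.shape) < missing_rate
        obs = np.where(drop, np.nan, obs)
    return pd.DataFrame(obs, index=truth.sites.index, columns=cohort.index)
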