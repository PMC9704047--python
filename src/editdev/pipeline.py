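"""End-to-end study driver: simulate a synthetic cohort, run every stage.

``simulate_study`` writes a self-contained study directory (reference FASTA,
annotation BEDs, cohort/metadata TSV, genotype VCF, per-sample SAM and
unmapped FASTQ, truth tables); ``run_study`` reloads it from disk through the
package's own readers and executes site calling, detection grouping, matrix
construction, differential editing, AEI, hyper-editing, energetics and edQTL
mapping, writing result tables next to the inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _seq, aei, fold, hyper, qtl, seqio, sites, stats, synth
from .config import FilterConfig
from .intervals import load_annotations

# per-sample Alu-wide editing probability rises with log-age, emulating the
# developmental increase in global Alu editing the index reads out
ALU_EDIT_BASE = 0.01
ALU_EDIT_AMPLITUDE = 0.03
ALU_EDIT_SLOPE = 1.5

PRESETS: dict[str, dict] = {
    "small": dict(length=60_000, n_genes=6, n_repeats=20, n_prenatal=10,
                  n_postnatal=8, n_sites=80, coverage=30.0,
                  edqtl=dict(n_loci=6, maf=0.3, beta=0.8, epochs=["both"]),
                  hyper=dict(n_regions=3, p_edit=0.35),
                  n_permutations=200, fold_flank=400),
    "cohort": dict(length=120_000, n_genes=10, n_repeats=36, n_prenatal=30,
                   n_postnatal=20, n_sites=160, coverage=30.0,
                   edqtl=dict(n_loci=10, maf=0.3, beta=0.8, epochs=["both"]),
                   hyper=dict(n_regions=4, p_edit=0.35),
                   n_permutations=200, fold_flank=400),
    "edqtl": dict(length=120_000, n_genes=10, n_repeats=30, n_prenatal=116,
                  n_postnatal=60, n_sites=120, coverage=30.0,
                  edqtl=dict(n_loci=30, maf=0.3, beta=0.8,
                             epochs=["prenatal", "postnatal", "both"]),
                  hyper=dict(n_regions=3, p_edit=0.35),
                  n_permutations=1000, fold_flank=400),
    "hyper": dict(length=100_000, n_genes=8, n_repeats=30, n_prenatal=12,
                  n_postnatal=12, n_sites=80, coverage=30.0,
                  edqtl=None, hyper=dict(n_regions=8, p_edit=0.35),
                  n_permutations=200, fold_flank=1000),
}


def simulate_study(out_dir: str | Path, seed: int = 0, preset: str = "small",
                   **overrides) -> dict:
    """Write a complete synthetic study directory; returns the parameter set."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    params = dict(PRESETS[preset])
    params.update(overrides)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(seed)
    s_ref, s_cohort, s_truth, s_geno, s_reads = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in master.spawn(5)]

    ref = synth.simulate_reference(params["length"], params["n_repeats"],
                                   params["n_genes"], seed=s_ref)
    ref.write(out)
    cohort = synth.simulate_cohort(params["n_prenatal"], params["n_postnatal"],
                                   seed=s_cohort)
    cohort.to_csv(out / "cohort.tsv", sep="\t")
    truth = synth.simulate_truth(ref, n_sites=params["n_sites"],
                                 edqtl_spec=params["edqtl"],
                                 hyper_spec=params["hyper"], seed=s_truth)
    truth.sites.to_csv(out / "truth_sites.tsv", sep="\t")
    truth.hyper_regions.to_csv(out / "truth_hyper_regions.tsv", sep="\t", index=False)
    with open(out / "known_sites.tsv", "w") as fh:
        for chrom, pos0, strand in sorted(ref.annotation.known_sites):
            fh.write(f"{chrom}\t{pos0 + 1}\t{strand}\n")
    dosages = None
    if params["edqtl"]:
        dosages = synth.simulate_genotypes(truth, cohort, seed=s_geno,
                                           path=out / "genotypes.vcf",
                                           contig_lengths={ref.chrom: len(ref.seq)})
        truth.variants.to_csv(out / "truth_variants.tsv", sep="\t")
    from scipy.special import expit
    la0 = np.log(synth.BIRTH_AGE_DAYS)
    alu_rates = {s: float(ALU_EDIT_BASE + ALU_EDIT_AMPLITUDE
                          * expit(ALU_EDIT_SLOPE * (np.log(m["age_days"]) - la0)))
                 for s, m in cohort.iterrows()}
    sim = synth.simulate_reads(ref, truth, cohort, out / "reads",
                               coverage=params["coverage"], seed=s_reads,
                               dosages=dosages, alu_edit_prob=alu_rates)
    sim.hyper_read_truth.to_csv(out / "truth_hyper_reads.tsv", sep="\t", index=False)
    params["seed"] = seed
    params["preset"] = preset
    (out / "params.json").write_text(json.dumps(params, indent=2) + "\n")
    return params


@dataclass
class StudyResults:
    per_sample_sites: dict
    groups: dict
    jaccard: pd.DataFrame
    matrix: sites.EditingMatrix
    differential: stats.DifferentialEditingResults
    aei_table: pd.DataFrame
    aei_age_spearman: float
    hyper_site_table: pd.DataFrame
    hyper_signals: pd.DataFrame
    hyper_enrichment: pd.DataFrame
    context: pd.DataFrame
    duplex_table: pd.DataFrame
    tier_table: pd.DataFrame | None
    edqtl: qtl.CisEdQTLResults | None


def _load_study(study_dir: Path):
    ann = load_annotations(gene_models=study_dir / "genes.bed",
                           repeats=study_dir / "repeats.bed",
                           known_sites=study_dir / "known_sites.tsv")
    fasta = seqio.read_fasta(study_dir / "reference.fa")
    reference = {name: _seq.encode(s) for name, s in fasta.items()}
    cohort = pd.read_csv(study_dir / "cohort.tsv", sep="\t", index_col=0)
    mirnas = seqio.read_fasta(study_dir / "mirnas.fa")
    return ann, reference, cohort, mirnas


def call_sample_sites(sam_path: Path, reference, ann, cfg: FilterConfig,
                      protocol: str = "forward"):
    """Consensus site calling for one sample's alignments.

    Two de novo passes under perturbed base-quality cutoffs emulate the
    two-caller consensus; supervised calls query the known-site catalog.
    """
    pile = sites.pileup_counts(seqio.read_alignments(sam_path, protocol),
                               reference, cfg, protocol, ann)
    calls = sites.calls_from_pileup(pile, reference)
    denovo_a = sites.call_denovo_sites(calls, cfg, ann)
    cfg_b = FilterConfig(**{**cfg.__dict__, "min_base_phred": cfg.min_base_phred + 5})
    pile_b = sites.pileup_counts(seqio.read_alignments(sam_path, protocol),
                                 reference, cfg_b, protocol, ann)
    denovo_b = sites.call_denovo_sites(sites.calls_from_pileup(pile_b, reference),
                                       cfg_b, ann)
    all_calls = sites.calls_from_pileup(pile, reference, source="supervised")
    supervised = sites.call_supervised_sites(all_calls, ann.known_sites, cfg)
    consensus = sites.intersect_call_sets([denovo_a, denovo_b], supervised)
    return sites.apply_site_filters(consensus, ann, reference, cfg)


def run_study(study_dir: str | Path, cfg: FilterConfig | None = None,
              seed: int = 0, protocol: str = "forward") -> StudyResults:
    """Execute every analysis stage over a simulated study directory."""
    study_dir = Path(study_dir)
    cfg = cfg or FilterConfig()
    params = json.loads((study_dir / "params.json").read_text())
    ann, reference, cohort, mirnas = _load_study(study_dir)

    # -- per-sample site calling + AEI ---------------------------------------
    per_sample: dict[str, dict] = {}
    aei_rows = []
    read_len = 100
    mapped_bases: dict[str, int] = {}
    for samp in cohort.index:
        sam_path = study_dir / "reads" / f"{samp}.sam"
        per_sample[samp] = call_sample_sites(sam_path, reference, ann, cfg, protocol)
        res = aei.compute_aei(seqio.read_alignments(sam_path, protocol),
                              reference, ann, cfg, sample_id=samp)
        aei_rows.append((samp, res.numerator, res.denominator, res.index))
        n_reads = sum(1 for _ in open(sam_path)) - 2  # header lines
        mapped_bases[samp] = n_reads * read_len
    aei_table = pd.DataFrame(aei_rows, columns=["sample_id", "numerator",
                                                "denominator", "aei"]
                             ).set_index("sample_id")
    rho = sps.spearmanr(aei_table["aei"],
                        cohort.loc[aei_table.index, "age_days"]).statistic

    # -- detection groups + matrix -------------------------------------------
    detected = {s: set(d.keys()) for s, d in per_sample.items()}
    groups, jaccard = sites.classify_detection_groups(detected, cohort, cfg)
    common = sorted(k for k, g in groups.items() if g == "common")
    levels = pd.DataFrame(
        {samp: {seqio.site_id(*k): per_sample[samp][k].call.level
                for k in common if k in per_sample[samp]}
         for samp in cohort.index})
    levels = levels.reindex([seqio.site_id(*k) for k in common])
    matrix = sites.build_editing_matrix(levels, cfg, seed=seed)

    # -- differential editing -------------------------------------------------
    covs = [c for c in ("sex", "ancestry1", "ancestry2") if c in cohort.columns]
    diff = stats.DifferentialEditingModel.from_matrix(matrix, cohort, covs).fit(cfg.fdr)

    # -- sequence context ------------------------------------------------------
    context = sites.sequence_context_profile(common, reference)

    # -- hyper-editing ---------------------------------------------------------
    aligner = hyper.TransformedAligner(reference, cfg)
    site_rows = []
    signal_rows = []
    gene_counts: dict[str, dict[str, int]] = {}
    all_cluster_sites: dict[tuple, set] = {}
    for samp in cohort.index:
        fq = study_dir / "reads" / f"{samp}.unmapped.fastq"
        reads = hyper.detect_hyper_reads(seqio.read_fastq(fq), reference, cfg,
                                         aligner=aligner)
        clusters, site_set = hyper.merge_hyper_clusters(reads, ann, cfg)
        sig = hyper.normalized_hyper_signal(len(site_set), mapped_bases[samp], samp)
        signal_rows.append((samp, sig.n_sites, sig.mapped_bases, sig.signal))
        counts: dict[str, int] = {}
        for chrom, pos0, strand in site_set:
            site_rows.append((samp, chrom, pos0, strand))
            for gid, _ in ann.gene_at(chrom, pos0):
                counts[gid] = counts.get(gid, 0) + 1
        gene_counts[samp] = counts
        for cl in clusters:
            key = (cl.interval.chrom, cl.interval.strand)
            all_cluster_sites.setdefault(key, set()).update(int(p) for p in cl.sites)
    hyper_site_table = pd.DataFrame(site_rows,
                                    columns=["sample_id", "chrom", "pos0", "strand"])
    hyper_signals = pd.DataFrame(signal_rows, columns=["sample_id", "n_sites",
                                                       "mapped_bases", "signal"]
                                 ).set_index("sample_id")
    counts_df = pd.DataFrame(gene_counts).fillna(0.0)
    gene_lengths = pd.Series({g: len(m.span) for g, m in ann.genes.items()})
    covs_h = [c for c in ("sex", "ancestry1") if c in cohort.columns]
    if len(counts_df):
        enrich = hyper.gene_hyper_enrichment(counts_df, cohort, covs_h, cfg,
                                             gene_lengths.loc[counts_df.index])
    else:
        enrich = pd.DataFrame(columns=["beta_postnatal", "t", "p", "skipped", "p_adj"])

    # -- energetics: miRNA duplexes on 3'UTR matrix sites ----------------------
    duplex_rows = []
    utr_sites = [sid for sid in matrix.levels.index
                 if ann.genic_region(*seqio.parse_site_id(sid)[:2]) == "3'UTR"][:20]
    for sid in utr_sites:
        chrom, pos0, strand = seqio.parse_site_id(sid)
        try:
            un, ed, _ = fold.make_edit_windows(reference, chrom, [pos0], strand, 50,
                                               center=pos0)
        except ValueError:
            continue
        for mid, mseq in mirnas.items():
            dr = fold.mirna_duplex_delta(mid, mseq, sid, un, ed)
            duplex_rows.append((mid, sid, dr.energy_unedited, dr.energy_edited,
                                dr.delta))
    duplex_table = pd.DataFrame(duplex_rows, columns=[
        "mirna", "site_id", "energy_unedited", "energy_edited", "delta"])

    # -- energetics: fold hyper regions, tier comparison -----------------------
    tier_table = None
    if all_cluster_sites and len(enrich):
        flank = params.get("fold_flank", 1000)
        region_rows = []
        for (chrom, strand), pos_set in sorted(all_cluster_sites.items()):
            positions = sorted(pos_set)
            genes_here = ann.gene_at(chrom, positions[0])
            if not genes_here:
                continue
            gid = genes_here[0][0]
            if gid not in enrich.index or pd.isna(enrich.loc[gid, "p_adj"]):
                continue
            un, ed, _ = fold.make_edit_windows(reference, chrom, positions, strand,
                                               flank)
            fu = fold.fold_minimum_energy(un, cfg, "unedited")
            fe = fold.fold_minimum_energy(ed, cfg, "edited")
            region_rows.append((f"{chrom}:{positions[0]}", gid,
                                float(enrich.loc[gid, "p_adj"]),
                                fu.energy, fe.energy,
                                fu.ds_fraction, fe.ds_fraction))
        if region_rows:
            region_table = pd.DataFrame(region_rows, columns=[
                "region_id", "gene", "p_adj", "energy_unedited", "energy_edited",
                "ds_unedited", "ds_edited"])
            tier_table, _ = fold.tier_energy_comparison(region_table)

    # -- edQTL -----------------------------------------------------------------
    edqtl_res = None
    vcf_path = study_dir / "genotypes.vcf"
    if vcf_path.exists() and len(matrix.levels):
        vtab, dosages = seqio.read_vcf_dosages(vcf_path)
        covariates = [c for c in qtl.DEFAULT_COVARIATES if c in cohort.columns]
        # keep enough residual degrees of freedom in the smallest partition
        n_min = int(min((cohort["epoch"] == "prenatal").sum(),
                        (cohort["epoch"] == "postnatal").sum()))
        covariates = covariates[:max(0, n_min - 5)]
        model = qtl.CisEdQTLModel(matrix.levels, dosages, vtab, cohort,
                                  covariates, cfg)
        edqtl_res = model.fit(seed=seed,
                              n_permutations=params.get("n_permutations", 200))

    # -- write outputs ---------------------------------------------------------
    out = study_dir / "results"
    out.mkdir(exist_ok=True)
    seqio.write_matrix(matrix.levels, out / "editing_matrix.tsv")
    diff.table.to_csv(out / "differential.tsv", sep="\t")
    aei_table.to_csv(out / "aei.tsv", sep="\t")
    hyper_signals.to_csv(out / "hyper_signal.tsv", sep="\t")
    enrich.to_csv(out / "hyper_gene_enrichment.tsv", sep="\t")
    duplex_table.to_csv(out / "mirna_duplex.tsv", sep="\t", index=False)
    if edqtl_res is not None:
        edqtl_res.categories.to_csv(out / "edqtl_categories.tsv", sep="\t")
    if tier_table is not None:
        tier_table.to_csv(out / "fold_tiers.tsv", sep="\t", index=False)
    group_df = pd.DataFrame(
        [(seqio.site_id(*k), g) for k, g in sorted(groups.items())],
        columns=["site_id", "group"])
    group_df.to_csv(out / "detection_groups.tsv", sep="\t", index=False)

    return StudyResults(per_sample, groups, jaccard, matrix, diff, aei_table,
                        float(rho), hyper_site_table, hyper_signals, enrich,
                        context, duplex_table, tier_table, edqtl_res)
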