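"""Central configuration: every numeric threshold used by the pipeline.

All stages read their cutoffs from a single :class:`FilterConfig` so that a
run is fully described by one plain-text config file.  Defaults are the
published values of the detection/filtering protocol this package
implements; the handful of knobs the protocol leaves unspecified
(read-end distance, homopolymer run length, imputation donors, folding
window) carry documented package defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class FilterConfig:
    # -- de novo selective-site calling -------------------------------------
    denovo_min_coverage: int = 10      # reads covering the site
    denovo_min_edited: int = 3         # reads carrying the edited base
    denovo_min_ratio: float = 0.01     # edited / (ref + edited)
    # -- supervised (known-site) calling ------------------------------------
    supervised_min_coverage: int = 5
    supervised_min_edited: int = 3
    # -- shared site filters -------------------------------------------------
    maf_mask: float = 0.05             # population-variant mask threshold
    detection_rate: float = 0.70       # fraction of samples a site must be seen in
    min_mean_level: float = 0.05       # minimum mean editing level
    max_sample_missing: float = 0.20   # samples above this missingness are dropped
    # -- hyper-editing read screen ------------------------------------------
    hyper_read_phred: int = 25         # minimum mean base quality per read
    hyper_site_phred: int = 30         # minimum base quality at a recovered edit
    hyper_frac_read_len: float = 0.05  # edits must be >= 5% of read length
    hyper_frac_mismatch: float = 0.60  # edits must be > 60% of all mismatches
    hyper_frac_mismatch_short: float = 0.80  # > 80% when read <= short_read_len
    short_read_len: int = 60
    hyper_density: float = 0.90        # edit span must not exceed 90% of read length
    read_end_frac: float = 0.20        # edits confined to either 20% read end -> fail
    mono_nt_frac: float = 0.60         # single-nucleotide content cap
    multimap_margin: float = 0.10      # A-to-G fraction margin for multi-placements
    # -- edQTL ---------------------------------------------------------------
    cis_window: int = 1_000_000        # bp either side of the editing site
    n_permutations: int = 1000
    fdr: float = 0.05
    # -- package-decided defaults -------------------------------------------
    read_end_bp: int = 6               # mismatches within this many bp of a read end ignored
    splice_adj_bp: int = 4             # ... or of a splice junction
    homopolymer_run: int = 5           # run length defining a homopolymer
    impute_k: int = 5                  # donors for missing-value imputation
    fold_window: int = 400             # max tile folded at once
    min_hairpin: int = 3               # minimum hairpin loop length
    seed_len: int = 20                 # exact-seed length for transformed alignment
    # -- extra knobs ---------------------------------------------------------
    min_mapq: int = 10                 # unique-mapping cutoff for AEI / pileup
    min_base_phred: int = 20           # pileup base-quality cutoff
    aligner_max_mismatch_frac: float = 0.10  # transformed-space extension cap
    qtl_maf_floor: float = 0.05        # within-partition variant MAF floor

    def __post_init__(self) -> None:
        fracs = [
            self.denovo_min_ratio, self.maf_mask, self.detection_rate,
            self.min_mean_level, self.max_sample_missing,
            self.hyper_frac_read_len, self.hyper_frac_mismatch,
            self.hyper_frac_mismatch_short, self.hyper_density,
            self.read_end_frac, self.mono_nt_frac, self.multimap_margin,
            self.fdr, self.aligner_max_mismatch_frac, self.qtl_maf_floor,
        ]
        if not all(0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("all fractional thresholds must lie in [0, 1]")
        counts = [
            self.denovo_min_coverage, self.denovo_min_edited,
            self.supervised_min_coverage, self.supervised_min_edited,
            self.hyper_read_phred, self.hyper_site_phred, self.short_read_len,
            self.cis_window, self.n_permutations, self.read_end_bp,
            self.splice_adj_bp, self.homopolymer_run, self.impute_k,
            self.fold_window, self.min_hairpin, self.seed_len,
        ]
        if not all(isinstance(c, int) and c > 0 for c in counts):
            raise ValueError("all count thresholds must be positive integers")

    # -- serialisation -------------------------------------------------------

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "FilterConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
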