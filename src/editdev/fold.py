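"""Structure energetics: RNA folding, double-strandedness, miRNA duplexes.

The folding engine is a stacking-weighted Nussinov-style dynamic program:
the energy of a structure is the sum of nearest-neighbor stack terms over
adjacent base pairs (Watson-Crick plus G:U wobble), with a minimum hairpin
loop.  This preserves the relative minimum-free-energy and double-stranded-
fraction comparisons the analysis rests on while admitting an exhaustive
enumeration oracle; a full loop-based engine can be plugged through the same
contract.  The objective is lexicographic — minimum energy, then maximum
paired bases, then a traceback preferring the smallest opening index — so
results are deterministic.

miRNA duplex energies come from the best ungapped antisense alignment of the
miRNA against a target window using the same stack table; strict mode
requires perfect Watson-Crick complementarity across the seed (miRNA
positions 2-8).  Editing is evaluated by folding an unedited and an edited
copy of the same window (A at the site versus G).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _seq
from .config import FilterConfig

# nearest-neighbor stack free energies (kcal/mol), 5'WX3' / 3'ZY5' keyed as
# ((W, Z), (X, Y)) base-pair tuples in code space (U is stored as T).
# Watson-Crick values follow the standard table; wobble-containing stacks use
# a fixed approximate value.  Exact numbers are configuration, not science.
_WC_STACKS = {
    ("AU", "AU"): -0.93, ("AU", "UA"): -1.10, ("UA", "AU"): -1.33,
    ("UA", "UA"): -0.93, ("AU", "GC"): -2.24, ("AU", "CG"): -2.08,
    ("UA", "GC"): -2.35, ("UA", "CG"): -2.11, ("GC", "AU"): -2.11,
    ("GC", "UA"): -2.08, ("CG", "AU"): -2.35, ("CG", "UA"): -2.24,
    ("GC", "GC"): -3.26, ("GC", "CG"): -3.42, ("CG", "GC"): -2.36,
    ("CG", "CG"): -3.26,
}
_WOBBLE_STACK = -1.00

_PAIRABLE = {(_seq.A, _seq.T), (_seq.T, _seq.A), (_seq.G, _seq.C),
             (_seq.C, _seq.G), (_seq.G, _seq.T), (_seq.T, _seq.G)}
_WOBBLE = {(_seq.G, _seq.T), (_seq.T, _seq.G)}
_WC = _PAIRABLE - _WOBBLE

_CODE2RNA = {_seq.A: "A", _seq.C: "C", _seq.G: "G", _seq.T: "U"}


def can_pair(a: int, b: int) -> bool:
    return (a, b) in _PAIRABLE


def stack_energy(pair1: tuple[int, int], pair2: tuple[int, int]) -> float:
    """Free energy of pair2 stacked on pair1 (both in code space)."""
    if pair1 not in _PAIRABLE or pair2 not in _PAIRABLE:
        raise ValueError("unpairable bases in stack")
    if pair1 in _WOBBLE or pair2 in _WOBBLE:
        return _WOBBLE_STACK
    key = (_CODE2RNA[pair1[0]] + _CODE2RNA[pair1[1]],
           _CODE2RNA[pair2[0]] + _CODE2RNA[pair2[1]])
    return _WC_STACKS[key]


def structure_energy(codes: np.ndarray, pairs: Sequence[tuple[int, int]]) -> float:
    """Energy of an explicit structure: sum of stack terms over adjacent pairs."""
    ps = sorted(pairs)
    by_open = dict(ps)
    e = 0.0
    for i, j in ps:
        if by_open.get(i + 1) == j - 1:
            e += stack_energy((int(codes[i]), int(codes[j])),
                              (int(codes[i + 1]), int(codes[j - 1])))
    return e


@dataclass
class FoldResult:
    seq_id: str
    dot_bracket: str
    energy: float
    ds_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ds_fraction <= 1.0:
            raise ValueError("ds_fraction outside [0, 1]")


# ---------------------------------------------------------------------------
# folding DP

# lexicographic (energy, -n_pairs) packed into one integer:
# combined = round(energy*100) * 1024 - n_pairs  (n_pairs < 512 per tile)
_SCALE = 1024
_INF = np.iinfo(np.int64).max // 4


def _pack(e_centi: int, n_pairs: int) -> int:
    return e_centi * _SCALE - n_pairs


def _unpack(combined: int) -> tuple[float, int]:
    q, r = divmod(combined, _SCALE)
    if r == 0:
        return q / 100.0, 0
    return (q + 1) / 100.0, _SCALE - r


def _fold_tile(codes: np.ndarray, min_hairpin: int) -> tuple[str, float, int]:
    """DP over one tile; returns (dot-bracket, energy, n_pairs)."""
    n = codes.size
    if n == 0:
        return "", 0.0, 0
    pairable = np.zeros((n, n), dtype=bool)
    stack_centi = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + min_hairpin + 1, n):
            if (int(codes[i]), int(codes[j])) in _PAIRABLE:
                pairable[i, j] = True
    V = np.full((n, n), _INF, dtype=np.int64)
    # W[i][j] for the region [i, j]; empty regions are 0
    W = np.zeros((n + 1, n + 1), dtype=np.int64)

    for span in range(min_hairpin + 1, n):
        for i in range(0, n - span):
            j = i + span
            if pairable[i, j]:
                best = W[i + 1, j - 1] if j - 1 >= i + 1 else 0
                if j - 2 >= i + 2 and pairable[i + 1, j - 1] and V[i + 1, j - 1] < _INF:
                    sc = int(round(stack_energy(
                        (int(codes[i]), int(codes[j])),
                        (int(codes[i + 1]), int(codes[j - 1]))) * 100))
                    best = min(best, sc * _SCALE + V[i + 1, j - 1])
                V[i, j] = best - 1  # the (i, j) pair itself
            # W recursion
            w = W[i + 1, j]
            ks = np.arange(i + min_hairpin + 1, j + 1)
            if ks.size:
                vk = V[i, ks]
                wk = W[ks + 1, j]
                ok = vk < _INF
                if ok.any():
                    w = min(w, int(np.min(vk[ok] + wk[ok])))
            W[i, j] = w
        # also fill W for spans below pairing threshold (all zero already)

    # traceback
    db = ["."] * n
    n_pairs_total = 0

    def trace_w(i: int, j: int) -> None:
        nonlocal n_pairs_total
        while i <= j:
            target = W[i, j]
            # prefer pairing the smallest opening index
            chosen = None
            for k in range(i + min_hairpin + 1, j + 1):
                if pairable[i, k] and V[i, k] < _INF and V[i, k] + W[k + 1, j] == target:
                    chosen = k
                    break
            if chosen is not None:
                trace_v(i, chosen)
                i = chosen + 1
                continue
            # i unpaired
            i += 1

    def trace_v(i: int, j: int) -> None:
        nonlocal n_pairs_total
        db[i], db[j] = "(", ")"
        n_pairs_total += 1
        inner = V[i, j] + 1  # remove this pair's count
        if j - 2 >= i + 2 and pairable[i + 1, j - 1] and V[i + 1, j - 1] < _INF:
            sc = int(round(stack_energy(
                (int(codes[i]), int(codes[j])),
                (int(codes[i + 1]), int(codes[j - 1]))) * 100))
            if sc * _SCALE + V[i + 1, j - 1] == inner:
                trace_v(i + 1, j - 1)
                return
        if j - 1 >= i + 1 and W[i + 1, j - 1] == inner:
            trace_w(i + 1, j - 1)

    combined = int(W[0, n - 1]) if n > 1 else 0
    trace_w(0, n - 1)
    energy, n_pairs = _unpack(combined)
    return "".join(db), energy, n_pairs


def fold_minimum_energy(seq: str, cfg: FilterConfig | None = None,
                        seq_id: str = "seq") -> FoldResult:
    """Minimum-energy fold; sequences beyond ``cfg.fold_window`` are folded in
    tiles and concatenated."""
    cfg = cfg or FilterConfig()
    codes = _seq.encode(seq)
    if (codes >= 4).any():
        raise ValueError("sequence contains non-ACGU characters")
    db_parts = []
    energy = 0.0
    for start in range(0, codes.size, cfg.fold_window):
        tile = codes[start:start + cfg.fold_window]
        db, e, _ = _fold_tile(tile, cfg.min_hairpin)
        db_parts.append(db)
        energy += e
    db = "".join(db_parts)
    return FoldResult(seq_id, db, energy, double_strand_fraction(db))


def enumerate_structures(codes: np.ndarray, min_hairpin: int = 3,
                         ) -> list[list[tuple[int, int]]]:
    """All valid secondary structures (no pseudoknots) of a short sequence."""
    n = codes.size
    memo: dict[tuple[int, int], list] = {}

    def rec(i: int, j: int) -> list[list[tuple[int, int]]]:
        if i > j:
            return [[]]
        if (i, j) in memo:
            return memo[(i, j)]
        out = [s for s in rec(i + 1, j)]
        for k in range(i + min_hairpin + 1, j + 1):
            if (int(codes[i]), int(codes[k])) in _PAIRABLE:
                for inner in rec(i + 1, k - 1):
                    for rest in rec(k + 1, j):
                        out.append([(i, k)] + inner + rest)
        memo[(i, j)] = out
        return out

    return rec(0, n - 1)


def double_strand_fraction(dot_bracket: str) -> float:
    """Fraction of bases paired in a dot-bracket string (validated balanced)."""
    depth = 0
    paired = 0
    for ch in dot_bracket:
        if ch == "(":
            depth += 1
            paired += 1
        elif ch == ")":
            depth -= 1
            paired += 1
            if depth < 0:
                raise ValueError("unbalanced dot-bracket string")
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if depth != 0:
        raise ValueError("unbalanced dot-bracket string")
    return paired / len(dot_bracket) if dot_bracket else 0.0


# ---------------------------------------------------------------------------
# edit windows


def make_edit_windows(reference: Mapping[str, np.ndarray], chrom: str,
                      positions: Sequence[int], strand: str, flank: int,
                      center: int | None = None) -> tuple[str, str, bool]:
    """(unedited, edited) transcript-strand sequences around editing site(s).

    ``positions`` are genomic A positions on the transcript strand (reference
    T positions for minus-strand sites); every one inside the window is
    flipped to G in the edited copy.  Windows truncated at a contig edge are
    flagged (third return value).
    """
    ref = reference[chrom]
    if center is None:
        center = int(round(float(np.mean(positions))))
    lo = center - flank
    hi = center + flank + 1
    truncated = lo < 0 or hi > ref.size
    lo, hi = max(0, lo), min(ref.size, hi)
    window = ref[lo:hi].copy()
    edited = window.copy()
    want = _seq.A if strand == "+" else _seq.T
    to = _seq.G if strand == "+" else _seq.C
    for p in positions:
        if lo <= p < hi:
            if window[p - lo] != want:
                raise ValueError(f"position {p} is not an editable adenosine")
            edited[p - lo] = to
    if strand == "-":
        window = _seq.revcomp(window)
        edited = _seq.revcomp(edited)
    return _seq.decode(window), _seq.decode(edited), truncated


# ---------------------------------------------------------------------------
# miRNA duplexes


@dataclass
class DuplexResult:
    mirna_id: str
    window_id: str
    energy_unedited: float
    energy_edited: float
    strict_seed: bool

    @property
    def delta(self) -> float:
        return self.energy_edited - self.energy_unedited


def best_duplex_energy(mirna: str, window: str, strict_seed: bool = False) -> float:
    """Lowest duplex energy over all ungapped antisense alignments.

    The miRNA (5'->3') pairs antiparallel with the window; paired runs
    contribute nearest-neighbor stack terms.  Strict mode demands perfect
    Watson-Crick complementarity at miRNA positions 2-8.  Returns 0 when no
    alignment is favorable.
    """
    if not 19 <= len(mirna) <= 25:
        raise ValueError("miRNA length must be 19-25 nt")
    m = _seq.encode(mirna)
    w = _seq.encode(window)
    L = m.size
    if w.size < L:
        raise ValueError("target window shorter than the miRNA")
    m_rev = m[::-1]  # align antiparallel: window position off+k pairs m_rev[k]
    best = 0.0
    for off in range(w.size - L + 1):
        tgt = w[off:off + L]
        paired = np.array([(int(t), int(mm)) in _PAIRABLE
                           for t, mm in zip(tgt, m_rev)])
        if strict_seed:
            # miRNA positions 2-8 (1-based) sit at m_rev indices L-2 .. L-8
            seed_idx = [L - 1 - k for k in range(1, 8)]
            if not all((int(tgt[si]), int(m_rev[si])) in _WC for si in seed_idx):
                continue
        e = 0.0
        for k in range(L - 1):
            if paired[k] and paired[k + 1]:
                e += stack_energy((int(tgt[k]), int(m_rev[k])),
                                  (int(tgt[k + 1]), int(m_rev[k + 1])))
        best = min(best, e)
    return best


def mirna_duplex_delta(mirna_id: str, mirna: str, window_id: str,
                       unedited: str, edited: str,
                       strict_seed: bool = False) -> DuplexResult:
    """Duplex energies for the unedited and edited copy of one window."""
    return DuplexResult(
        mirna_id, window_id,
        best_duplex_energy(mirna, unedited, strict_seed),
        best_duplex_energy(mirna, edited, strict_seed),
        strict_seed,
    )


# ---------------------------------------------------------------------------
# tiered comparison


def assign_tier(p_adj: float) -> int:
    """Gene tier from the adjusted differential hyper-editing p value."""
    if p_adj < 1e-10:
        return 3
    if p_adj < 1e-5:
        return 2
    if p_adj < 0.05:
        return 1
    return 0


def tier_energy_comparison(region_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tier 3 versus lower tiers on fold energy and double-strandedness.

    ``region_table`` needs columns: region_id, gene, p_adj, energy_unedited,
    energy_edited, ds_unedited, ds_edited.  Returns the table with a ``tier``
    column plus Mann-Whitney results for Tier 3 against each other tier on
    unedited values and on (edited - unedited) deltas; empty comparisons are
    flagged rather than tested.
    """
    from .stats import mann_whitney

    tab = region_table.copy()
    tab["tier"] = tab["p_adj"].map(assign_tier)
    tab["energy_delta"] = tab["energy_edited"] - tab["energy_unedited"]
    tab["ds_delta"] = tab["ds_edited"] - tab["ds_unedited"]
    rows = []
    t3 = tab[tab["tier"] == 3]
    for other in (2, 1, 0):
        to = tab[tab["tier"] == other]
        for metric in ("energy_unedited", "ds_unedited", "energy_delta", "ds_delta"):
            if len(t3) == 0 or len(to) == 0:
                rows.append((other, metric, np.nan, np.nan, True))
                continue
            u, p = mann_whitney(t3[metric].to_numpy(), to[metric].to_numpy())
            rows.append((other, metric, u, p, False))
    tests = pd.DataFrame(rows, columns=["vs_tier", "metric", "U", "p", "skipped"])
    return tab, tests
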