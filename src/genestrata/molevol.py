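"""Reciprocal-best-hit ortholog pairing and Nei–Gojobori (1986) Ka/Ks.

Ka/Ks is estimated by codon counting: each codon contributes synonymous and
nonsynonymous *sites* according to the fraction of its single-nucleotide
mutations that preserve the encoded amino acid, and each differing codon pair
contributes *differences* averaged over all orderings of its mutational
pathway, excluding pathways that pass through stop codons.  Proportions are
corrected for multiple substitutions with the Jukes–Cantor formula
``d = -(3/4) ln(1 - 4p/3)``.  Unlike maximum-likelihood codon models, this
counting estimator ignores transition/transversion bias and codon frequencies,
which typically inflates Ks slightly; stratified *comparisons* of Ka, Ks and
their ratio between gene-age groups are unaffected in direction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from scipy import stats

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)
_NUCS = "ACGT"


def _aa(codon: str) -> str | None:
    """Amino acid for a codon, or None for stop codons."""
    if codon in _STOPS:
        return None
    return _TABLE.forward_table[codon]


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon; they sum to 3.

    At each position the synonymous fraction is taken over the mutations that
    do not create a stop codon; a position whose every mutation creates a stop
    counts as fully nonsynonymous.
    """
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon} in coding sequence")
    aa0 = _aa(codon)
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_valid = 0
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            mutant = codon[:pos] + nuc + codon[pos + 1:]
            if mutant in _STOPS:
                continue
            n_valid += 1
            if _aa(mutant) == aa0:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Multi-difference codons are averaged over every ordering of the single
    mutations; orderings passing through a stop codon are excluded.  If every
    ordering is blocked by stops, the raw difference count is split evenly.
    """
    for c in (c1, c2):
        if c in _STOPS:
            raise ValueError(f"stop codon {c} in coding sequence")
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0
    syn_tot = nsyn_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        current = c1
        syn = nsyn = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1:]
            if nxt in _STOPS:
                ok = False
                break
            if _aa(nxt) == _aa(current):
                syn += 1
            else:
                nsyn += 1
            current = nxt
        if ok:
            syn_tot += syn
            nsyn_tot += nsyn
            n_paths += 1
    if n_paths == 0:
        return k / 2.0, k / 2.0
    return syn_tot / n_paths, nsyn_tot / n_paths


@dataclass(frozen=True)
class OrthologPair:
    """A gap-free pairwise codon alignment of two putative orthologs."""

    gene_a: str
    gene_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences differ in length")
        if len(self.seq_a) % 3 != 0:
            raise ValueError("alignment length not divisible by 3")
        for seq, name in ((self.seq_a, self.gene_a), (self.seq_b, self.gene_b)):
            if set(seq) - set(_NUCS):
                raise ValueError(f"{name}: non-ACGT characters (alignments must be gap-free)")
            for i in range(0, len(seq), 3):
                if seq[i:i + 3] in _STOPS:
                    raise ValueError(f"{name}: internal stop codon at position {i + 1}")


@dataclass(frozen=True)
class KaKsResult:
    S: float    # synonymous sites
    N: float    # nonsynonymous sites
    Sd: float   # synonymous differences
    Nd: float   # nonsynonymous differences
    Ka: float   # NaN when saturated
    Ks: float
    ratio: float  # Ka/Ks; NaN when Ks == 0 or either rate is saturated


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return float("nan")  # saturated
    if p == 0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_kaks(pair: OrthologPair) -> KaKsResult:
    """Nei–Gojobori Ka/Ks for one gap-free codon alignment."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(pair.seq_a), 3):
        ca, cb = pair.seq_a[i:i + 3], pair.seq_b[i:i + 3]
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = codon_differences(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = _jukes_cantor(pS)
    Ka = _jukes_cantor(pN)
    if math.isnan(Ka) or math.isnan(Ks) or Ks == 0:
        ratio = float("nan")
    else:
        ratio = Ka / Ks
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, Ka=Ka, Ks=Ks, ratio=ratio)


# ---------------------------------------------------------------------------
# Reciprocal best hits
# ---------------------------------------------------------------------------

def _best_hits(hits) -> dict[str, str]:
    """Top subject per query: highest bitscore, then lowest e-value, then
    lexicographically smallest subject id."""
    best: dict[str, tuple] = {}
    for h in hits:
        key = (-h.bitscore, h.evalue, h.subject_taxon)
        if h.query_gene not in best or key < best[h.query_gene]:
            best[h.query_gene] = key
    return {q: k[2] for q, k in best.items()}


def reciprocal_best_hits(hits_ab: Iterable, hits_ba: Iterable,
                         ) -> tuple[list[tuple[str, str]], list[str], list[str]]:
    """Mutual-top-hit ortholog pairs between two gene universes.

    ``hits_ab`` are hits of species A queries against species B genes (subject
    gene id carried in the hit's subject field) and vice versa.  Returns
    (pairs sorted by gene_a, unpaired A queries, unpaired B queries).
    """
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs = sorted(
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    )
    paired_a = {a for a, _ in pairs}
    paired_b = {b for _, b in pairs}
    unpaired_a = sorted(set(best_ab) - paired_a)
    unpaired_b = sorted(set(best_ba) - paired_b)
    return pairs, unpaired_a, unpaired_b


def kaks_by_stratum(results: Mapping[str, KaKsResult], calls,
                    new_ranks: set[int]) -> dict:
    """One-sided tests that new genes show elevated Ka, Ks and Ka/Ks.

    ``results`` maps focal gene id -> KaKsResult; group membership comes from
    founder strata in ``calls``.  Pairs with undefined (saturated or Ks=0)
    ratios are excluded from the ratio comparison, with the count reported.
    """
    founder = {c.gene_id: c.founder_ps for c in calls if c.founder_ps is not None}
    rows = []
    for g, res in results.items():
        if g in founder:
            rows.append({"gene_id": g, "founder_ps": founder[g],
                         "Ka": res.Ka, "Ks": res.Ks, "ratio": res.ratio})
    df = pd.DataFrame(rows)
    if df.empty or not df["founder_ps"].isin(new_ranks).any():
        raise ValueError("new-gene group is empty")
    if (~df["founder_ps"].isin(new_ranks)).sum() == 0:
        raise ValueError("old-gene group is empty")
    is_new = df["founder_ps"].isin(new_ranks)
    report = {"n_new": int(is_new.sum()), "n_old": int((~is_new).sum())}
    for col in ("Ka", "Ks", "ratio"):
        new_vals = df.loc[is_new, col].dropna()
        old_vals = df.loc[~is_new, col].dropna()
        n_excl = int(df[col].isna().sum())
        if n_excl:
            report.setdefault("n_undefined_excluded", {})[col] = n_excl
        if len(new_vals) == 0 or len(old_vals) == 0:
            report[col] = {"p_one_sided": float("nan")}
            continue
        _, p = stats.mannwhitneyu(new_vals, old_vals, alternative="greater")
        report[col] = {
            "p_one_sided": float(p),
            "median_new": float(new_vals.median()),
            "median_old": float(old_vals.median()),
        }
    return report


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_codon_pairs(path: str | Path) -> list[OrthologPair]:
    """Read paired codon FASTA: consecutive records 2k, 2k+1 form one pair."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2 != 0:
        raise ValueError(f"{path}: odd number of records in paired FASTA")
    pairs = []
    for i in range(0, len(records), 2):
        a, b = records[i], records[i + 1]
        pairs.append(OrthologPair(gene_a=a.id, gene_b=b.id,
                                  seq_a=str(a.seq).upper(), seq_b=str(b.seq).upper()))
    return pairs


def write_codon_pairs(path: str | Path, pairs: Sequence[OrthologPair]) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f">{p.gene_a}\n{p.seq_a}\n>{p.gene_b}\n{p.seq_b}\n")


def kaks_frame(pairs: Sequence[OrthologPair],
               results: Sequence[KaKsResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_a": p.gene_a, "gene_b": p.gene_b,
        "S": r.S, "N": r.N, "Sd": r.Sd, "Nd": r.Nd,
        "Ka": r.Ka, "Ks": r.Ks, "ratio": r.ratio,
    } for p, r in zip(pairs, results)],
        columns=["gene_a", "gene_b", "S", "N", "Sd", "Nd", "Ka", "Ks", "ratio"])
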