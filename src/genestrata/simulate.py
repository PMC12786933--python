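"""Synthetic-data generation for every pipeline input, with serialized ground truth.

The generator emulates the data classes the pipeline consumes in real use:

* homology hit tables whose bitscores decay exponentially with divergence
  time, so the deepest detected taxon encodes a planted true age; planted
  homology-detection-failure (HDF) genes get an inflated decay rate so their
  deep-taxon scores fall below the detection threshold, and planted
  contaminant-like genes hit a single deep subclade only;
* gene families sharing founder ages, expressed as an all-vs-all similarity
  list for clustering;
* GFF3/FASTA gene models whose CDS length and exon count shrink with
  decreasing gene age;
* tissue TPM matrices with planted expression breadth and tissue specificity
  (young genes narrow, old genes broad, specific young genes concentrated in
  one tissue);
* stress count matrices (negative binomial) with planted differentially
  expressed genes, and a latent-factor co-expression matrix with planted
  modules containing young hub genes;
* codon-aligned ortholog pairs with controlled synonymous/nonsynonymous
  change counts, plus reciprocal-best-hit tables with decoy paralogs.

Everything is driven by one integer seed; regenerating with the same seed
reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ages import PhylostratumLadder, build_ladder
from .formats import HomologyHit
from .molevol import _NUCS, _STOPS, _aa
from .transcriptome import ExpressionMatrix

# A realistic 18-stratum ladder fixture in the style of an insect lineage;
# anchor ages (4250, 1598, 35, 9 MYA) follow published divergence-time
# compilations, intermediate ages are interpolated.  This is a fixture for
# testing, not a statement about any real species.
FOCAL_LINEAGE = [
    "cellular_organisms", "Eukaryota", "Opisthokonta", "Metazoa", "Eumetazoa",
    "Bilateria", "Protostomia", "Ecdysozoa", "Arthropoda", "Insecta",
    "Endopterygota", "Lepidoptera", "Glossata", "Noctuoidea", "Noctuidae",
    "focal_genus", "focal_species_pair", "focal_species",
]
STRATUM_AGES = [4250.0, 1598.0, 1200.0, 950.0, 800.0, 680.0, 620.0, 560.0,
                440.0, 400.0, 350.0, 300.0, 250.0, 150.0, 35.0, 27.0, 18.0, 9.0]

TISSUES = ["antenna", "body_wall", "brain", "cuticle", "fat_body", "hemocytes",
           "malpighian_tubule", "male_gonad", "midgut", "ovary",
           "pheromone_gland", "prothoracic_gland", "salivary_gland", "thorax"]

STRESS_CLASSES = {
    "parasitization": "parasitization",
    "pesticide_A": "pesticide",
    "virus": "virus",
    "host_plant": "host_plant",
}

_AAS = "ACDEFGHIKLMNPQRSTVWY"
_CODONS = [a + b + c for a in _NUCS for b in _NUCS for c in _NUCS
           if a + b + c not in _STOPS]


def default_ladder() -> PhylostratumLadder:
    ages = dict(zip(FOCAL_LINEAGE, STRATUM_AGES))
    return build_ladder(FOCAL_LINEAGE, ages)


@dataclass
class SimulationParams:
    """Study conditions for the synthetic cohort (defaults are the conditions)."""

    base_birth_rate: float = 0.05        # genes per MY off-peak
    peak_ranks: tuple[int, ...] = (5, 9, 15)
    peak_fold: float = 20.0
    n_subclades: int = 8                 # database subclades per stratum
    deep_coverage: tuple[int, int] = (4, 8)   # subclades hit at the deepest stratum
    n_hdf: int = 20
    n_contaminant: int = 16
    bitscore_a_range: tuple[float, float] = (150.0, 250.0)
    bitscore_noise_sd: float = 3.0
    outgroup_target_score: float = 60.0  # expected score one stratum beyond truth
    hdf_detected_score: tuple[float, float] = (30.0, 34.0)
    detection_threshold: float = 30.0
    cross_rank_families: int = 10
    n_replicates: int = 2                # per tissue
    expr_noise_sd: float = 0.2           # lognormal replicate noise
    brain_bias: float = 0.8              # fraction of specific new genes peaking in brain
    nb_dispersion: float = 0.1
    de_fold: float = 4.0
    n_stress_reps: int = 4
    coexpr_block: int = 40
    coexpr_noise_genes: int = 30
    coexpr_samples: int = 20
    coexpr_noise_sd: float = 0.12
    n_young_hubs: int = 10
    n_ortholog_pairs: int = 150
    codon_length: int = 300

    def validate(self) -> None:
        if self.n_hdf < 0 or self.n_contaminant < 0:
            raise ValueError("planted case counts must be non-negative")
        if not 0 <= self.brain_bias <= 1:
            raise ValueError("brain_bias is a fraction")
        if self.peak_fold <= 1:
            raise ValueError("peak_fold must exceed 1")


@dataclass
class SyntheticCohort:
    """All pipeline inputs for one simulated cohort, plus ground truth."""

    params: SimulationParams
    seed: int
    ladder: PhylostratumLadder
    lineages: dict[str, list[str]]
    hits: list[HomologyHit]
    hit_rows: pd.DataFrame              # 13-column outfmt-6 dialect
    self_hits: list[tuple[str, str, float]]
    gff3_text: str
    fasta_text: str
    truth: pd.DataFrame                 # per-gene ground truth
    tissue_matrix: ExpressionMatrix
    stress: dict[str, tuple[pd.DataFrame, dict[str, str]]]  # contrast -> (counts, groups)
    coexpr_expr: pd.DataFrame
    coexpr_traits: pd.DataFrame
    coexpr_truth: pd.DataFrame          # gene, planted_module, is_young_hub
    ortho_ab: pd.DataFrame
    ortho_ba: pd.DataFrame
    rbh_truth: pd.DataFrame
    codon_pairs_fasta: str
    kaks_truth: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.truth["gene_id"])

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Serialize every input + truth under ``outdir``; returns path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def p(name: str) -> Path:
            paths[name] = outdir / name
            return paths[name]

        payload = dataclasses.asdict(self.params)
        payload["seed"] = self.seed
        p("params.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        with open(p("stratum_ages.tsv"), "w") as fh:
            for _, name, age in self.ladder.strata:
                fh.write(f"{name}\t{age:g}\n")
        with open(p("lineages.tsv"), "w") as fh:
            for taxon in sorted(self.lineages):
                fh.write(f"{taxon}\t{';'.join(self.lineages[taxon])}\n")
        self.hit_rows.to_csv(p("hits.tsv"), sep="\t", header=False, index=False)
        with open(p("self_hits.tsv"), "w") as fh:
            for a, b, e in self.self_hits:
                fh.write(f"{a}\t{b}\t{e:.6g}\n")
        p("genes.gff3").write_text(self.gff3_text)
        p("proteins.faa").write_text(self.fasta_text)
        self.truth.to_csv(p("truth.tsv"), sep="\t", index=False, float_format="%.6g")
        self.tissue_matrix.values.to_csv(p("tissue_tpm.tsv"), sep="\t",
                                         float_format="%.6g")
        self.tissue_matrix.sample_meta.to_csv(p("tissue_samples.tsv"), sep="\t")
        rows = []
        for contrast, (counts, groups) in self.stress.items():
            counts.to_csv(p(f"stress_{contrast}_counts.tsv"), sep="\t")
            for s, g in groups.items():
                rows.append({"contrast": contrast,
                             "class": STRESS_CLASSES.get(contrast, "other"),
                             "sample": s, "group": g})
        pd.DataFrame(rows).to_csv(p("stress_groups.tsv"), sep="\t", index=False)
        self.coexpr_expr.to_csv(p("coexpr_expr.tsv"), sep="\t", float_format="%.6g")
        self.coexpr_traits.to_csv(p("coexpr_traits.tsv"), sep="\t")
        self.coexpr_truth.to_csv(p("truth_modules.tsv"), sep="\t", index=False)
        self.ortho_ab.to_csv(p("orth_ab.tsv"), sep="\t", header=False, index=False)
        self.ortho_ba.to_csv(p("orth_ba.tsv"), sep="\t", header=False, index=False)
        self.rbh_truth.to_csv(p("truth_rbh.tsv"), sep="\t", index=False)
        p("codon_pairs.fasta").write_text(self.codon_pairs_fasta)
        self.kaks_truth.to_csv(p("truth_kaks.tsv"), sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def stratum_gene_counts(ladder: PhylostratumLadder,
                        params: SimulationParams) -> dict[int, int]:
    """Planted founder counts per stratum from a piecewise-constant birth rate."""
    counts = {}
    for r, _, age in ladder.strata:
        interval = age if r == 1 else ladder.age_of(r - 1) - age
        rate = params.base_birth_rate
        if r in params.peak_ranks:
            rate *= params.peak_fold
        counts[r] = max(1, round(rate * interval))
    return counts


def make_lineages(ladder: PhylostratumLadder, n_subclades: int) -> dict[str, list[str]]:
    """Database taxa: ``n_subclades`` per stratum below the root-to-tip path."""
    names = ladder.names
    lineages: dict[str, list[str]] = {}
    for r in range(1, ladder.n_strata):  # strata 1..K-1 host outgroup taxa
        for s in range(1, n_subclades + 1):
            taxon = f"t_r{r:02d}_s{s}"
            lineages[taxon] = names[:r] + [f"sc_r{r:02d}_{s}", taxon]
    lineages[names[-1]] = list(names)
    return lineages


def _hit_row(gene: str, taxon: str, score: float, rng) -> dict:
    evalue = 1e-3 * 2.0 ** (-score)
    length = int(rng.integers(80, 400))
    return {
        "qseqid": gene, "sseqid": f"{taxon}_p1",
        "pident": round(float(rng.uniform(30, 95)), 1),
        "length": length, "mismatch": int(rng.integers(0, length // 2)),
        "gapopen": int(rng.integers(0, 5)),
        "qstart": 1, "qend": length, "sstart": 1, "send": length,
        "evalue": f"{evalue:.3g}", "bitscore": round(float(score), 1),
        "staxid": taxon,
    }


def _decay_distance(rank: int, ladder: PhylostratumLadder) -> float:
    return 0.0 if rank == ladder.n_strata else ladder.age_of(rank)


# ---------------------------------------------------------------------------
# standalone generators (also used by the cohort)
# ---------------------------------------------------------------------------

def simulate_de_matrix(n_genes: int = 2000, n_deg: int = 100, fold: float = 4.0,
                       n_per_group: int = 4, dispersion: float = 0.1,
                       seed: int = 0, deg_min_mean: float = 50.0,
                       ) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Negative-binomial count matrix with planted fold-change genes.

    Planted effects go on adequately expressed genes (baseline mean >=
    ``deg_min_mean``) since that is where real DE calls are made.  Returns
    (counts, sample->group map, per-gene truth with is_deg and direction).
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    baseline = np.maximum(rng.lognormal(np.log(150.0), 1.2, size=n_genes), 1.0)
    eligible = np.flatnonzero(baseline >= deg_min_mean)
    if n_deg > len(eligible):
        raise ValueError("not enough well-expressed genes for planted DEGs")
    deg_idx = rng.choice(eligible, size=n_deg, replace=False)
    up = rng.random(n_deg) < 0.5

    treated = [f"T{i+1}" for i in range(n_per_group)]
    control = [f"C{i+1}" for i in range(n_per_group)]
    mean_t = baseline.copy()
    mean_t[deg_idx[up]] *= fold
    mean_t[deg_idx[~up]] /= fold

    def draw(mean: np.ndarray, n_samples: int) -> np.ndarray:
        n = 1.0 / dispersion
        p = n / (n + mean[:, None])
        return rng.negative_binomial(n, np.broadcast_to(p, (len(mean), n_samples)))

    counts = pd.DataFrame(
        np.hstack([draw(mean_t, n_per_group), draw(baseline, n_per_group)]),
        index=genes, columns=treated + control)
    groups = {s: "treated" for s in treated} | {s: "control" for s in control}
    truth = pd.DataFrame({"gene_id": genes, "is_deg": False, "direction": "none"})
    truth.loc[deg_idx, "is_deg"] = True
    truth.loc[deg_idx[up], "direction"] = "up"
    truth.loc[deg_idx[~up], "direction"] = "down"
    return counts, groups, truth


def simulate_coexpression(gene_ids_block1: Sequence[str],
                          gene_ids_block2: Sequence[str],
                          gene_ids_noise: Sequence[str],
                          n_samples: int = 20, noise_sd: float = 0.12,
                          factor_noise_sd: float = 0.3, seed: int = 0,
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two latent-factor modules + unstructured noise genes, log-scale values.

    Block 1 is driven by a factor tied to a balanced treatment indicator
    (first half treated); block 2 by an independent factor.  Returns
    (expr genes × samples, traits samples × 1, truth gene->module).
    """
    rng = np.random.default_rng(seed)
    samples = [f"s{i+1:02d}" for i in range(n_samples)]
    treat = np.array([1.0] * (n_samples // 2) + [0.0] * (n_samples - n_samples // 2))
    f1 = 2.0 * (treat - 0.5) + rng.normal(0, factor_noise_sd, n_samples)
    f2 = rng.normal(0, 1.0, n_samples)

    rows, truth_rows = [], []
    for g in gene_ids_block1:
        loading = rng.uniform(0.9, 1.2)
        rows.append(loading * f1 + rng.normal(0, noise_sd, n_samples))
        truth_rows.append({"gene_id": g, "planted_module": "block1"})
    for g in gene_ids_block2:
        loading = rng.uniform(0.9, 1.2)
        rows.append(loading * f2 + rng.normal(0, noise_sd, n_samples))
        truth_rows.append({"gene_id": g, "planted_module": "block2"})
    for g in gene_ids_noise:
        rows.append(rng.normal(0, 1.0, n_samples))
        truth_rows.append({"gene_id": g, "planted_module": "none"})
    genes = list(gene_ids_block1) + list(gene_ids_block2) + list(gene_ids_noise)
    expr = pd.DataFrame(np.array(rows), index=genes, columns=samples)
    traits = pd.DataFrame({"treatment": treat}, index=samples)
    traits.index.name = "sample"
    return expr, traits, pd.DataFrame(truth_rows)


_SYN_NEIGHBORS: dict[str, list[tuple[int, str]]] = {}
_NONSYN_NEIGHBORS: dict[str, list[tuple[int, str]]] = {}
for _c in _CODONS:
    syn, nonsyn = [], []
    for _pos in range(3):
        for _n in _NUCS:
            if _n == _c[_pos]:
                continue
            _m = _c[:_pos] + _n + _c[_pos + 1:]
            if _m in _STOPS:
                continue
            (syn if _aa(_m) == _aa(_c) else nonsyn).append((_pos, _n))
    _SYN_NEIGHBORS[_c] = syn
    _NONSYN_NEIGHBORS[_c] = nonsyn
_SYN_CAPABLE = [c for c in _CODONS if _SYN_NEIGHBORS[c]]


def simulate_codon_pair(n_syn: int, n_nonsyn: int, length: int,
                        rng: np.random.Generator) -> tuple[str, str]:
    """A codon alignment with exactly the given single-nucleotide change counts.

    Changes are planted in distinct codons, one nucleotide each, so the
    pathway-averaged difference counts equal the planted counts exactly.
    """
    if n_syn + n_nonsyn > length:
        raise ValueError("more changes than codons")
    codons_a = [_CODONS[i] for i in rng.integers(0, len(_CODONS), size=length)]
    positions = rng.choice(length, size=n_syn + n_nonsyn, replace=False)
    codons_b = list(codons_a)
    for k, pos in enumerate(positions):
        if k < n_syn:
            # re-draw a codon that has a synonymous single-nt neighbour
            donor = _SYN_CAPABLE[rng.integers(0, len(_SYN_CAPABLE))]
            codons_a[pos] = donor
            p, n = _SYN_NEIGHBORS[donor][rng.integers(0, len(_SYN_NEIGHBORS[donor]))]
        else:
            donor = codons_a[pos]
            choices = _NONSYN_NEIGHBORS[donor]
            p, n = choices[rng.integers(0, len(choices))]
        codons_b[pos] = donor[:p] + n + donor[p + 1:]
    return "".join(codons_a), "".join(codons_b)


def simulate_rbh_tables(pair_ids: Sequence[tuple[str, str]],
                        decoy_fraction: float = 0.05, seed: int = 0,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Reciprocal one-to-one hit tables with decoy paralogs at 90 % bitscore."""
    rng = np.random.default_rng(seed)
    n = len(pair_ids)
    scores = rng.uniform(300, 500, size=n)
    decoys = rng.random(n) < decoy_fraction
    rows_ab, rows_ba = [], []
    for i, (a, b) in enumerate(pair_ids):
        rows_ab.append(_hit_row(a, b, scores[i], rng))
        rows_ba.append(_hit_row(b, a, scores[i] * rng.uniform(0.98, 1.0), rng))
        if decoys[i]:
            # decoy paralogs at 90% of the query's own best score, both directions
            j = (i + 1) % n
            rows_ab.append(_hit_row(a, pair_ids[j][1], scores[i] * 0.9, rng))
            rows_ba.append(_hit_row(b, pair_ids[j][0], scores[i] * 0.9, rng))
    truth = pd.DataFrame(pair_ids, columns=["gene_a", "gene_b"])
    return pd.DataFrame(rows_ab), pd.DataFrame(rows_ba), truth


# ---------------------------------------------------------------------------
# the full cohort
# ---------------------------------------------------------------------------

def _plan_genes(ladder: PhylostratumLadder, params: SimulationParams,
                rng: np.random.Generator) -> pd.DataFrame:
    """Assign gene ids, true ages, planted case labels and family structure."""
    counts = stratum_gene_counts(ladder, params)
    records = []
    for r in sorted(counts):
        for _ in range(counts[r]):
            records.append({"true_raw_ps": r, "is_hdf_case": False,
                            "is_contaminant_case": False, "hdf_true_ps": 0})
    for _ in range(params.n_hdf):
        # truly old gene whose deep homologs decay below the search threshold;
        # the detectable (observed) age is a mid-ladder stratum
        records.append({"true_raw_ps": int(rng.integers(8, 14)),
                        "is_hdf_case": True, "is_contaminant_case": False,
                        "hdf_true_ps": int(rng.integers(2, 7))})
    for _ in range(params.n_contaminant):
        records.append({"true_raw_ps": 1, "is_hdf_case": False,
                        "is_contaminant_case": True, "hdf_true_ps": 0})
    truth = pd.DataFrame(records)
    truth.insert(0, "gene_id", [f"g{i:04d}" for i in range(1, len(truth) + 1)])

    # families: multicopy probability rises with age; planted within one stratum
    K = ladder.n_strata
    age1 = ladder.age_of(1)
    truth["family_id"] = ""
    truth["true_founder_ps"] = truth["true_raw_ps"]
    fam_counter = 0
    normal = truth[~truth.is_hdf_case & ~truth.is_contaminant_case]
    for r in sorted(counts):
        idx = list(normal[normal.true_raw_ps == r].index)
        p_multi = 0.2 + 0.6 * (ladder.age_of(r) / age1) ** 0.35
        n_multi = int(round(p_multi * len(idx)))
        pool = list(rng.permutation(idx)[:n_multi])
        while len(pool) >= 2:
            size = int(rng.integers(2, 4)) if len(pool) >= 3 else 2
            members, pool = pool[:size], pool[size:]
            fam_counter += 1
            truth.loc[members, "family_id"] = f"fam{fam_counter:04d}"
    # cross-stratum families exercise founder propagation: the younger member
    # inherits the older member's stratum as its founder age
    singles = truth[(truth.family_id == "") & ~truth.is_hdf_case
                    & ~truth.is_contaminant_case]
    old_pool = list(singles[singles.true_raw_ps.between(2, 10)].index)
    young_pool = list(singles[singles.true_raw_ps.between(11, K)].index)
    rng.shuffle(old_pool)
    rng.shuffle(young_pool)
    for k in range(min(params.cross_rank_families, len(old_pool), len(young_pool))):
        fam_counter += 1
        fid = f"fam{fam_counter:04d}"
        o, y = old_pool[k], young_pool[k]
        truth.loc[[o, y], "family_id"] = fid
        truth.loc[y, "true_founder_ps"] = truth.loc[o, "true_raw_ps"]
    solo = truth.index[truth.family_id == ""]
    for j, i in enumerate(solo, start=1):
        truth.loc[i, "family_id"] = f"solo{j:04d}"
    truth.loc[truth.is_contaminant_case, "true_founder_ps"] = -1
    truth["expected_status"] = "confident"
    truth.loc[truth.is_hdf_case, "expected_status"] = "hdf_uncertain"
    truth.loc[truth.is_contaminant_case, "expected_status"] = \
        "excluded_low_representativeness"
    return truth


def _make_hits(truth: pd.DataFrame, ladder: PhylostratumLadder,
               params: SimulationParams, rng: np.random.Generator,
               ) -> pd.DataFrame:
    """Hit rows encoding the planted ages through exponential bitscore decay."""
    K = ladder.n_strata
    focal_taxon = ladder.names[-1]
    rows = []
    for rec in truth.itertuples():
        g = rec.gene_id
        a = float(rng.uniform(*params.bitscore_a_range))
        if rec.is_contaminant_case:
            s = int(rng.integers(1, params.n_subclades + 1))
            score = float(rng.uniform(60, 120))
            rows.append(_hit_row(g, f"t_r01_s{s}", score, rng))
            rows.append(_hit_row(g, focal_taxon, a, rng))
            continue
        r0 = int(rec.true_raw_ps)
        if rec.is_hdf_case:
            s_det = float(rng.uniform(*params.hdf_detected_score))
            b = np.log(a / s_det) / _decay_distance(r0, ladder)
        elif r0 == 1:
            b = np.log(a / params.outgroup_target_score) / ladder.age_of(1)
        elif r0 < K:
            b = np.log(a / params.outgroup_target_score) / ladder.age_of(r0 - 1)
        else:
            b = 0.0  # focal-only gene; no outgroup hits at all
        for r in range(r0, K):
            if r == r0:
                m = int(rng.integers(params.deep_coverage[0],
                                     params.deep_coverage[1] + 1))
            else:
                m = int(rng.integers(1, 3))
            subclades = rng.choice(params.n_subclades, size=m, replace=False) + 1
            d = _decay_distance(r, ladder)
            for s in subclades:
                score = a * np.exp(-b * d) + rng.normal(0, params.bitscore_noise_sd)
                rows.append(_hit_row(g, f"t_r{r:02d}_s{s}", max(score, 5.0), rng))
        self_score = a + rng.normal(0, params.bitscore_noise_sd)
        rows.append(_hit_row(g, focal_taxon, max(self_score, 5.0), rng))
    return pd.DataFrame(rows)


def _make_self_hits(truth: pd.DataFrame,
                    rng: np.random.Generator) -> list[tuple[str, str, float]]:
    triples = []
    for fid, members in truth.groupby("family_id")["gene_id"]:
        ms = sorted(members)
        for i in range(len(ms)):
            triples.append((ms[i], ms[i], 1e-180))
            for j in range(i + 1, len(ms)):
                triples.append((ms[i], ms[j], 1e-120 * 10 ** float(rng.uniform(0, 20))))
    return sorted(triples)


def _make_gene_models(truth: pd.DataFrame, ladder: PhylostratumLadder,
                      rng: np.random.Generator) -> tuple[str, str, pd.DataFrame]:
    """GFF3 + protein FASTA with age-correlated CDS length and exon count."""
    age1 = ladder.age_of(1)
    gff = ["##gff-version 3"]
    fasta = []
    cds_list, exon_list = [], []
    cursor: dict[str, int] = {}
    for rec in truth.itertuples():
        r = int(rec.true_raw_ps) if rec.true_raw_ps >= 1 else ladder.n_strata
        rel_age = ladder.age_of(r) / age1
        target_cds = 1000.0 + 800.0 * rel_age ** 0.5
        cds = int(3 * max(30, round(rng.lognormal(np.log(target_cds), 0.35) / 3)))
        exons = int(max(1, rng.poisson(3.0 + 5.3 * rel_age ** 0.5)))
        cds_list.append(cds)
        exon_list.append(exons)
        chrom = f"chr{(rec.Index % 5) + 1}"
        start = cursor.get(chrom, 1)
        strand = "+" if rng.random() < 0.5 else "-"
        seg = cds // exons
        seg_lengths = [seg] * exons
        seg_lengths[-1] += cds - seg * exons
        spans = []
        pos = start
        for L in seg_lengths:
            spans.append((pos, pos + L - 1))
            pos += L + 100
        end = spans[-1][1]
        cursor[chrom] = end + 500
        g = rec.gene_id
        gff.append(f"{chrom}\tsim\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={g}")
        isoforms = [(f"{g}.t1", spans)]
        if rng.random() < 0.3 and exons > 1:
            # decoy shorter isoform: drops the last exon
            short = spans[:-1]
            isoforms.append((f"{g}.t2", short))
        for tid, tspans in isoforms:
            t_cds = sum(b - a0 + 1 for a0, b in tspans)
            gff.append(f"{chrom}\tsim\tmRNA\t{tspans[0][0]}\t{tspans[-1][1]}"
                       f"\t.\t{strand}\t.\tID={tid};Parent={g}")
            for a0, b in tspans:
                gff.append(f"{chrom}\tsim\texon\t{a0}\t{b}\t.\t{strand}\t.\tParent={tid}")
                gff.append(f"{chrom}\tsim\tCDS\t{a0}\t{b}\t.\t{strand}\t0\tParent={tid}")
            plen = t_cds // 3 - 1
            seq = "".join(_AAS[i] for i in rng.integers(0, len(_AAS), size=max(plen, 1)))
            fasta.append(f">{tid}\n{seq}")
    out = truth[["gene_id"]].copy()
    out["true_cds"] = cds_list
    out["true_exons"] = exon_list
    return "\n".join(gff) + "\n", "\n".join(fasta) + "\n", out


def _make_tissue_matrix(truth: pd.DataFrame, ladder: PhylostratumLadder,
                        params: SimulationParams, rng: np.random.Generator,
                        ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """TPM matrix with planted breadth and tissue specificity."""
    age1 = ladder.age_of(1)
    K = ladder.n_strata
    n_t = len(TISSUES)
    samples = [f"{t}_rep{i+1}" for t in TISSUES for i in range(params.n_replicates)]
    meta = pd.DataFrame({
        "sample": samples,
        "tissue": [s.rsplit("_rep", 1)[0] for s in samples],
        "stage": "mixed", "condition": "none",
    }).set_index("sample")

    values = np.zeros((len(truth), len(samples)))
    breadth_class, peak_tissues = [], []
    brain = TISSUES.index("brain")
    for i, rec in enumerate(truth.itertuples()):
        r = int(rec.true_founder_ps) if rec.true_founder_ps >= 1 else K
        is_new = r >= K - 3
        p_silent = 0.10 if is_new else 0.04
        if rng.random() < p_silent:
            breadth_class.append(0)
            peak_tissues.append("none")
            continue
        rel_age = ladder.age_of(r) / age1
        mu = 1.5 + 11.0 * rel_age ** 0.4
        breadth = int(np.clip(round(rng.normal(mu, 2.0)), 1, n_t))
        if is_new:
            breadth = int(np.clip(breadth, 1, 3))
        if is_new and breadth <= 2 and rng.random() < params.brain_bias:
            peak = brain
        else:
            peak = int(rng.integers(0, n_t))
        others = [t for t in range(n_t) if t != peak]
        chosen = [peak] + list(rng.choice(others, size=breadth - 1, replace=False))
        breadth_class.append(breadth)
        peak_tissues.append(TISSUES[peak])
        for t in chosen:
            base = (3.0 + rng.lognormal(np.log(40.0), 0.5) if t == peak
                    else 3.0 + rng.lognormal(np.log(4.0), 0.6))
            for j in range(params.n_replicates):
                col = t * params.n_replicates + j
                values[i, col] = base * np.exp(rng.normal(0, params.expr_noise_sd))
    tpm = pd.DataFrame(values, index=list(truth.gene_id), columns=samples)
    expr_truth = pd.DataFrame({"gene_id": truth.gene_id,
                               "breadth_class": breadth_class,
                               "peak_tissue": peak_tissues})
    return ExpressionMatrix(values=tpm, sample_meta=meta), expr_truth


def _make_stress(truth: pd.DataFrame, ladder: PhylostratumLadder,
                 params: SimulationParams, rng: np.random.Generator,
                 ) -> tuple[dict[str, tuple[pd.DataFrame, dict[str, str]]], pd.DataFrame]:
    K = ladder.n_strata
    genes = list(truth.gene_id)
    n = len(genes)
    baseline = np.maximum(rng.lognormal(np.log(150.0), 1.2, size=n), 1.0)
    founder = truth.true_founder_ps.values
    is_new = founder >= K - 3
    eligible = baseline >= 50.0
    deg_truth = pd.DataFrame({"gene_id": genes})
    stress = {}
    plan = {"parasitization": (15, 60), "pesticide_A": (30, 70),
            "virus": (12, 50), "host_plant": (10, 55)}
    for contrast, (n_new_deg, n_old_deg) in plan.items():
        new_idx = np.flatnonzero(is_new & eligible)
        old_idx = np.flatnonzero(~is_new & eligible)
        chosen_new = rng.choice(new_idx, size=min(n_new_deg, len(new_idx)),
                                replace=False)
        chosen_old = rng.choice(old_idx, size=min(n_old_deg, len(old_idx)),
                                replace=False)
        chosen = np.concatenate([chosen_new, chosen_old])
        up = rng.random(len(chosen)) < 0.7  # most stress responses upregulated
        mean_t = baseline.copy()
        mean_t[chosen[up]] *= params.de_fold
        mean_t[chosen[~up]] /= params.de_fold
        nb_n = 1.0 / params.nb_dispersion
        reps = params.n_stress_reps

        def draw(mean: np.ndarray) -> np.ndarray:
            p = nb_n / (nb_n + mean[:, None])
            return rng.negative_binomial(nb_n, np.broadcast_to(p, (n, reps)))

        treated = [f"{contrast}_T{i+1}" for i in range(reps)]
        control = [f"{contrast}_C{i+1}" for i in range(reps)]
        counts = pd.DataFrame(np.hstack([draw(mean_t), draw(baseline)]),
                              index=genes, columns=treated + control)
        groups = {s: "treated" for s in treated} | {s: "control" for s in control}
        stress[contrast] = (counts, groups)
        col = np.array(["none"] * n, dtype=object)
        col[chosen[up]] = "up"
        col[chosen[~up]] = "down"
        deg_truth[f"deg_{contrast}"] = col
    return stress, deg_truth


def simulate_cohort(params: SimulationParams | None = None,
                    seed: int = 0) -> SyntheticCohort:
    """Generate every pipeline input for one synthetic cohort, with truth."""
    params = params or SimulationParams()
    params.validate()
    ladder = default_ladder()
    if ladder.n_strata < 4:
        raise ValueError("ladder must have at least 4 strata")
    rng = np.random.default_rng(seed)

    truth = _plan_genes(ladder, params, rng)
    if len(truth) < 100:
        raise ValueError("cohort must contain at least 100 genes")
    lineages = make_lineages(ladder, params.n_subclades)
    hit_rows = _make_hits(truth, ladder, params, rng)
    hits = [HomologyHit(query_gene=r.qseqid, subject_taxon=r.staxid,
                        bitscore=float(r.bitscore), evalue=float(r.evalue))
            for r in hit_rows.itertuples()]
    self_hits = _make_self_hits(truth, rng)
    gff3_text, fasta_text, model_truth = _make_gene_models(truth, ladder, rng)
    tissue_matrix, expr_truth = _make_tissue_matrix(truth, ladder, params, rng)
    stress, deg_truth = _make_stress(truth, ladder, params, rng)

    # co-expression: block1 carries planted young hub genes
    K = ladder.n_strata
    young = list(truth[(truth.true_founder_ps >= K - 3)
                       & ~truth.is_contaminant_case].gene_id)[:params.n_young_hubs]
    old_pool = list(truth[(truth.true_founder_ps.between(1, 8))
                          & ~truth.is_hdf_case].gene_id)
    b1 = young + old_pool[:params.coexpr_block - len(young)]
    b2 = old_pool[params.coexpr_block:2 * params.coexpr_block]
    noise = old_pool[2 * params.coexpr_block:
                     2 * params.coexpr_block + params.coexpr_noise_genes]
    coexpr_expr, coexpr_traits, coexpr_truth = simulate_coexpression(
        b1, b2, noise, n_samples=params.coexpr_samples,
        noise_sd=params.coexpr_noise_sd, seed=int(rng.integers(0, 2**31)))
    coexpr_truth["is_young_hub"] = coexpr_truth.gene_id.isin(young)

    # orthologs: codon pairs with age-dependent substitution profiles
    founder = dict(zip(truth.gene_id, truth.true_founder_ps))
    new_cands = [g for g in truth.gene_id if founder[g] >= K - 3]
    old_cands = [g for g in truth.gene_id if 1 <= founder[g] < K - 3]
    n_new_pairs = min(len(new_cands), params.n_ortholog_pairs // 3)
    pair_genes = sorted(new_cands[:n_new_pairs]
                        + old_cands[:params.n_ortholog_pairs - n_new_pairs])
    fasta_parts, kaks_rows = [], []
    for g in pair_genes:
        # relaxed constraint in young genes: elevated Ka, Ks and Ka/Ks
        is_new = founder[g] >= K - 3
        n_syn = int(rng.integers(10, 15)) if is_new else int(rng.integers(6, 10))
        n_nonsyn = int(rng.integers(18, 27)) if is_new else int(rng.integers(2, 7))
        sa, sb = simulate_codon_pair(n_syn, n_nonsyn, params.codon_length, rng)
        partner = f"o_{g}"
        fasta_parts.append(f">{g}\n{sa}\n>{partner}\n{sb}")
        kaks_rows.append({"gene_a": g, "gene_b": partner,
                          "planted_syn": n_syn, "planted_nonsyn": n_nonsyn})
    kaks_truth = pd.DataFrame(kaks_rows)
    ortho_ab, ortho_ba, rbh_truth = simulate_rbh_tables(
        [(g, f"o_{g}") for g in pair_genes], seed=int(rng.integers(0, 2**31)))

    truth = (truth.merge(model_truth, on="gene_id")
                  .merge(expr_truth, on="gene_id")
                  .merge(deg_truth, on="gene_id"))
    return SyntheticCohort(
        params=params, seed=seed, ladder=ladder, lineages=lineages,
        hits=hits, hit_rows=hit_rows, self_hits=self_hits,
        gff3_text=gff3_text, fasta_text=fasta_text, truth=truth,
        tissue_matrix=tissue_matrix, stress=stress,
        coexpr_expr=coexpr_expr, coexpr_traits=coexpr_traits,
        coexpr_truth=coexpr_truth, ortho_ab=ortho_ab, ortho_ba=ortho_ba,
        rbh_truth=rbh_truth,
        codon_pairs_fasta="\n".join(fasta_parts) + "\n",
        kaks_truth=kaks_truth,
    )
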