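"""Phylostratigraphic gene-age inference.

A gene's *phylostratum* is the oldest node of the focal species' root-to-tip
taxonomic lineage at which homologs are still detectable.  The pipeline here
follows the family-aware, detection-failure-aware refinement of classical
phylostratigraphy:

1. **Raw age** — map every homology hit's taxon onto the focal lineage and take
   the oldest (smallest-rank) divergence stratum.
2. **Representativeness filter** — a gene whose hits at its assigned stratum
   cover too few of the database-represented subclades of that stratum is a
   likely contaminant or horizontal transfer and is excluded.
3. **Family clustering** — Markov clustering (MCL) of the focal proteome's
   all-vs-all similarities; each family inherits the oldest *reliable* member
   age as its founder age.
4. **Homology detection failure (HDF)** — per gene, bitscores of detected
   homologs are fit to an exponential decay in divergence time; if the
   extrapolated score in the closest outgroup beyond the founder stratum has an
   appreciable probability of lying below the detection threshold, the age call
   is flagged ``hdf_uncertain`` (the age is retained, not reassigned).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.sparse import csgraph

from .formats import HomologyHit, RunConfig

logger = logging.getLogger(__name__)

SIMILARITY_CAP = 200.0  # cap on -log10(evalue) similarity


@dataclass(frozen=True)
class PhylostratumLadder:
    """Ordered phylostrata of the focal species, rank 1 = oldest."""

    strata: tuple[tuple[int, str, float], ...]  # (rank, name, age in MYA)
    focal_species: str

    def __post_init__(self) -> None:
        ranks = [r for r, _, _ in self.strata]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError("ranks must be consecutive from 1")
        if len(self.strata) < 2:
            raise ValueError("a ladder needs at least 2 strata")
        ages = [a for _, _, a in self.strata]
        for i in range(1, len(ages)):
            if ages[i] >= ages[i - 1]:
                raise ValueError(
                    f"ages must strictly decrease with rank: "
                    f"{self.strata[i - 1][1]}={ages[i - 1]} vs {self.strata[i][1]}={ages[i]}"
                )

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    @property
    def names(self) -> list[str]:
        return [n for _, n, _ in self.strata]

    def age_of(self, rank: int) -> float:
        return self.strata[rank - 1][2]

    def rank_of(self, name: str) -> int:
        for r, n, _ in self.strata:
            if n == name:
                return r
        raise KeyError(name)


def build_ladder(focal_lineage: Sequence[str], ages: Mapping[str, float],
                 focal_species: str | None = None) -> PhylostratumLadder:
    """Assemble a :class:`PhylostratumLadder` from the focal lineage and an age table.

    ``focal_lineage`` is ordered root → tip; every name must appear in ``ages``
    and ages must strictly decrease toward the tip.
    """
    if not focal_lineage:
        raise ValueError("focal lineage is empty")
    missing = [n for n in focal_lineage if n not in ages]
    if missing:
        raise ValueError(f"strata without ages: {missing}")
    strata = tuple(
        (i + 1, name, float(ages[name])) for i, name in enumerate(focal_lineage)
    )
    return PhylostratumLadder(strata=strata,
                              focal_species=focal_species or focal_lineage[-1])


def divergence_rank(taxon_lineage: Sequence[str], ladder: PhylostratumLadder) -> int | None:
    """Rank of the most derived focal-lineage stratum containing the taxon.

    Returns ``None`` when the taxon shares no stratum with the focal lineage.
    """
    names = set(taxon_lineage)
    best = None
    for r, n, _ in ladder.strata:
        if n in names:
            best = r
    return best


def assign_raw_age(gene: str, hits: Iterable[HomologyHit],
                   lineages: Mapping[str, Sequence[str]],
                   ladder: PhylostratumLadder) -> int | None:
    """Oldest divergence stratum over a gene's hits; ``None`` if no usable hit."""
    best: int | None = None
    for hit in hits:
        lineage = lineages.get(hit.subject_taxon)
        if lineage is None:
            logger.warning("gene %s: hit taxon %s has no lineage record; ignored",
                           gene, hit.subject_taxon)
            continue
        r = divergence_rank(lineage, ladder)
        if r is None:
            logger.warning("gene %s: taxon %s shares no stratum with focal lineage",
                           gene, hit.subject_taxon)
            continue
        if best is None or r < best:
            best = r
    return best


def _subclade_label(lineage: Sequence[str], stratum_name: str, taxon: str) -> str:
    """The lineage element just below ``stratum_name``, or the taxon itself."""
    idx = list(lineage).index(stratum_name)
    return lineage[idx + 1] if idx + 1 < len(lineage) else taxon


def clade_census(lineages: Mapping[str, Sequence[str]],
                 ladder: PhylostratumLadder) -> dict[int, set[str]]:
    """Database-represented subclades per stratum.

    A taxon belongs to the census of the stratum at which it diverges from the
    focal lineage; its subclade is the lineage level immediately below that
    stratum (or the taxon itself for terminal taxa).
    """
    census: dict[int, set[str]] = {r: set() for r, _, _ in ladder.strata}
    for taxon, lineage in lineages.items():
        r = divergence_rank(lineage, ladder)
        if r is None:
            continue
        census[r].add(_subclade_label(lineage, ladder.strata[r - 1][1], taxon))
    return census


def representativeness(gene: str, hits: Iterable[HomologyHit], raw_ps: int,
                       census: Mapping[int, set[str]],
                       lineages: Mapping[str, Sequence[str]],
                       ladder: PhylostratumLadder) -> float | None:
    """Percent of the assigned stratum's database subclades covered by hits.

    Low coverage of the deepest stratum (< 30 % by default) marks putative
    contamination or horizontal transfer.  Returns ``None`` (undefined) when the
    stratum has an empty census.
    """
    available = census.get(raw_ps, set())
    if not available:
        return None
    stratum_name = ladder.strata[raw_ps - 1][1]
    covered = set()
    for hit in hits:
        lineage = lineages.get(hit.subject_taxon)
        if lineage is None:
            continue
        if divergence_rank(lineage, ladder) != raw_ps:
            continue
        covered.add(_subclade_label(lineage, stratum_name, hit.subject_taxon))
    return 100.0 * len(covered & available) / len(available)


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def mcl_cluster(similarity: np.ndarray, inflation: float = 2.0,
                prune_threshold: float = 1e-5, max_iter: int = 200,
                tol: float = 1e-6) -> list[list[int]]:
    """Markov clustering of a square symmetric non-negative similarity matrix.

    Alternates expansion (matrix self-product) and inflation (elementwise power
    followed by column re-normalization), pruning entries below
    ``prune_threshold``, until the maximum column change falls below ``tol``.
    Families are the connected components of the attractor support.  Returns a
    partition as lists of row indices.
    """
    M = np.asarray(similarity, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("similarity must be square")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("similarity must be symmetric")
    if (M < 0).any():
        raise ValueError("similarity must be non-negative")
    if inflation <= 1:
        raise ValueError("inflation must exceed 1")

    n = M.shape[0]
    M = M.copy()

    def normalize(X: np.ndarray) -> np.ndarray:
        colsum = X.sum(axis=0)
        colsum[colsum == 0] = 1.0
        return X / colsum

    M = normalize(M)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M                      # expansion
        M = np.power(M, inflation)     # inflation
        M[M < prune_threshold] = 0.0   # prune
        M = normalize(M)
        if np.abs(M - prev).max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge within %d iterations; "
                       "returning current partition", max_iter)

    support = sparse.csr_matrix((M > 0) | (M.T > 0))
    n_comp, labels = csgraph.connected_components(support, directed=False)
    families: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        families.setdefault(int(lab), []).append(idx)
    # deterministic order: by size (desc) then smallest member index
    return sorted(families.values(), key=lambda m: (-len(m), m[0]))


def similarity_from_self_hits(genes: Sequence[str],
                              self_hits: Iterable[tuple[str, str, float]],
                              cap: float = SIMILARITY_CAP) -> np.ndarray:
    """Similarity matrix for MCL from an all-vs-all hit list of (a, b, evalue).

    Similarity is ``-log10(evalue)`` capped at ``cap``; the matrix is
    symmetrized by the maximum and the diagonal set to the cap.
    """
    index = {g: i for i, g in enumerate(genes)}
    S = np.zeros((len(genes), len(genes)))
    for a, b, evalue in self_hits:
        if a not in index or b not in index:
            continue
        sim = cap if evalue <= 0 else min(-math.log10(evalue), cap)
        i, j = index[a], index[b]
        S[i, j] = max(S[i, j], sim)
        S[j, i] = max(S[j, i], sim)
    np.fill_diagonal(S, cap)
    return S


def founder_age(partition: Sequence[Sequence[str]], raw_ages: Mapping[str, int],
                status: Mapping[str, str]) -> dict[str, int | None]:
    """Propagate the oldest reliable member age to every family member.

    Reliable means status not in {excluded_low_representativeness, unassigned}.
    Families without any reliable member get ``None`` (members unassigned).
    """
    founder: dict[str, int | None] = {}
    for family in partition:
        reliable = [raw_ages[g] for g in family
                    if status.get(g, "confident") not in
                    ("excluded_low_representativeness", "unassigned")
                    and raw_ages.get(g) is not None]
        f = min(reliable) if reliable else None
        for g in family:
            founder[g] = f
    return founder


# ---------------------------------------------------------------------------
# Bitscore decay and homology detection failure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BitscoreDecayFit:
    """Least-squares fit of bitscore = a * exp(-b * distance)."""

    a: float
    b: float
    residual_sd: float
    n_points: int

    def predict(self, distance: float) -> float:
        return self.a * math.exp(-self.b * distance)


def fit_bitscore_decay(detected: Sequence[tuple[float, float]]) -> BitscoreDecayFit | None:
    """Fit an exponential bitscore decay to (distance, bitscore) points.

    Requires >= 3 points at distinct distances; returns ``None`` otherwise.
    The fit is ordinary least squares on the original score scale, initialized
    from a log-linear regression.  ``residual_sd`` is floored at ``0.01 * a``.
    """
    pts = [(float(d), float(s)) for d, s in detected]
    if len({d for d, _ in pts}) < 3:
        return None
    d = np.array([p[0] for p in pts])
    s = np.array([p[1] for p in pts])

    # log-linear initialization (exact for noiseless exponentials)
    pos = s > 0
    if pos.sum() >= 2 and len(np.unique(d[pos])) >= 2:
        slope, intercept = np.polyfit(d[pos], np.log(s[pos]), 1)
        a0 = float(np.exp(intercept))
        b0 = max(-float(slope), 0.0)
    else:
        a0, b0 = max(float(s.max()), 1e-6), 0.1

    def model(x, a, b):
        return a * np.exp(-b * x)

    try:
        (a, b), _ = optimize.curve_fit(
            model, d, s, p0=(a0, b0), bounds=([1e-12, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError:
        a, b = a0, b0
    resid = s - model(d, a, b)
    dof = max(len(pts) - 2, 1)
    sd = float(np.sqrt((resid ** 2).sum() / dof))
    sd = max(sd, 0.01 * a)
    return BitscoreDecayFit(a=float(a), b=float(b), residual_sd=sd, n_points=len(pts))


def hdf_probability(fit: BitscoreDecayFit, outgroup_distance: float,
                    detection_threshold_bitscore: float) -> float:
    """P(score < detection threshold) at the outgroup distance.

    The score at a given distance is modelled as Gaussian around the fitted
    decay curve with the fit's residual standard deviation.  A high value means
    non-detection in the outgroup is uninformative (the homolog could simply
    have decayed past the search threshold), so the age call is uncertain.
    """
    mean = fit.predict(outgroup_distance)
    return float(stats.norm.cdf(detection_threshold_bitscore, loc=mean,
                                scale=fit.residual_sd))


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class GeneAgeCall:
    """Per-gene age call with provenance of the filtering decisions."""

    gene_id: str
    raw_ps: int | None
    family_id: str | None
    founder_ps: int | None
    representativeness: float | None
    hdf_probability: float
    status: str  # confident | hdf_uncertain | excluded_low_representativeness | unassigned


def _hit_distance(rank: int, ladder: PhylostratumLadder) -> float:
    # stratum ages in MY; hits within the focal (terminal) stratum are at 0
    return 0.0 if rank == ladder.n_strata else ladder.age_of(rank)


def call_ages(genes: Sequence[str], hits: Iterable[HomologyHit],
              lineages: Mapping[str, Sequence[str]], ladder: PhylostratumLadder,
              config: RunConfig | None = None,
              self_hits: Iterable[tuple[str, str, float]] | None = None,
              ) -> list[GeneAgeCall]:
    """Run the four-step age-inference pipeline for a gene cohort.

    ``hits`` is the (already e-value-filtered) homology table against the
    taxonomically annotated database; ``self_hits`` the focal all-vs-all
    (gene_a, gene_b, evalue) triples used for family clustering.  Genes absent
    from the hit table are reported ``unassigned``.
    """
    config = config or RunConfig()
    by_gene: dict[str, list[HomologyHit]] = {g: [] for g in genes}
    for h in hits:
        if h.query_gene in by_gene:
            by_gene[h.query_gene].append(h)

    census = clade_census(lineages, ladder)

    raw: dict[str, int | None] = {}
    rep: dict[str, float | None] = {}
    status: dict[str, str] = {}
    for g in sorted(genes):
        r = assign_raw_age(g, by_gene[g], lineages, ladder)
        raw[g] = r
        if r is None:
            rep[g] = None
            status[g] = "unassigned"
            continue
        score = representativeness(g, by_gene[g], r, census, lineages, ladder)
        rep[g] = score
        if score is None:
            status[g] = "unassigned"
        elif score < config.representativeness_cutoff:
            status[g] = "excluded_low_representativeness"
        else:
            status[g] = "confident"

    # family clustering on the focal all-vs-all similarities
    order = sorted(genes)
    if self_hits is not None:
        S = similarity_from_self_hits(order, self_hits)
        partition_idx = mcl_cluster(S, inflation=config.mcl_inflation,
                                    prune_threshold=config.mcl_prune)
        partition = [[order[i] for i in members] for members in partition_idx]
    else:
        partition = [[g] for g in order]

    family_of: dict[str, str] = {}
    for k, members in enumerate(partition, start=1):
        fid = f"f{k}"
        for g in members:
            family_of[g] = fid

    founder = founder_age(partition, raw, status)
    for g in order:
        if founder[g] is None and status[g] == "confident":
            status[g] = "unassigned"

    # HDF check at the stratum one rank older than the founder stratum
    hdf_p: dict[str, float] = {g: float("nan") for g in genes}
    for g in order:
        if status[g] != "confident":
            continue
        f_ps = founder[g]
        if f_ps is None or f_ps <= 1:
            continue
        best_by_rank: dict[int, float] = {}
        for h in by_gene[g]:
            lineage = lineages.get(h.subject_taxon)
            if lineage is None:
                continue
            r = divergence_rank(lineage, ladder)
            if r is None:
                continue
            best_by_rank[r] = max(best_by_rank.get(r, 0.0), h.bitscore)
        pts = [(_hit_distance(r, ladder), s) for r, s in sorted(best_by_rank.items())]
        fit = fit_bitscore_decay(pts)
        if fit is None:
            logger.info("gene %s: <3 distinct distances, HDF probability undefined; "
                        "age kept as confident", g)
            continue
        p = hdf_probability(fit, ladder.age_of(f_ps - 1),
                            config.detection_threshold_bitscore)
        hdf_p[g] = p
        if p >= config.hdf_alpha:
            status[g] = "hdf_uncertain"

    calls = []
    for g in genes:
        r = raw[g]
        calls.append(GeneAgeCall(
            gene_id=g,
            raw_ps=r,
            family_id=family_of.get(g),
            founder_ps=founder.get(g) if status[g] != "unassigned" else None,
            representativeness=rep[g],
            hdf_probability=hdf_p[g],
            status=status[g],
        ))
    return calls


def calls_to_frame(calls: Sequence[GeneAgeCall]) -> pd.DataFrame:
    """Gene-age calls as a DataFrame in the documented column order."""
    return pd.DataFrame(
        [{
            "gene_id": c.gene_id,
            "raw_ps": c.raw_ps,
            "family_id": c.family_id,
            "founder_ps": c.founder_ps,
            "representativeness": c.representativeness,
            "hdf_probability": c.hdf_probability,
            "status": c.status,
        } for c in calls],
        columns=["gene_id", "raw_ps", "family_id", "founder_ps",
                 "representativeness", "hdf_probability", "status"],
    )


def write_gene_ages(path: str | Path, calls: Sequence[GeneAgeCall]) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_families(path: str | Path, calls: Sequence[GeneAgeCall]) -> None:
    df = calls_to_frame(calls)[["family_id", "gene_id"]].sort_values(
        ["family_id", "gene_id"], key=lambda s: s.map(str))
    df.to_csv(path, sep="\t", index=False)
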