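"""Per-stratum genomic feature statistics and age-trend tests.

Gene birth rates divide the number of genes founded in a stratum by the length
of the preceding time interval; structural trends (CDS length, exon count,
copy number) are compared across strata with rank-based tests.  "Gene age" in
correlations means the stratum age in MY unless noted; the rank index is
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ages import GeneAgeCall, PhylostratumLadder
from .formats import GeneModel


@dataclass(frozen=True)
class StratumSummary:
    rank: int
    n_genes: int
    birth_rate: float          # genes / MY
    mean_cds: float            # bp, NaN when no genes carry models
    mean_exons: float
    pct_multicopy: float       # percent, NaN when no genes


def _assigned(calls: Sequence[GeneAgeCall]) -> list[GeneAgeCall]:
    return [c for c in calls
            if c.founder_ps is not None
            and c.status not in ("excluded_low_representativeness", "unassigned")]


def birth_rates(calls: Sequence[GeneAgeCall], ladder: PhylostratumLadder,
                models: Mapping[str, GeneModel] | None = None,
                family_sizes: Mapping[str, int] | None = None,
                ) -> tuple[list[StratumSummary], float, list[int]]:
    """Per-stratum summaries plus the mean birth rate and above-mean ("peak") ranks.

    For rank r > 1 the rate is n_genes(r) / (age(r-1) - age(r)); rank 1 uses its
    own age as the interval.  Returns (summaries, mean_rate, peak_ranks).
    """
    usable = _assigned(calls)
    counts = {r: 0 for r, _, _ in ladder.strata}
    for c in usable:
        counts[c.founder_ps] += 1

    summaries = []
    rates = []
    for r, _, age in ladder.strata:
        if r == 1:
            interval = age
        else:
            interval = ladder.age_of(r - 1) - age
        if interval <= 0:
            raise ValueError(f"zero-length interval at rank {r}")
        rate = counts[r] / interval
        rates.append(rate)
        members = [c for c in usable if c.founder_ps == r]
        if models:
            cds = [models[c.gene_id].cds_length for c in members if c.gene_id in models]
            exn = [models[c.gene_id].exon_count for c in members if c.gene_id in models]
        else:
            cds, exn = [], []
        if family_sizes and members:
            multi = sum(family_sizes.get(c.gene_id, 1) >= 2 for c in members)
            pct_multi = 100.0 * multi / len(members)
        else:
            pct_multi = float("nan")
        summaries.append(StratumSummary(
            rank=r, n_genes=counts[r], birth_rate=rate,
            mean_cds=float(np.mean(cds)) if cds else float("nan"),
            mean_exons=float(np.mean(exn)) if exn else float("nan"),
            pct_multicopy=pct_multi,
        ))
    mean_rate = float(np.mean(rates))
    peaks = [s.rank for s in summaries if s.birth_rate > mean_rate]
    return summaries, mean_rate, peaks


def family_sizes_from_calls(calls: Sequence[GeneAgeCall]) -> dict[str, int]:
    """Map gene -> size of its family (singletons = 1)."""
    sizes: dict[str, int] = {}
    for c in calls:
        if c.family_id is not None:
            sizes[c.family_id] = sizes.get(c.family_id, 0) + 1
    return {c.gene_id: sizes.get(c.family_id, 1) for c in calls}


def copy_number_trend(calls: Sequence[GeneAgeCall], ladder: PhylostratumLadder,
                      ) -> tuple[pd.DataFrame, float, float]:
    """Per-rank multicopy percentage and its Spearman correlation with gene age.

    Multicopy means family size >= 2.  Age is recoded so that older strata have
    larger values (their age in MY), matching the convention that a positive
    correlation means "older genes are more often multicopy".  Ranks without
    genes are skipped; rho is NaN when fewer than 3 ranks remain or the
    percentages are constant.
    """
    fam_size = family_sizes_from_calls(calls)
    usable = _assigned(calls)
    rows = []
    for r, _, age in ladder.strata:
        members = [c for c in usable if c.founder_ps == r]
        if not members:
            continue
        pct = 100.0 * sum(fam_size[c.gene_id] >= 2 for c in members) / len(members)
        rows.append({"rank": r, "age_mya": age, "pct_multicopy": pct,
                     "n_genes": len(members)})
    df = pd.DataFrame(rows, columns=["rank", "age_mya", "pct_multicopy", "n_genes"])
    if len(df) < 3 or df["pct_multicopy"].nunique() == 1:
        return df, float("nan"), float("nan")
    rho, p = stats.spearmanr(df["age_mya"], df["pct_multicopy"])
    return df, float(rho), float(p)


def newgene_length_permutation(models: Mapping[str, GeneModel],
                               calls: Sequence[GeneAgeCall],
                               new_ranks: set[int], n_perm: int = 10000,
                               seed: int = 0) -> tuple[float, float, float]:
    """Permutation test for shorter-than-expected CDS length of new genes.

    Observed statistic: mean CDS length of genes with founder stratum in
    ``new_ranks``.  Null: means of ``n_perm`` random gene sets of the same size
    drawn from the whole cohort.  One-sided add-one p-value for "shorter than
    expected": (1 + #{perm mean <= observed}) / (n_perm + 1).
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be at least 1000")
    usable = [c for c in _assigned(calls) if c.gene_id in models]
    lengths = np.array([models[c.gene_id].cds_length for c in usable], dtype=float)
    is_new = np.array([c.founder_ps in new_ranks for c in usable])
    n_new = int(is_new.sum())
    if n_new == 0:
        raise ValueError("new-gene set is empty")
    observed = float(lengths[is_new].mean())
    rng = np.random.default_rng(seed)
    perm_means = np.empty(n_perm)
    for i in range(n_perm):
        perm_means[i] = lengths[rng.choice(len(lengths), size=n_new, replace=False)].mean()
    expected = float(perm_means.mean())
    p = (1 + int((perm_means <= observed).sum())) / (n_perm + 1)
    return observed, expected, float(p)


def age_feature_tests(models: Mapping[str, GeneModel], calls: Sequence[GeneAgeCall],
                      ladder: PhylostratumLadder, new_ranks: set[int],
                      old_rank: int = 1) -> dict:
    """Structural-feature vs. age report.

    Per-rank mean CDS/exon counts; Pearson correlation of per-rank mean CDS
    against stratum age (per-gene correlation also reported); one-sided
    Wilcoxon rank-sum tests that new genes have smaller CDS length and fewer
    exons than genes of ``old_rank``.
    """
    usable = [c for c in _assigned(calls) if c.gene_id in models]
    if len({c.founder_ps for c in usable}) < 2:
        raise ValueError("need at least 2 populated strata")
    df = pd.DataFrame({
        "gene_id": [c.gene_id for c in usable],
        "founder_ps": [c.founder_ps for c in usable],
        "cds": [models[c.gene_id].cds_length for c in usable],
        "exons": [models[c.gene_id].exon_count for c in usable],
    })
    df["age_mya"] = df["founder_ps"].map({r: a for r, _, a in ladder.strata})
    per_rank = (df.groupby("founder_ps")
                  .agg(n=("gene_id", "size"), mean_cds=("cds", "mean"),
                       mean_exons=("exons", "mean"), age_mya=("age_mya", "first"))
                  .reset_index())

    def safe_pearson(x, y):
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            return float("nan"), float("nan")
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)

    r_rank, p_rank = safe_pearson(per_rank["age_mya"], per_rank["mean_cds"])
    r_gene, p_gene = safe_pearson(df["age_mya"], df["cds"])

    new = df[df["founder_ps"].isin(new_ranks)]
    old = df[df["founder_ps"] == old_rank]
    tests = {}
    for feature in ("cds", "exons"):
        if len(new) and len(old):
            stat, p = stats.mannwhitneyu(new[feature], old[feature],
                                         alternative="less")
            tests[feature] = {"U": float(stat), "p_one_sided": float(p),
                              "new_mean": float(new[feature].mean()),
                              "old_mean": float(old[feature].mean())}
        else:
            tests[feature] = {"U": float("nan"), "p_one_sided": float("nan"),
                              "new_mean": float("nan"), "old_mean": float("nan")}
    return {
        "per_rank": per_rank,
        "cds_age_pearson_per_rank": {"R": r_rank, "p": p_rank},
        "cds_age_pearson_per_gene": {"R": r_gene, "p": p_gene},
        "wilcoxon_new_vs_old": tests,
    }
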