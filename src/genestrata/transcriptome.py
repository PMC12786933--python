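"""Expression breadth, tissue specificity (tau) and the transcriptome age index.

tau summarizes how concentrated a gene's expression is across tissues
(0 = uniform, 1 = single-tissue); the transcriptome age index (TAI) is the
expression-weighted mean phylostratum rank of a sample, so high TAI marks
transcriptomes skewed toward evolutionarily young genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ages import GeneAgeCall
from .formats import RunConfig


@dataclass
class ExpressionMatrix:
    """Genes × samples TPM matrix with per-sample metadata.

    ``sample_meta`` is indexed by sample id and must carry a ``tissue`` column;
    ``stage`` and ``condition`` columns are optional.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("TPM values must be non-negative")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    def tissue_means(self) -> pd.DataFrame:
        """Collapse replicates to tissues by arithmetic mean TPM."""
        tissues = self.sample_meta.loc[self.values.columns, "tissue"]
        if tissues.isna().any():
            raise ValueError("samples with missing tissue label")
        out = self.values.T.groupby(tissues.values).mean().T
        return out.reindex(sorted(out.columns), axis=1)


@dataclass(frozen=True)
class TauResult:
    gene_id: str
    tau: float
    peak_tissue: str
    is_specific: bool


@dataclass(frozen=True)
class TAIResult:
    sample_or_tissue: str
    tai: float


def expression_breadth(matrix: ExpressionMatrix, tpm_cutoff: float = 1.0,
                       broad_cutoff: int = 10) -> pd.DataFrame:
    """Number of tissues in which each gene is expressed (mean TPM strictly > cutoff).

    Returns a frame with columns breadth and is_broad (breadth >= broad_cutoff).
    """
    means = matrix.tissue_means()
    breadth = (means > tpm_cutoff).sum(axis=1)
    return pd.DataFrame({
        "breadth": breadth.astype(int),
        "is_broad": breadth >= broad_cutoff,
    })


def tau_index(matrix: ExpressionMatrix, log_transform: bool = True,
              specific_cutoff: float = 0.8) -> list[TauResult]:
    """Per-gene tissue-specificity index tau.

    With per-tissue means x_i (log2(TPM+1)-transformed by default) and
    x̂_i = x_i / max_i x_i, tau = Σ(1 − x̂_i) / (n − 1).  Genes with all-zero
    expression are skipped; a single-tissue matrix makes tau undefined.
    """
    means = matrix.tissue_means()
    if means.shape[1] < 2:
        raise ValueError("tau undefined with a single tissue")
    X = np.log2(means + 1.0) if log_transform else means.copy()
    results = []
    n = X.shape[1]
    for gene, row in X.iterrows():
        mx = row.max()
        if mx <= 0:
            continue  # all-zero gene
        xhat = row / mx
        tau = float((1.0 - xhat).sum() / (n - 1))
        results.append(TauResult(
            gene_id=str(gene), tau=tau, peak_tissue=str(row.idxmax()),
            is_specific=tau > specific_cutoff,
        ))
    return results


def transcriptome_age_index(matrix: ExpressionMatrix,
                            calls: Sequence[GeneAgeCall],
                            per_tissue: bool = True) -> list[TAIResult]:
    """Expression-weighted mean phylostratum rank, TAI = Σ(PS_i · e_i) / Σ e_i.

    Computed over genes with positive expression and an assigned founder
    stratum; genes without an age call are excluded (count logged via the
    return of fewer genes).  Per-sample values always reported; per-tissue
    values (replicates averaged first) appended when ``per_tissue``.
    """
    ps = pd.Series({c.gene_id: c.founder_ps for c in calls
                    if c.founder_ps is not None}, dtype=float)
    results: list[TAIResult] = []

    def _tai(frame: pd.DataFrame, labels: Sequence[str]) -> None:
        common = frame.index.intersection(ps.index)
        sub = frame.loc[common]
        ranks = ps.loc[common].values
        for col in labels:
            e = sub[col].values
            mask = e > 0
            if not mask.any():
                results.append(TAIResult(sample_or_tissue=str(col), tai=float("nan")))
                continue
            tai = float(np.sum(ranks[mask] * e[mask]) / np.sum(e[mask]))
            results.append(TAIResult(sample_or_tissue=str(col), tai=tai))

    _tai(matrix.values, list(matrix.values.columns))
    if per_tissue:
        means = matrix.tissue_means()
        _tai(means, list(means.columns))
    return results


def age_expression_report(matrix: ExpressionMatrix, calls: Sequence[GeneAgeCall],
                          new_ranks: set[int], config: RunConfig | None = None) -> dict:
    """Age-stratified expression comparisons.

    (i) hypergeometric over-representation of expressed genes among new genes;
    (ii) one-sided Wilcoxon tests: new genes have smaller breadth and larger
    tau than old genes; (iii) chi-square comparison of peak-tissue
    distributions between tissue-specific new and old genes (cells with
    expected count < 1 pooled into an "other" bin).
    """
    config = config or RunConfig()
    founder = {c.gene_id: c.founder_ps for c in calls if c.founder_ps is not None}
    genes = [g for g in matrix.values.index if g in founder]
    is_new = {g: founder[g] in new_ranks for g in genes}

    # (i) expressed anywhere (any sample TPM > cutoff)
    expressed = (matrix.values.loc[genes] > config.expressed_tpm_cutoff).any(axis=1)
    M = len(genes)                       # population
    K = int(expressed.sum())             # expressed genes
    n_draw = sum(is_new.values())        # new genes
    k_obs = int(expressed[[g for g in genes if is_new[g]]].sum())
    p_hyper = float(stats.hypergeom.sf(k_obs - 1, M, K, n_draw)) if n_draw else float("nan")

    breadth = expression_breadth(matrix, config.expressed_tpm_cutoff,
                                 config.broad_tissue_cutoff).loc[genes]
    taus = {t.gene_id: t for t in tau_index(matrix,
                                            specific_cutoff=config.tau_specific_cutoff)}

    new_genes = [g for g in genes if is_new[g]]
    old_genes = [g for g in genes if not is_new[g]]

    def wilcoxon(vals_new, vals_old, alternative):
        if len(vals_new) == 0 or len(vals_old) == 0:
            return float("nan")
        _, p = stats.mannwhitneyu(vals_new, vals_old, alternative=alternative)
        return float(p)

    p_breadth = wilcoxon(breadth.loc[new_genes, "breadth"],
                         breadth.loc[old_genes, "breadth"], "less")
    tau_new = [taus[g].tau for g in new_genes if g in taus]
    tau_old = [taus[g].tau for g in old_genes if g in taus]
    p_tau = wilcoxon(tau_new, tau_old, "greater")

    # (iii) peak-tissue distribution of tissue-specific genes
    spec_new = [taus[g].peak_tissue for g in new_genes
                if g in taus and taus[g].is_specific]
    spec_old = [taus[g].peak_tissue for g in old_genes
                if g in taus and taus[g].is_specific]
    chi_p, pooled = float("nan"), False
    if spec_new and spec_old:
        tissues = sorted(set(spec_new) | set(spec_old))
        table = np.array([[spec_new.count(t) for t in tissues],
                          [spec_old.count(t) for t in tissues]], dtype=float)
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        weak = expected.min(axis=0) < 1.0
        if weak.any() and (~weak).sum() >= 1:
            pooled = True
            kept = table[:, ~weak]
            other = table[:, weak].sum(axis=1, keepdims=True)
            table = np.hstack([kept, other]) if other.sum() else kept
        if table.shape[1] >= 2:
            _, chi_p, _, _ = stats.chi2_contingency(table)
            chi_p = float(chi_p)

    return {
        "hypergeom_expressed_new": {
            "population": M, "expressed": K, "new": n_draw,
            "expressed_new": k_obs, "p": p_hyper,
        },
        "wilcoxon_breadth_p": p_breadth,
        "wilcoxon_tau_p": p_tau,
        "mean_breadth_new": float(breadth.loc[new_genes, "breadth"].mean())
            if new_genes else float("nan"),
        "mean_breadth_old": float(breadth.loc[old_genes, "breadth"].mean())
            if old_genes else float("nan"),
        "mean_tau_new": float(np.mean(tau_new)) if tau_new else float("nan"),
        "mean_tau_old": float(np.mean(tau_old)) if tau_old else float("nan"),
        "chi_square_peak_tissue": {"p": chi_p, "cells_pooled": pooled,
                                   "n_specific_new": len(spec_new),
                                   "n_specific_old": len(spec_old)},
    }
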