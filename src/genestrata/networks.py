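"""Stress-response differential expression and weighted co-expression networks.

The DE routine is a deliberately simple, self-contained stand-in for
negative-binomial tools: median-of-ratios library-size normalization, a
per-gene t-test on log2(normalized+1) values with empirical-Bayes
variance moderation toward the mean–variance trend (the limma-trend idea;
indispensable for power at 3–4 replicates per group), and Benjamini–Hochberg
FDR control.  Real-data users can instead ingest externally produced
per-contrast result tables through :func:`contrast_results_from_table`.

The network follows the weighted co-expression recipe: soft-thresholded
absolute correlation adjacency, unsigned topological overlap (TOM),
average-linkage clustering of 1−TOM with a static height cut, module
eigengenes as first principal components, kME membership and module–trait
correlations with hub calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .ages import GeneAgeCall
from .formats import RunConfig

GREY = "grey"


@dataclass(frozen=True)
class ContrastResult:
    gene_id: str
    contrast: str
    log2fc: float
    fdr: float
    is_deg: bool
    direction: str  # up | down | none
    pvalue: float = float("nan")  # raw p; NaN for externally ingested tables


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (reference = geometric mean over samples)."""
    log_counts = np.log(counts.replace(0, np.nan))
    log_ref = log_counts.mean(axis=1)
    usable = log_ref.notna()
    if not usable.any():
        raise ValueError("no gene is positive in every sample")
    ratios = log_counts.loc[usable].sub(log_ref[usable], axis=0)
    sf = np.exp(ratios.median(axis=0, skipna=True))
    return sf / np.exp(np.log(sf).mean())


def _trigamma_inverse(x: float) -> float:
    """Solve psi'(y) = x by Newton iteration (Smyth's moment estimator)."""
    from scipy import special
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        step = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y -= step
        if abs(step) < 1e-8:
            break
    return float(y)


def _moderated_t(y_t: np.ndarray, y_c: np.ndarray, abundance: np.ndarray,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Trend-moderated two-sample t-test (limma-trend style).

    Per-gene pooled variances are shrunk toward a lowess fit of log variance
    against mean abundance; the prior degrees of freedom come from the moment
    estimator on the log-variance residuals.  Returns (log2fc, p-values).
    """
    from scipy import special
    from statsmodels.nonparametric.smoothers_lowess import lowess

    n1, n2 = y_t.shape[1], y_c.shape[1]
    d = n1 + n2 - 2
    delta = y_t.mean(axis=1) - y_c.mean(axis=1)
    ss = (((y_t - y_t.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
          + ((y_c - y_c.mean(axis=1, keepdims=True)) ** 2).sum(axis=1))
    s2 = ss / d
    z = np.log(s2 + 1e-10)
    fit = lowess(z, abundance, frac=0.4, return_sorted=False)
    # Jensen bias of E[log s^2] under chi^2_d
    bias = special.digamma(d / 2.0) - np.log(d / 2.0)
    s0sq = np.exp(fit - bias)
    var_z = float(np.var(z - fit))
    excess = var_z - special.polygamma(1, d / 2.0)
    if excess > 1e-6:
        d0 = 2.0 * _trigamma_inverse(excess)
        s2_mod = (d0 * s0sq + d * s2) / (d0 + d)
        df_total = d0 + d
    else:
        s2_mod, df_total = s0sq, 1e6  # variances fully explained by the trend
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    tstat = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    return delta, pvals


def simple_de(counts: pd.DataFrame, groups: Mapping[str, str],
              contrast: str = "treated_vs_control",
              config: RunConfig | None = None) -> list[ContrastResult]:
    """Moderated-t differential expression between treated and control samples.

    ``groups`` maps sample id -> {"treated", "control"}; each group needs at
    least 2 samples.  Genes with zero counts in every sample are excluded.
    log2fc is treated minus control on the log2(normalized+1) scale.
    """
    config = config or RunConfig()
    samples = [s for s in counts.columns if s in groups]
    treated = [s for s in samples if groups[s] == "treated"]
    control = [s for s in samples if groups[s] == "control"]
    if len(treated) < 2 or len(control) < 2:
        raise ValueError("need >= 2 samples per group")
    sub = counts[treated + control]
    nonzero = sub.sum(axis=1) > 0
    sub = sub.loc[nonzero]
    sf = size_factors(sub)
    norm = sub.div(sf, axis=1)
    logx = np.log2(norm + 1.0)
    x_t = logx[treated].values
    x_c = logx[control].values
    lfc, pvals = _moderated_t(x_t, x_c, logx.values.mean(axis=1))
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    results = []
    for gene, l2, q, p in zip(sub.index, lfc, fdrs, pvals):
        deg = bool(q < config.de_fdr and abs(l2) >= config.de_abs_lfc)
        direction = "none" if not deg else ("up" if l2 > 0 else "down")
        results.append(ContrastResult(gene_id=str(gene), contrast=contrast,
                                      log2fc=float(l2), fdr=float(q),
                                      is_deg=deg, direction=direction,
                                      pvalue=float(p)))
    return results


def contrast_results_from_table(df: pd.DataFrame, contrast: str,
                                config: RunConfig | None = None) -> list[ContrastResult]:
    """Ingest an external DE table with columns gene_id, log2fc, fdr."""
    config = config or RunConfig()
    out = []
    for r in df.itertuples():
        deg = bool(r.fdr < config.de_fdr and abs(r.log2fc) >= config.de_abs_lfc)
        direction = "none" if not deg else ("up" if r.log2fc > 0 else "down")
        out.append(ContrastResult(gene_id=str(r.gene_id), contrast=contrast,
                                  log2fc=float(r.log2fc), fdr=float(r.fdr),
                                  is_deg=deg, direction=direction))
    return out


def newgene_deg_summary(contrasts: Sequence[ContrastResult],
                        calls: Sequence[GeneAgeCall], new_ranks: set[int],
                        contrast_class: Mapping[str, str] | None = None,
                        ) -> dict:
    """Counts of differentially expressed new genes per contrast and overall.

    ``contrast_class`` optionally maps contrast name -> experiment class
    (e.g. parasitization / pesticide / virus / host_plant) for per-class totals.
    A gene DE in several contrasts counts once in the union.
    """
    new_genes = {c.gene_id for c in calls
                 if c.founder_ps is not None and c.founder_ps in new_ranks}
    per_contrast: dict[str, dict] = {}
    union: set[str] = set()
    for r in contrasts:
        rec = per_contrast.setdefault(r.contrast, {"n_deg": 0, "up": 0, "down": 0})
        if r.is_deg and r.gene_id in new_genes:
            rec["n_deg"] += 1
            rec[r.direction] += 1
            union.add(r.gene_id)
    per_class: dict[str, int] = {}
    if contrast_class:
        class_genes: dict[str, set[str]] = {}
        for r in contrasts:
            if r.is_deg and r.gene_id in new_genes:
                cls = contrast_class.get(r.contrast, "other")
                class_genes.setdefault(cls, set()).add(r.gene_id)
        per_class = {cls: len(g) for cls, g in sorted(class_genes.items())}
    return {"per_contrast": per_contrast, "union_new_degs": len(union),
            "union_gene_ids": sorted(union), "per_class": per_class}


# ---------------------------------------------------------------------------
# Co-expression network
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionNetwork:
    genes: list[str]
    adjacency: np.ndarray                  # symmetric, in [0,1]
    tom: np.ndarray                        # symmetric, in [0,1]
    module_of: dict[str, str]              # gene -> module label, grey = unassigned
    eigengene: dict[str, pd.Series] = field(default_factory=dict)
    kme: pd.DataFrame | None = None        # genes × modules
    trait_cor: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    samples: list[str] = field(default_factory=list)
    expr: pd.DataFrame | None = None       # genes × samples, log scale

    @property
    def modules(self) -> list[str]:
        return sorted({m for m in self.module_of.values() if m != GREY},
                      key=lambda m: int(m[1:]))


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned TOM: (Σ_u a_iu·a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij), diag 1."""
    A = np.asarray(adjacency, dtype=float)
    n = A.shape[0]
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + A) / (kmin + 1.0 - A)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def build_network(expr: pd.DataFrame, config: RunConfig | None = None,
                  ) -> CoexpressionNetwork:
    """Weighted co-expression network from a log-scale genes × samples matrix.

    All-zero and constant-expression genes are dropped (correlation undefined).
    Adjacency is |Pearson correlation|^soft_power; modules come from
    average-linkage clustering of 1−TOM cut at ``tree_cut_height``, keeping
    clusters of at least ``min_module_size`` genes and labelling them m1, m2, …
    in decreasing size; the rest are grey.
    """
    config = config or RunConfig()
    X = expr.loc[expr.sum(axis=1) != 0]
    stds = X.std(axis=1)
    constant = stds == 0
    if constant.any():
        import logging
        logging.getLogger(__name__).warning(
            "%d constant-expression genes dropped", int(constant.sum()))
        X = X.loc[~constant]
    genes = [str(g) for g in X.index]
    corr = np.corrcoef(X.values)
    A = np.abs(corr) ** config.soft_power
    np.fill_diagonal(A, 1.0)
    tom = topological_overlap(A)

    dissim = 1.0 - tom
    dissim = np.maximum((dissim + dissim.T) / 2.0, 0.0)
    np.fill_diagonal(dissim, 0.0)
    Z = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=config.tree_cut_height, criterion="distance")

    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(i)
    big = [m for m in clusters.values() if len(m) >= config.min_module_size]
    big.sort(key=lambda m: (-len(m), m[0]))
    module_of = {g: GREY for g in genes}
    for k, members in enumerate(big, start=1):
        for i in members:
            module_of[genes[i]] = f"m{k}"

    return CoexpressionNetwork(
        genes=genes, adjacency=A, tom=tom, module_of=module_of,
        samples=[str(s) for s in X.columns], expr=X,
    )


def module_eigengenes_kme(network: CoexpressionNetwork) -> CoexpressionNetwork:
    """Attach module eigengenes (first PCs) and all-gene kME values.

    Each eigengene is the first principal component of the module's
    standardized expression submatrix, sign-oriented so its mean correlation
    with member genes is positive; kME(g, m) is the Pearson correlation of
    gene g's profile with eigengene m.
    """
    expr = network.expr
    if expr is None:
        raise ValueError("network carries no expression matrix")
    eigengenes: dict[str, pd.Series] = {}
    for module in network.modules:
        members = [g for g in network.genes if network.module_of[g] == module]
        sub = expr.loc[members]
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1).replace(0, 1.0)
        Z = sub.sub(mu, axis=0).div(sd, axis=0)
        try:
            u, s, vt = np.linalg.svd(Z.values, full_matrices=False)
            me = pd.Series(vt[0], index=expr.columns)
        except np.linalg.LinAlgError:
            me = Z.mean(axis=0)
            import logging
            logging.getLogger(__name__).warning(
                "module %s: SVD failed, mean-profile eigengene used", module)
        cors = np.array([np.corrcoef(expr.loc[g], me)[0, 1] for g in members])
        if np.nanmean(cors) < 0:
            me = -me
        eigengenes[module] = me

    kme = pd.DataFrame(index=network.genes, columns=network.modules, dtype=float)
    for module, me in eigengenes.items():
        me_vals = me.values
        for g in network.genes:
            x = expr.loc[g].values
            if x.std() == 0 or me_vals.std() == 0:
                kme.loc[g, module] = float("nan")
            else:
                kme.loc[g, module] = float(np.corrcoef(x, me_vals)[0, 1])
    network.eigengene = eigengenes
    network.kme = kme
    return network


def module_trait_hubs(network: CoexpressionNetwork,
                      traits: pd.DataFrame,
                      calls: Sequence[GeneAgeCall], new_ranks: set[int],
                      config: RunConfig | None = None) -> dict:
    """Module–trait correlations, per-trait top module, and hub genes.

    ``traits`` is samples × traits with numeric encodings (e.g. a 0/1
    treatment indicator).  For each trait the module with the largest |r| is
    highlighted; hubs are its genes with kME above ``hub_kme``, flagged as
    new-gene hubs when their founder stratum falls in ``new_ranks``.
    """
    config = config or RunConfig()
    if network.kme is None:
        module_eigengenes_kme(network)
    founder = {c.gene_id: c.founder_ps for c in calls if c.founder_ps is not None}

    trait_cor: dict[tuple[str, str], tuple[float, float]] = {}
    for trait in traits.columns:
        tvals = traits.loc[network.samples, trait].astype(float)
        if tvals.std() == 0:
            raise ValueError(f"trait {trait} is constant")
        for module, me in network.eigengene.items():
            r, p = stats.pearsonr(me.loc[network.samples], tvals)
            trait_cor[(module, trait)] = (float(r), float(p))
    network.trait_cor = trait_cor

    report: dict = {"modules": network.modules, "trait_cor": trait_cor}
    per_trait = {}
    for trait in traits.columns:
        cands = [(abs(r), module) for (module, t), (r, p) in trait_cor.items()
                 if t == trait]
        if not cands:
            continue
        _, top = max(cands)
        r, p = trait_cor[(top, trait)]
        members = [g for g in network.genes if network.module_of[g] == top]
        hubs = sorted(g for g in members
                      if network.kme.loc[g, top] > config.hub_kme)
        member_report = sorted(g for g in members
                               if network.kme.loc[g, top] > config.module_kme)
        per_trait[str(trait)] = {
            "top_module": top, "r": r, "p": p,
            "hubs": hubs,
            "new_gene_hubs": sorted(g for g in hubs
                                    if founder.get(g) in new_ranks),
            "members_kme": member_report,
        }
    report["per_trait"] = per_trait
    return report


def edge_list(network: CoexpressionNetwork, min_adjacency: float = 0.1,
              ) -> pd.DataFrame:
    """Thresholded adjacency edge list (gene_a, gene_b, weight) for viewers."""
    rows = []
    n = len(network.genes)
    for i in range(n):
        for j in range(i + 1, n):
            w = network.adjacency[i, j]
            if w >= min_adjacency:
                rows.append({"gene_a": network.genes[i],
                             "gene_b": network.genes[j], "weight": float(w)})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])
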