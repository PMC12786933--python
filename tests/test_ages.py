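import math

import numpy as np
import pytest
from scipy import stats

from genestrata.ages import (assign_raw_age, build_ladder, clade_census,
                             divergence_rank, fit_bitscore_decay, founder_age,
                             hdf_probability, mcl_cluster, representativeness)
from genestrata.formats import HomologyHit


def hit(gene, taxon, score=100.0, evalue=1e-30):
    return HomologyHit(query_gene=gene, subject_taxon=taxon,
                       bitscore=score, evalue=evalue)


# ---------------------------------------------------------------------------
# ladder
# ---------------------------------------------------------------------------

def test_ladder_ranks_and_ages(small_ladder):
    assert small_ladder.n_strata == 4
    assert [r for r, _, _ in small_ladder.strata] == [1, 2, 3, 4]
    assert [small_ladder.age_of(r) for r in (1, 2, 3, 4)] == [4250, 1598, 35, 9]


def test_ladder_order_independent_of_age_table_rows():
    lineage = ["root", "mid", "tip"]
    a = build_ladder(lineage, {"root": 100, "mid": 50, "tip": 10})
    b = build_ladder(lineage, {"tip": 10, "root": 100, "mid": 50})
    assert a == b


def test_ladder_rejects_non_monotone_ages():
    with pytest.raises(ValueError, match="mid"):
        build_ladder(["root", "mid", "tip"], {"root": 100, "mid": 120, "tip": 10})


# ---------------------------------------------------------------------------
# raw age
# ---------------------------------------------------------------------------

def test_raw_age_from_sister_species_is_genus_rank(small_ladder):
    lineages = {
        "sister": ["cellular_organisms", "Eukaryota", "genus", "sister"],
        "species": ["cellular_organisms", "Eukaryota", "genus", "species"],
    }
    hits = [hit("g", "sister"), hit("g", "species")]
    assert assign_raw_age("g", hits, lineages, small_ladder) == 3


def test_raw_age_focal_only_is_youngest_rank(small_ladder):
    lineages = {"species": ["cellular_organisms", "Eukaryota", "genus", "species"]}
    assert assign_raw_age("g", [hit("g", "species")], lineages, small_ladder) == 4


def test_raw_age_unknown_taxon_ignored_with_warning(small_ladder, caplog):
    lineages = {"species": ["cellular_organisms", "Eukaryota", "genus", "species"]}
    hits = [hit("g", "mystery"), hit("g", "species")]
    with caplog.at_level("WARNING"):
        assert assign_raw_age("g", hits, lineages, small_ladder) == 4
    assert "mystery" in caplog.text


def test_raw_age_matches_bruteforce_oracle_on_random_instances(small_ladder):
    """Implementation equals a direct per-hit minimum-rank scan."""
    names = small_ladder.names
    rng = np.random.default_rng(42)
    rank_of = {n: r for r, n, _ in small_ladder.strata}
    # taxa diverging at every rank
    lineages = {}
    for r in range(1, 5):
        for s in range(3):
            t = f"x{r}_{s}"
            lineages[t] = names[:r] + ([t] if r < 4 else [])
    taxa = list(lineages)
    for _ in range(100):
        n_hits = int(rng.integers(1, 30))
        chosen = rng.choice(taxa, size=n_hits)
        hits = [hit("g", t) for t in chosen]
        # oracle: scan every hit, take the minimum divergence rank directly
        oracle = min(max(rank_of[n] for n in lineages[t] if n in rank_of)
                     for t in chosen)
        assert assign_raw_age("g", hits, lineages, small_ladder) == oracle


def test_cohort_raw_age_recovers_planted_ranks(calls_truth):
    normal = calls_truth[~calls_truth.is_hdf_case & ~calls_truth.is_contaminant_case]
    assert (normal.raw_ps == normal.true_raw_ps).all()


# ---------------------------------------------------------------------------
# representativeness
# ---------------------------------------------------------------------------

def _rep_setup(n_subclades, n_hit_subclades, ladder):
    names = ladder.names
    lineages = {}
    for s in range(n_subclades):
        t = f"deep{s}"
        lineages[t] = [names[0], f"sub{s}", t]
    hits = [hit("g", f"deep{s}") for s in range(n_hit_subclades)]
    census = clade_census(lineages, ladder)
    return hits, census, lineages


def test_representativeness_at_exact_cutoff_not_excluded(small_ladder):
    """Hits in 3 of 10 subclades score exactly 30.0; rule is strictly below."""
    hits, census, lineages = _rep_setup(10, 3, small_ladder)
    score = representativeness("g", hits, 1, census, lineages, small_ladder)
    assert score == pytest.approx(30.0)


def test_representativeness_full_coverage(small_ladder):
    hits, census, lineages = _rep_setup(6, 6, small_ladder)
    assert representativeness("g", hits, 1, census, lineages,
                              small_ladder) == pytest.approx(100.0)


def test_contaminant_like_single_subclade_score(small_ladder):
    hits, census, lineages = _rep_setup(8, 1, small_ladder)
    assert representativeness("g", hits, 1, census, lineages,
                              small_ladder) == pytest.approx(12.5)


def test_empty_census_gives_undefined_score(small_ladder):
    hits, _, lineages = _rep_setup(4, 2, small_ladder)
    assert representativeness("g", hits, 2, {2: set()}, lineages,
                              small_ladder) is None


def test_cohort_contaminants_excluded(calls_truth):
    cont = calls_truth[calls_truth.is_contaminant_case]
    assert len(cont) > 0
    assert (cont.status == "excluded_low_representativeness").all()


# ---------------------------------------------------------------------------
# MCL
# ---------------------------------------------------------------------------

def _block_matrix(blocks, n, within=1.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    S = rng.uniform(0, noise, size=(n, n))
    S = (S + S.T) / 2
    for members in blocks:
        for i in members:
            for j in members:
                S[i, j] = within
    np.fill_diagonal(S, within)
    return S


def test_mcl_two_disjoint_cliques():
    S = _block_matrix([[0, 1, 2], [3, 4, 5]], 6)
    fams = mcl_cluster(S)
    assert sorted(sorted(f) for f in fams) == [[0, 1, 2], [3, 4, 5]]


def test_mcl_single_gene_singleton():
    fams = mcl_cluster(np.array([[1.0]]))
    assert fams == [[0]]


def test_mcl_recovers_planted_three_families_with_noise():
    blocks = [list(range(0, 10)), list(range(10, 20)), list(range(20, 30))]
    S = _block_matrix(blocks, 30, within=1.0, noise=0.05, seed=3)
    fams = mcl_cluster(S, inflation=2.0)
    labels = np.empty(30, dtype=int)
    for k, f in enumerate(fams):
        labels[f] = k
    truth = np.repeat([0, 1, 2], 10)
    # Rand index must be exactly 1 (identical partition up to labels)
    from sklearn.metrics import rand_score
    assert rand_score(truth, labels) == 1.0


def test_mcl_rejects_asymmetric_input():
    S = np.array([[1.0, 0.5], [0.2, 1.0]])
    with pytest.raises(ValueError, match="symmetric"):
        mcl_cluster(S)


def test_mcl_partition_covers_blockdiagonal_exactly():
    blocks = [list(range(0, 4)), list(range(4, 9)), [9]]
    S = _block_matrix(blocks, 10)
    fams = mcl_cluster(S)
    assert sorted(sum(fams, [])) == list(range(10))
    assert sorted(sorted(f) for f in fams) == [sorted(b) for b in
                                               sorted(blocks, key=sorted)]


# ---------------------------------------------------------------------------
# founder ages
# ---------------------------------------------------------------------------

def test_founder_is_oldest_reliable_member():
    part = [["a", "b", "c"]]
    raw = {"a": 3, "b": 7, "c": 12}
    out = founder_age(part, raw, {})
    assert out == {"a": 3, "b": 3, "c": 3}


def test_founder_singleton_keeps_own_rank():
    assert founder_age([["z"]], {"z": 15}, {})["z"] == 15


def test_founder_skips_excluded_members():
    part = [["a", "b"]]
    raw = {"a": 5, "b": 18}
    status = {"a": "excluded_low_representativeness"}
    assert founder_age(part, raw, status)["b"] == 18


def test_founder_family_without_reliable_members_unassigned():
    part = [["a", "b"]]
    raw = {"a": 5, "b": 6}
    status = {"a": "unassigned", "b": "excluded_low_representativeness"}
    out = founder_age(part, raw, status)
    assert out == {"a": None, "b": None}


def test_founder_never_younger_than_raw(calls_truth):
    assigned = calls_truth.dropna(subset=["founder_ps", "raw_ps"])
    assert (assigned.founder_ps <= assigned.raw_ps).all()


def test_founder_multiset_invariant_to_input_order(cohort):
    from genestrata.ages import call_ages

    rev_genes = list(reversed(cohort.genes))
    rev_hits = list(reversed(cohort.hits))
    calls_fwd = call_ages(cohort.genes, cohort.hits, cohort.lineages,
                          cohort.ladder, self_hits=cohort.self_hits)
    calls_rev = call_ages(rev_genes, rev_hits, cohort.lineages,
                          cohort.ladder, self_hits=cohort.self_hits)
    fwd = sorted((c.gene_id, c.founder_ps) for c in calls_fwd)
    rev = sorted((c.gene_id, c.founder_ps) for c in calls_rev)
    assert fwd == rev


# ---------------------------------------------------------------------------
# bitscore decay and HDF
# ---------------------------------------------------------------------------

def test_decay_fit_exact_exponential_closed_form():
    pts = [(0, 100.0), (1, 50.0), (2, 25.0)]
    fit = fit_bitscore_decay(pts)
    assert fit.a == pytest.approx(100.0, abs=1e-6)
    assert fit.b == pytest.approx(math.log(2), abs=1e-6)
    assert fit.residual_sd == pytest.approx(0.01 * fit.a, rel=1e-6)


def test_decay_fit_constant_scores_no_decay_limit():
    fit = fit_bitscore_decay([(0, 80.0), (1, 80.0), (2, 80.0)])
    assert fit.b == pytest.approx(0.0, abs=1e-8)
    assert fit.predict(5.0) == pytest.approx(80.0, rel=1e-6)


def test_decay_fit_requires_three_distinct_distances():
    assert fit_bitscore_decay([(0, 100.0), (0, 90.0), (1, 50.0)]) is None


def test_decay_fit_parameter_recovery_under_noise():
    rng = np.random.default_rng(7)
    a, b = 200.0, 0.5
    d = np.linspace(0, 6, 10)
    s = a * np.exp(-b * d) + rng.normal(0, 5, size=10)
    fit = fit_bitscore_decay(list(zip(d, s)))
    assert fit.a == pytest.approx(a, rel=0.10)
    assert fit.b == pytest.approx(b, rel=0.15)


def test_hdf_probability_far_above_threshold_is_confident():
    from genestrata.ages import BitscoreDecayFit

    fit = BitscoreDecayFit(a=100.0, b=0.0, residual_sd=1.0, n_points=5)
    assert hdf_probability(fit, 1.0, 20.0) < 1e-12


def test_hdf_probability_at_threshold_is_half():
    from genestrata.ages import BitscoreDecayFit

    fit = BitscoreDecayFit(a=20.0, b=0.0, residual_sd=2.0, n_points=5)
    assert hdf_probability(fit, 3.0, 20.0) == pytest.approx(0.5)


def test_hdf_probability_matches_normal_cdf():
    from genestrata.ages import BitscoreDecayFit

    fit = BitscoreDecayFit(a=100.0, b=math.log(2), residual_sd=2.0, n_points=5)
    # mean at d=3 is 12.5
    expect = stats.norm.cdf((20 - 12.5) / 2)
    assert hdf_probability(fit, 3.0, 20.0) == pytest.approx(expect, rel=1e-9)


def test_cohort_hdf_sensitivity(calls_truth):
    hdf = calls_truth[calls_truth.is_hdf_case]
    assert len(hdf) >= 10
    assert (hdf.status == "hdf_uncertain").mean() >= 0.9


def test_cohort_founder_recovery_complete(calls_truth):
    normal = calls_truth[~calls_truth.is_hdf_case & ~calls_truth.is_contaminant_case]
    assert (normal.founder_ps == normal.true_founder_ps).all()


def test_divergence_rank_none_for_alien_lineage(small_ladder):
    assert divergence_rank(["other_root", "weird"], small_ladder) is None
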