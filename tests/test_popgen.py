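import numpy as np
import pytest

from landgen.genotypes import MISSING, GenotypeTable
from landgen.popgen import (diversity_summary, global_theta, hierarchical_f,
                            hwe_test_mc, null_allele_em, pairwise_fst,
                            weir_cockerham_components, _pop_locus_stats)

from conftest import make_table
from oracles import balanced_nested_components, wc_theta_longhand


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def test_unbiased_he_worked_example():
    """(1,2),(1,2),(1,1),(2,2): Ho=0.5, He=(8/7)*0.5."""
    gt = make_table({"P1": [[(1, 2)], [(1, 2)], [(1, 1)], [(2, 2)]]})
    table = diversity_summary(gt).table
    assert table.loc["P1", "Ho"] == pytest.approx(0.5)
    assert table.loc["P1", "He"] == pytest.approx(8 / 7 * 0.5, abs=1e-12)


def test_monomorphic_population_has_undefined_fis():
    gt = make_table({"P1": [[(3, 3)]] * 10})
    with pytest.warns(UserWarning, match="Fis undefined"):
        table = diversity_summary(gt).table
    assert table.loc["P1", "Ho"] == 0.0
    assert table.loc["P1", "He"] == 0.0
    assert np.isnan(table.loc["P1", "Fis"])


def test_private_alleles_counted_against_all_other_populations():
    gt = make_table({
        "P1": [[(1, 2)], [(1, 1)]],
        "P2": [[(2, 3)], [(3, 3)]],
    })
    table = diversity_summary(gt).table
    assert table.loc["P1", "PA"] == 1      # allele 1
    assert table.loc["P2", "PA"] == 1      # allele 3; allele 2 is shared


def test_na_sums_alleles_over_loci():
    gt = make_table({"P1": [[(1, 2), (7, 9)], [(2, 3), (7, 7)]]})
    table = diversity_summary(gt).table
    assert table.loc["P1", "Na"] == 3 + 2
    assert table.loc["P1", "A"] == pytest.approx(2.5)


# ---------------------------------------------------------------------------
# Hardy-Weinberg Monte-Carlo
# ---------------------------------------------------------------------------

def test_hwe_monomorphic_returns_one():
    gt = make_table({"P1": [[(4, 4)]] * 10})
    assert hwe_test_mc(gt, "P1", "L1", seed=0) == 1.0


def test_hwe_all_homozygotes_strongly_rejected():
    """20 individuals, two alleles at 0.5, zero heterozygotes."""
    gt = make_table({"P1": [[(1, 1)]] * 10 + [[(2, 2)]] * 10})
    p = hwe_test_mc(gt, "P1", "L1", n_iter=2000, seed=1)
    assert p < 0.01


def test_hwe_p_bounded_below_by_mc_resolution():
    gt = make_table({"P1": [[(1, 1)]] * 10 + [[(2, 2)]] * 10})
    p = hwe_test_mc(gt, "P1", "L1", n_iter=99, seed=1)
    assert p >= 1 / 100


# ---------------------------------------------------------------------------
# Null-allele EM
# ---------------------------------------------------------------------------

def test_em_zero_when_counts_fit_hardy_weinberg():
    """Genotype counts exactly at HW proportions, no missing data."""
    # p = (0.5, 0.5), n = 100: 25 hom1, 50 het, 25 hom2
    inds = [[(1, 1)]] * 25 + [[(1, 2)]] * 50 + [[(2, 2)]] * 25
    gt = make_table({"P1": inds})
    est = null_allele_em(gt, "L1", "P1")
    assert est.converged
    assert est.r <= 1e-6


def test_em_recovers_planted_null_frequency():
    """r = 0.2 planted at n = 500 under HW is recovered within 0.05."""
    rng = np.random.default_rng(42)
    freqs = np.array([0.4, 0.3, 0.2, 0.1])
    alleles = np.arange(1, 5)
    inds = []
    for _ in range(500):
        pair = []
        for _ in range(2):
            if rng.random() < 0.2:
                pair.append(0)                       # null copy
            else:
                pair.append(rng.choice(alleles, p=freqs))
        a, b = pair
        if a == 0 and b == 0:
            inds.append([None])
        elif a == 0:
            inds.append([(b, b)])
        elif b == 0:
            inds.append([(a, a)])
        else:
            inds.append([(a, b)])
    gt = make_table({"P1": inds})
    est = null_allele_em(gt, "L1", "P1")
    assert est.converged
    assert 0.15 <= est.r <= 0.25


def test_em_all_missing_hits_boundary_with_warning():
    gt = make_table({"P1": [[None]] * 5})
    with pytest.warns(UserWarning, match="boundary"):
        est = null_allele_em(gt, "L1", "P1")
    assert est.r == 1.0


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def test_theta_fixed_difference_is_one():
    gt = make_table({"A": [[(1, 1)]] * 10, "B": [[(2, 2)]] * 10})
    assert pairwise_fst(gt).values[0, 1] == pytest.approx(1.0)


def test_theta_identical_populations_not_positive():
    inds = [[(1, 2)], [(1, 1)], [(2, 3)], [(3, 3)], [(1, 3)]]
    gt = make_table({"A": inds, "B": inds})
    assert pairwise_fst(gt).values[0, 1] <= 0.0


def test_theta_matches_longhand_oracle():
    """Vectorized theta equals the printed-equation evaluation to 1e-12."""
    pops = {
        "A": [[(1, 2)], [(1, 1)], [(2, 2)], [(1, 2)], [(2, 3)], [(3, 3)]],
        "B": [[(2, 2)], [(2, 3)], [(3, 3)], [(3, 3)], [(2, 3)]],
    }
    gt = make_table(pops)
    expected = wc_theta_longhand([
        [(1, 2), (1, 1), (2, 2), (1, 2), (2, 3), (3, 3)],
        [(2, 2), (2, 3), (3, 3), (3, 3), (2, 3)],
    ])
    assert pairwise_fst(gt).values[0, 1] == pytest.approx(expected, abs=1e-12)


def test_theta_invariant_to_relabeling_and_order(ibd_scenario):
    *_, gt = ibd_scenario
    theta = pairwise_fst(gt).values
    # relabel alleles with an order-preserving-free bijection
    relabeled = gt.calls.copy()
    mask = relabeled != MISSING
    relabeled[mask] = 97 - relabeled[mask]
    gt2 = GenotypeTable(gt.individuals, gt.loci, relabeled, gt.populations)
    assert np.allclose(pairwise_fst(gt2).values, theta, atol=1e-12)
    # permute individuals
    rng = np.random.default_rng(0)
    perm = rng.permutation(gt.n_individuals)
    gt3 = GenotypeTable([gt.individuals[i] for i in perm], gt.loci,
                        gt.calls[perm], [gt.populations[i] for i in perm])
    t3 = pairwise_fst(gt3)
    order = [t3.labels.index(l) for l in pairwise_fst(gt).labels]
    assert np.allclose(t3.values[np.ix_(order, order)], theta, atol=1e-12)


def test_ena_is_noop_without_homozygote_excess():
    """With counts at exact HW and no missing data, r_hat = 0 everywhere and
    the corrected theta equals the raw theta to 1e-9."""
    a = [[(1, 1)]] * 16 + [[(1, 2)]] * 48 + [[(2, 2)]] * 36
    b = [[(1, 1)]] * 36 + [[(1, 2)]] * 48 + [[(2, 2)]] * 16
    gt = make_table({"A": a, "B": b})
    raw = pairwise_fst(gt, correction="none").values
    ena = pairwise_fst(gt, correction="ena").values
    assert np.allclose(raw, ena, atol=1e-9)


def test_ena_shrinks_null_inflated_theta():
    """Null-allele masking inflates raw theta; the ENA correction moves it
    back toward the null-free value."""
    rng = np.random.default_rng(3)
    pops = {}
    for pop, freqs in (("A", [0.7, 0.2, 0.1]), ("B", [0.2, 0.2, 0.6])):
        inds = []
        for _ in range(300):
            a, b = rng.choice([1, 2, 3], size=2, p=freqs)
            inds.append([(min(a, b), max(a, b))])
        pops[pop] = inds
    clean = make_table(pops)
    theta_clean = pairwise_fst(clean).values[0, 1]
    masked = {}
    for pop, inds in pops.items():
        out = []
        for (call,) in inds:
            hidden = rng.random(2) < 0.25
            if hidden.all():
                out.append([None])
            elif hidden[0]:
                out.append([(call[1], call[1])])
            elif hidden[1]:
                out.append([(call[0], call[0])])
            else:
                out.append([call])
        masked[pop] = out
    dirty = make_table(masked)
    theta_ena = pairwise_fst(dirty, correction="ena").values[0, 1]
    assert theta_ena == pytest.approx(theta_clean, abs=0.02)
    for pop in ("A", "B"):
        est = null_allele_em(dirty, "L1", pop)
        assert est.r == pytest.approx(0.25, abs=0.07)


def test_pair_sharing_no_locus_is_error():
    gt = make_table({"A": [[(1, 2), None], [(1, 1), None]],
                     "B": [[None, (2, 2)], [None, (2, 3)]]})
    with pytest.raises(ValueError, match="share no scored locus"):
        pairwise_fst(gt)


# ---------------------------------------------------------------------------
# Hierarchical F
# ---------------------------------------------------------------------------

def test_single_level_reproduces_global_theta(ibd_scenario):
    *_, gt = ibd_scenario
    hf = hierarchical_f(gt)
    assert hf.f["F_Pop/T"] == pytest.approx(global_theta(gt), abs=1e-9)


def test_duplicated_groups_have_no_between_group_variance():
    rng = np.random.default_rng(12)
    def draw():
        return [[tuple(sorted(rng.integers(1, 5, 2))) for _ in range(3)]
                for _ in range(20)]
    inds_a, inds_b = draw(), draw()
    gt = make_table({"A1": inds_a, "B1": inds_b, "A2": inds_a, "B2": inds_b})
    groups = {"A1": "G1", "B1": "G1", "A2": "G2", "B2": "G2"}
    hf = hierarchical_f(gt, groups=groups, group_name="Grp")
    assert abs(hf.f["F_Grp/T"]) < 0.05


def test_components_match_balanced_textbook_anova():
    """On a balanced design the Henderson solution equals the classical
    mean-square recursion for nested ANOVA, allele by allele."""
    rng = np.random.default_rng(7)
    # 3 groups x 2 pops x 4 individuals, one biallelic locus
    pops = {}
    groups = {}
    raw = []                      # indicator data for the oracle, allele 1
    for g in range(3):
        grp = []
        for p in range(2):
            name = f"G{g}P{p}"
            groups[name] = f"G{g}"
            inds = []
            pop_y = []
            for _ in range(4):
                call = tuple(sorted(rng.integers(1, 3, size=2)))
                inds.append([call])
                pop_y.append(tuple(float(a == 1) for a in call))
            pops[name] = inds
            grp.append(pop_y)
        raw.append(grp)
    gt = make_table(pops)
    hf = hierarchical_f(gt, groups=groups, group_name="Grp")
    comp = hf.components.sum(axis=0)
    # biallelic: allele-2 indicators mirror allele 1, doubling each component
    oracle = [2 * v for v in balanced_nested_components(raw)]
    assert comp == pytest.approx(oracle, abs=1e-9)


def test_single_population_group_flagged():
    gt = make_table({"A": [[(1, 2)], [(2, 2)]],
                     "B": [[(1, 1)], [(1, 2)]],
                     "C": [[(2, 3)], [(3, 3)]]})
    with pytest.warns(UserWarning, match="low information"):
        hf = hierarchical_f(gt, groups={"A": "G1", "B": "G1", "C": "G2"})
    assert hf.low_information_groups == ["G2"]


def test_bootstrap_ci_orders_and_widens_with_fewer_loci(ibd_scenario):
    *_, gt = ibd_scenario
    hf_full = hierarchical_f(gt, B=200, seed=0)
    lo, hi = hf_full.ci["F_Pop/T"]
    assert lo <= hi
    # averaged over random 3-locus subsets, fewer loci give wider intervals
    rng = np.random.default_rng(1)
    widths = []
    for _ in range(8):
        pick = rng.choice(gt.loci, size=3, replace=False)
        hf_small = hierarchical_f(gt.subset_loci(list(pick)), B=200, seed=0)
        lo_s, hi_s = hf_small.ci["F_Pop/T"]
        widths.append(hi_s - lo_s)
    assert np.mean(widths) > (hi - lo)


def test_weir_cockerham_components_requires_two_pops():
    gt = make_table({"A": [[(1, 2)], [(2, 2)]]})
    stats = _pop_locus_stats(gt, 0, ["A"], "none", True, 1e-8, 100)
    with pytest.raises(ValueError, match=">= 2 populations"):
        weir_cockerham_components(stats)
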