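"""Population-genetic estimators for co-dominant microsatellite data.

Implements the classical moment estimators this package's inference rests on:

* per-population diversity summaries (allele counts, private alleles,
  observed/expected heterozygosity, multi-locus inbreeding 1 - Ho/He);
* a Monte-Carlo Hardy-Weinberg test (allele shuffling within locus and
  population, one-sided toward heterozygote deficit);
* an EM estimator of null-allele frequency under the standard model in which
  null homozygotes appear as missing data and null heterozygotes as apparent
  homozygotes;
* Weir & Cockerham's theta (variance-component FST), pairwise and global,
  with an optional "exclude null alleles" (ENA) correction that rescales
  visible allele frequencies with the EM estimates;
* hierarchical F-statistics from an unbalanced nested ANOVA of allele
  indicators (total > group > population > individual > gene copy), with a
  bootstrap over loci for confidence intervals.

Missing data are handled by pairwise/per-locus deletion throughout; nothing
is imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .genotypes import MISSING, GenotypeTable

__all__ = [
    "DiversitySummary",
    "NullAlleleEstimate",
    "FstMatrix",
    "HierarchicalFResult",
    "diversity_summary",
    "hwe_test_mc",
    "null_allele_em",
    "pairwise_fst",
    "global_theta",
    "weir_cockerham_components",
    "hierarchical_f",
]


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversitySummary:
    """Per-population diversity table plus per locus x population frequencies.

    ``table`` columns: n, Na, PA, A, Ho, He, Fis.  ``frequencies`` is a long
    DataFrame (population, locus, allele, count, freq).
    """

    table: pd.DataFrame
    frequencies: pd.DataFrame

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.4f")


def _unbiased_he(freqs: np.ndarray, n_ind: int) -> float:
    """Nei (1978) small-sample expected heterozygosity, n_ind diploids."""
    return (2 * n_ind / (2 * n_ind - 1)) * (1.0 - float(np.sum(freqs ** 2)))


def diversity_summary(gt: GenotypeTable) -> DiversitySummary:
    """Compute n, Na, PA, A, Ho, He and Fis = 1 - Ho/He per population.

    Ho is the fraction of non-missing calls that are heterozygous, averaged
    over loci; He the unbiased expected heterozygosity averaged over loci;
    private alleles are counted against every other population in the table.
    Fis uses the multi-locus means (a population with He = 0 at every locus
    gets Fis = NaN with a warning).
    """
    pops = gt.population_ids()
    # which populations carry each (locus, allele)
    carriers: dict[tuple[int, int], set[str]] = {}
    freq_rows = []
    stats = {}
    for pop in pops:
        ho_per_locus, he_per_locus, a_per_locus = [], [], []
        na = 0
        pop_alleles: set[tuple[int, int]] = set()
        n_ind_pop = len(gt.indices_of(pop))
        for li, locus in enumerate(gt.loci):
            obs = gt.calls_at(locus, pop)
            if len(obs) == 0:
                continue
            alleles, counts = np.unique(obs, return_counts=True)
            freqs = counts / counts.sum()
            for al, ct, fr in zip(alleles, counts, freqs):
                freq_rows.append((pop, locus, int(al), int(ct), float(fr)))
                carriers.setdefault((li, int(al)), set()).add(pop)
                pop_alleles.add((li, int(al)))
            na += len(alleles)
            a_per_locus.append(len(alleles))
            ho_per_locus.append(float(np.mean(obs[:, 0] != obs[:, 1])))
            he_per_locus.append(_unbiased_he(freqs, len(obs)))
        ho, he = float(np.mean(ho_per_locus)), float(np.mean(he_per_locus))
        if he == 0.0:
            warnings.warn(f"population {pop!r}: He = 0 at every locus; Fis undefined")
            fis = np.nan
        else:
            fis = 1.0 - ho / he
        stats[pop] = dict(n=n_ind_pop, Na=na, A=float(np.mean(a_per_locus)),
                          Ho=ho, He=he, Fis=fis, _alleles=pop_alleles)
    for pop in pops:
        stats[pop]["PA"] = sum(
            1 for key in stats[pop].pop("_alleles") if len(carriers[key]) == 1
        )
    table = pd.DataFrame.from_dict(stats, orient="index")
    table = table[["n", "Na", "PA", "A", "Ho", "He", "Fis"]]
    table.index.name = "population"
    freqs = pd.DataFrame(freq_rows, columns=["population", "locus", "allele",
                                             "count", "freq"])
    return DiversitySummary(table, freqs)


# ---------------------------------------------------------------------------
# Hardy-Weinberg Monte-Carlo test
# ---------------------------------------------------------------------------

def hwe_test_mc(gt: GenotypeTable, population: str, locus: str | None = None,
                n_iter: int = 2000, seed: int | None = None) -> float:
    """Monte-Carlo Hardy-Weinberg test, one-sided toward heterozygote deficit.

    Alleles are pooled within each locus of the population and re-paired at
    random ``n_iter`` times; the statistic is the observed heterozygote count
    (summed over loci when ``locus`` is None), and
    ``p = (#{replicates with het count <= observed} + 1) / (n_iter + 1)``.
    Monomorphic data return p = 1 by convention.
    """
    rng = np.random.default_rng(seed)
    loci = [locus] if locus is not None else gt.loci
    obs_het = 0
    rep_het = np.zeros(n_iter, dtype=np.int64)
    informative = False
    for loc in loci:
        obs = gt.calls_at(loc, population)
        if len(obs) < 1:
            continue
        alleles = obs.ravel()
        if np.unique(alleles).size < 2:
            continue
        if locus is not None and len(obs) < 3:
            raise ValueError("need >= 3 scored individuals for a per-locus test")
        informative = True
        obs_het += int(np.sum(obs[:, 0] != obs[:, 1]))
        tiled = np.broadcast_to(alleles, (n_iter, alleles.size))
        shuffled = rng.permuted(tiled, axis=1)
        pairs = shuffled.reshape(n_iter, -1, 2)
        rep_het += np.sum(pairs[:, :, 0] != pairs[:, :, 1], axis=1)
    if not informative:
        return 1.0
    k = int(np.sum(rep_het <= obs_het))
    return (k + 1) / (n_iter + 1)


# ---------------------------------------------------------------------------
# Null-allele EM
# ---------------------------------------------------------------------------

@dataclass
class NullAlleleEstimate:
    """EM estimate of the null-allele frequency at one locus in one population."""

    r: float                        # null-allele frequency in [0, 1]
    alleles: np.ndarray             # visible allele codes
    freqs: np.ndarray               # visible allele frequencies; sum = 1 - r
    n_iter: int
    converged: bool

    def corrected_frequencies(self) -> np.ndarray:
        """Visible frequencies rescaled to sum to 1 (the ENA scheme)."""
        if self.r >= 1.0:
            raise ValueError("no visible alleles; corrected frequencies undefined")
        return self.freqs / (1.0 - self.r)


def _em_null_from_counts(hom: np.ndarray, het_copies: np.ndarray, n_missing: int,
                         tol: float, max_iter: int) -> tuple[np.ndarray, float, int, bool]:
    """Core EM on sufficient statistics.

    ``hom[i]``: observed homozygote count for visible allele i; ``het_copies[i]``:
    copies of allele i in observed heterozygotes; ``n_missing``: blank
    individuals (candidate null homozygotes).  Model: HWE with one null allele
    of frequency r; apparent homozygotes i arise from i/i or i/null.
    """
    n_total = int(hom.sum() + het_copies.sum() / 2 + n_missing)
    if n_total == 0:
        raise ValueError("no individuals")
    if hom.sum() + het_copies.sum() == 0:
        # every call blank: boundary estimate
        return np.zeros(0), 1.0, 0, True
    two_n = 2.0 * n_total

    def loglik(q_, r_):
        ll = 0.0
        with np.errstate(divide="ignore"):
            hom_p = q_ ** 2 + 2.0 * q_ * r_
            ll += float(np.sum(np.where(hom > 0, hom * np.log(np.maximum(hom_p, 1e-300)), 0.0)))
            ll += float(np.sum(np.where(het_copies > 0, het_copies * np.log(np.maximum(q_, 1e-300)), 0.0)))
        if n_missing:
            ll += 2.0 * n_missing * np.log(max(r_, 1e-300))
        return ll

    r = float(np.clip(np.sqrt(n_missing / n_total), 1e-3, 0.5))
    q = (2 * hom + het_copies) / (2 * hom + het_copies).sum() * (1.0 - r)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = q + 2.0 * r
        e_null = np.where(denom > 0, hom * 2.0 * r / np.where(denom > 0, denom, 1.0), 0.0)
        q_new = (het_copies + 2.0 * hom - e_null) / two_n
        r_new = (e_null.sum() + 2.0 * n_missing) / two_n
        delta = max(np.max(np.abs(q_new - q), initial=0.0), abs(r_new - r))
        q, r = q_new, float(r_new)
        if delta < tol:
            converged = True
            break
    # EM contracts geometrically slowly at the r = 0 boundary; snap when the
    # boundary likelihood is as good as the interior iterate
    if n_missing == 0 and 0.0 < r < 1e-2:
        q0 = (het_copies + 2.0 * hom) / two_n
        if loglik(q0, 0.0) >= loglik(q, r) - 1e-9:
            return q0, 0.0, it, True
    return q, r, it, converged


def null_allele_em(gt: GenotypeTable, locus: str, population: str,
                   tol: float = 1e-8, max_iter: int = 10000) -> NullAlleleEstimate:
    """Estimate the null-allele frequency at ``locus`` in ``population`` by EM.

    Missing genotypes are treated as candidate null homozygotes and the excess
    of apparent homozygotes as null heterozygotes, under HWE.  An estimate at
    the r = 1 boundary (all calls blank) comes back with a warning.
    """
    li = gt.locus_index(locus)
    idx = gt.indices_of(population)
    calls = gt.calls[idx, li, :]
    missing = calls[:, 0] == MISSING
    obs = calls[~missing]
    alleles = np.unique(obs) if len(obs) else np.array([], dtype=np.int32)
    hom = np.zeros(alleles.size)
    het_copies = np.zeros(alleles.size)
    code_ix = {int(a): i for i, a in enumerate(alleles)}
    for a1, a2 in obs:
        if a1 == a2:
            hom[code_ix[int(a1)]] += 1
        else:
            het_copies[code_ix[int(a1)]] += 1
            het_copies[code_ix[int(a2)]] += 1
    q, r, n_iter, converged = _em_null_from_counts(
        hom, het_copies, int(missing.sum()), tol, max_iter
    )
    if r >= 1.0:
        warnings.warn(
            f"locus {locus!r} in population {population!r}: all calls missing; "
            "null-allele frequency at the r = 1 boundary"
        )
        q = np.zeros(alleles.size)
    if not converged:
        warnings.warn(f"null-allele EM did not converge in {max_iter} iterations")
    return NullAlleleEstimate(r=float(r), alleles=alleles, freqs=np.asarray(q),
                              n_iter=n_iter, converged=converged)


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def _pop_locus_stats(gt: GenotypeTable, li: int, pops: Sequence[str],
                     correction: str, ena_deflate_n: bool,
                     tol: float, max_iter: int):
    """Per population: (n_i, allele codes, freq vector, het-proportion vector).

    With the ENA correction, frequencies are the EM visible frequencies
    rescaled to sum to one and sample sizes are deflated by (1 - r_hat); with
    r_hat = 0 both reduce exactly to the raw values.
    """
    out = []
    for pop in pops:
        calls = gt.calls[gt.indices_of(pop), li, :]
        obs = calls[calls[:, 0] != MISSING]
        n_i = len(obs)
        if n_i == 0:
            out.append((0.0, np.array([]), np.array([]), np.array([])))
            continue
        alleles, counts = np.unique(obs, return_counts=True)
        freqs = counts / counts.sum()
        het = (obs[:, 0][:, None] == alleles) != (obs[:, 1][:, None] == alleles)
        h = het.mean(axis=0)
        if correction == "ena" and alleles.size:
            hom = np.array([np.sum((obs[:, 0] == a) & (obs[:, 1] == a)) for a in alleles],
                           dtype=float)
            het_copies = counts - 2 * hom
            n_missing = int((calls[:, 0] == MISSING).sum())
            q, r, _, _ = _em_null_from_counts(hom, het_copies, n_missing,
                                              tol, max_iter)
            if r < 1.0:
                freqs = q / (1.0 - r)
                freqs = freqs / freqs.sum()
                if ena_deflate_n:
                    n_i = n_i * (1.0 - r)
        out.append((float(n_i), alleles, freqs, h))
    return out


def weir_cockerham_components(stats) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components for one locus.

    ``stats`` is the per-population list of (n_i, alleles, freqs, het props);
    returns the sums over alleles of the among-population (a), among-
    individual (b) and within-individual (c) components.
    """
    stats = [s for s in stats if s[0] > 0]
    r = len(stats)
    if r < 2:
        raise ValueError("need >= 2 populations with data")
    n = np.array([s[0] for s in stats])
    all_alleles = np.unique(np.concatenate([s[1] for s in stats]))
    nbar = n.mean()
    if nbar <= 1:
        raise ValueError("need > 1 individual per population on average")
    n_c = (r * nbar - np.sum(n ** 2) / (r * nbar)) / (r - 1)
    p = np.zeros((r, all_alleles.size))
    h = np.zeros((r, all_alleles.size))
    for i, (_, alleles, freqs, hets) in enumerate(stats):
        ix = np.searchsorted(all_alleles, alleles)
        p[i, ix] = freqs
        h[i, ix] = hets
    pbar = (n[:, None] * p).sum(axis=0) / (r * nbar)
    s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n[:, None] * h).sum(axis=0) / (r * nbar)
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar / n_c * (s2 - (inner - hbar / 4.0) / (nbar - 1))
    b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0
    return float(a.sum()), float(b.sum()), float(c.sum())


@dataclass
class FstMatrix:
    """Pairwise Weir-Cockerham theta with per-locus components retained.

    ``a`` and ``abc`` have shape (n_pop, n_pop, n_loci): the among-population
    component and the total component per locus for each pair; theta combines
    loci as the ratio of summed components.
    """

    labels: list[str]
    values: np.ndarray
    corrected: bool
    a: np.ndarray
    abc: np.ndarray

    def distance_matrix(self) -> DistanceMatrix:
        return DistanceMatrix(list(self.labels), self.values, kind="genetic",
                              transform="ena" if self.corrected else None)

    def write_phylip(self, path) -> None:
        self.distance_matrix().write_phylip(path)


def pairwise_fst(gt: GenotypeTable, correction: str = "none",
                 ena_deflate_n: bool = True, tol: float = 1e-8,
                 max_iter: int = 10000) -> FstMatrix:
    """Pairwise Weir & Cockerham theta between all populations.

    ``correction="ena"`` first adjusts visible allele frequencies and sample
    sizes per locus x population with the EM null-allele estimates (the
    "excluding null alleles" scheme); loci combine as the ratio of summed
    variance components.  A pair sharing no scored locus is an error.
    """
    if correction not in {"none", "ena"}:
        raise ValueError("correction must be 'none' or 'ena'")
    pops = gt.population_ids()
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    npop, L = len(pops), gt.n_loci
    stats_by_locus = [
        _pop_locus_stats(gt, li, pops, correction, ena_deflate_n, tol, max_iter)
        for li in range(L)
    ]
    a = np.zeros((npop, npop, L))
    abc = np.zeros((npop, npop, L))
    theta = np.zeros((npop, npop))
    for i in range(npop):
        for j in range(i + 1, npop):
            any_locus = False
            for li in range(L):
                si, sj = stats_by_locus[li][i], stats_by_locus[li][j]
                if si[0] < 2 or sj[0] < 2:
                    continue
                al, bl, cl = weir_cockerham_components([si, sj])
                a[i, j, li] = a[j, i, li] = al
                abc[i, j, li] = abc[j, i, li] = al + bl + cl
                any_locus = True
            if not any_locus:
                raise ValueError(
                    f"populations {pops[i]!r} and {pops[j]!r} share no scored locus"
                )
            denom = abc[i, j].sum()
            theta[i, j] = theta[j, i] = a[i, j].sum() / denom if denom else 0.0
    return FstMatrix(labels=pops, values=theta, corrected=correction == "ena",
                     a=a, abc=abc)


def global_theta(gt: GenotypeTable, correction: str = "none") -> float:
    """Multi-population Weir & Cockerham theta over all loci."""
    pops = gt.population_ids()
    a_sum = abc_sum = 0.0
    for li in range(gt.n_loci):
        stats = _pop_locus_stats(gt, li, pops, correction, True, 1e-8, 10000)
        stats = [s for s in stats if s[0] >= 1]
        if len(stats) < 2:
            continue
        al, bl, cl = weir_cockerham_components(stats)
        a_sum += al
        abc_sum += al + bl + cl
    if abc_sum == 0:
        raise ValueError("no informative locus")
    return a_sum / abc_sum


# ---------------------------------------------------------------------------
# Hierarchical F-statistics (nested ANOVA of allele indicators)
# ---------------------------------------------------------------------------

@dataclass
class HierarchicalFResult:
    """Moment-based hierarchical F-statistics with per-locus components.

    ``levels`` are the nesting labels from coarse to fine (e.g.
    ``["mountain", "population", "individual"]``); ``components`` is a
    (n_loci, n_levels + 1) array of variance components (the extra final
    column is the within-individual component); ``f`` maps
    ``"F_<fine>/<coarse>"`` to the point estimate and ``ci`` to percentile
    bootstrap intervals over loci (when computed).
    """

    levels: list[str]
    loci: list[str]
    components: np.ndarray
    f: dict[str, float]
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    low_information_groups: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, value in self.f.items():
            lo, hi = self.ci.get(name, (np.nan, np.nan))
            rows.append((name, value, lo, hi))
        return pd.DataFrame(rows, columns=["F", "estimate", "ci_low", "ci_high"]
                            ).set_index("F")

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.4f")


def _f_from_components(comp: np.ndarray, levels: Sequence[str]) -> dict[str, float]:
    """F-statistics as ratios of summed components.

    ``comp`` is the per-level component vector summed over loci, ordered
    coarse to fine with the within-individual component last.  F for fine
    level l against coarse level m sums the components strictly between m and
    l (inclusive of l) over the components from m down to the residual.
    """
    names = list(levels) + ["within"]
    total = ["T"] + list(levels)
    out: dict[str, float] = {}
    k = len(levels)
    for fine in range(k):           # component index of the fine level
        for coarse in range(fine + 1):
            num = comp[coarse:fine + 1].sum()
            den = comp[coarse:].sum()
            label = f"F_{levels[fine]}/{total[coarse]}"
            out[label] = float(num / den) if den else np.nan
    return out


def _henderson_components(values: np.ndarray, level_codes: np.ndarray) -> np.ndarray:
    """Henderson method-I variance components for a fully nested design.

    ``values``: (n_obs, n_alleles) indicator matrix of gene copies;
    ``level_codes``: (n_levels, n_obs) integer codes per nesting level from
    coarse to fine (the finest is the individual; the residual is between
    gene copies within individuals).  Returns the per-level components
    (n_levels + 1,), summed over alleles.
    """
    n_obs = values.shape[0]
    n_comp = level_codes.shape[0] + 1
    # A_l = sum over groups of (group total)^2 / group size, per allele;
    # level 0 is the grand total, the last "level" is the observation itself.
    A = np.empty((n_comp + 1, values.shape[1]))
    sizes: list[np.ndarray] = []
    A[0] = values.sum(axis=0) ** 2 / n_obs
    for ell in range(level_codes.shape[0]):
        codes = level_codes[ell]
        n_g = np.bincount(codes).astype(float)
        totals = np.zeros((n_g.size, values.shape[1]))
        np.add.at(totals, codes, values)
        A[ell + 1] = (totals ** 2 / n_g[:, None]).sum(axis=0)
        sizes.append(n_g)
    A[n_comp] = (values ** 2).sum(axis=0)
    ss = np.diff(A, axis=0).sum(axis=1)          # SS per nesting step, summed over alleles

    # expectation coefficients: k[l, m] for grouping level l, component m
    k = np.empty((n_comp + 1, n_comp))
    for ell in range(n_comp + 1):                # 0=total .. n_comp=observations
        for m in range(1, n_comp + 1):           # component m lives at level m
            if ell >= m:
                k[ell, m - 1] = n_obs
            else:
                if m == n_comp:                  # residual: unit-sized cells
                    sub = np.ones(n_obs)
                    codes_m = np.arange(n_obs)
                else:
                    sub = sizes[m - 1]
                    codes_m = level_codes[m - 1]
                if ell == 0:
                    k[ell, m - 1] = float(np.sum(sub ** 2) / n_obs)
                else:
                    codes_l = level_codes[ell - 1]
                    n_l = sizes[ell - 1]
                    # parent level-l group of each level-m cell (nested design:
                    # all observations of a cell share one parent)
                    parent = np.zeros(sub.size, dtype=int)
                    parent[codes_m] = codes_l
                    k[ell, m - 1] = float(np.sum(sub ** 2 / n_l[parent]))
    coeff = np.diff(k, axis=0)
    return np.linalg.solve(coeff, ss)


def hierarchical_f(gt: GenotypeTable, groups: Mapping[str, str] | None = None,
                   group_name: str = "Grp", B: int = 0, seed: int | None = None
                   ) -> HierarchicalFResult:
    """Hierarchical F-statistics with an optional grouping of populations.

    Levels are total > [group >] population > individual > gene copy; the
    variance components come from an unbalanced nested ANOVA of allele
    indicator variables, pooled over alleles within a locus and combined over
    loci as ratios of summed components.  ``B > 0`` adds a percentile
    bootstrap over loci (resampling loci with replacement) for every F.
    """
    pops = gt.population_ids()
    level_names = ["Pop", "Ind"]
    low_info: list[str] = []
    if groups is not None:
        missing = [p for p in pops if p not in groups]
        if missing:
            raise ValueError(f"populations without a group label: {missing}")
        level_names = [group_name, "Pop", "Ind"]
        counts = pd.Series([groups[p] for p in pops]).value_counts()
        low_info = [str(g) for g, c in counts.items() if c == 1]
        if low_info:
            warnings.warn(
                f"groups with a single population (low information): {low_info}"
            )
    pop_code = {p: i for i, p in enumerate(pops)}
    n_levels = len(level_names)
    comp = np.zeros((gt.n_loci, n_levels + 1))
    for li in range(gt.n_loci):
        scored = gt.calls[:, li, 0] != MISSING
        idx = np.flatnonzero(scored)
        obs = gt.calls[idx, li, :]                      # (k, 2)
        alleles = np.unique(obs)
        copies = obs.reshape(-1)                        # gene copies, 2 per ind
        values = (copies[:, None] == alleles).astype(float)
        ind_codes = np.repeat(np.arange(idx.size), 2)
        pop_of_obs = np.repeat(
            np.array([pop_code[gt.populations[i]] for i in idx]), 2
        )
        code_levels = []
        if groups is not None:
            group_labels = sorted({groups[p] for p in pops})
            g_code = {g: i for i, g in enumerate(group_labels)}
            grp_of_obs = np.array([g_code[groups[pops[c]]] for c in pop_of_obs])
            code_levels.append(grp_of_obs)
        code_levels.append(pop_of_obs)
        code_levels.append(ind_codes)
        # re-code each level to consecutive ints (required by bincount)
        coded = []
        for lv in code_levels:
            _, inv = np.unique(lv, return_inverse=True)
            coded.append(inv)
        comp[li] = _henderson_components(values, np.asarray(coded))

    f = _f_from_components(comp.sum(axis=0), level_names)
    ci: dict[str, tuple[float, float]] = {}
    if B > 0:
        rng = np.random.default_rng(seed)
        boots = {k: [] for k in f}
        for _ in range(B):
            pick = rng.integers(0, gt.n_loci, size=gt.n_loci)
            fb = _f_from_components(comp[pick].sum(axis=0), level_names)
            for k, v in fb.items():
                boots[k].append(v)
        for k, vals in boots.items():
            arr = np.asarray(vals)
            arr = arr[np.isfinite(arr)]
            if arr.size:
                ci[k] = (float(np.percentile(arr, 2.5)),
                         float(np.percentile(arr, 97.5)))
    return HierarchicalFResult(levels=level_names, loci=list(gt.loci),
                               components=comp, f=f, ci=ci,
                               low_information_groups=low_info)
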