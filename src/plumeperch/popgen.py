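"""Reference population-genetic statistics and permutation tests.

Implements the classical toolbox for codominant markers:

* Hardy–Weinberg exact test (Levene conditional probability of the genotype
  array, Monte Carlo over random re-pairings of gene copies — the
  Guo–Thompson style sampler).
* Linkage disequilibrium: permutation G-test on the two-locus genotype
  contingency table.
* Weir & Cockerham's (1984) theta — the variance-components F_ST estimator —
  with a permutation significance test.
* Monte Carlo exact test of allelic differentiation (Raymond–Rousset style),
  combined across loci with Fisher's method.
* Three-level hierarchical AMOVA (years / plumes within years / within
  plumes) on allele-identity distances between gene copies.

All Monte Carlo routines take an explicit seed and use the add-one rule
``p = (1 + hits) / (n_perm + 1)`` so that estimated p-values are never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

from .genotype_data import MISSING, GenotypeDataset

_EPS = 1e-9


# ------------------------------------------------------------ allele counts


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele counts for one group, on a dataset-wide code space.

    ``codes[l]`` is the sorted array of allele codes observed at locus ``l``
    anywhere in the source dataset (so tables from different groups align);
    ``counts[l]`` are this group's gene-copy counts on that code space and
    ``n_copies[l]`` their sum (``2 * N`` at a fully-typed locus).
    """

    group: str | None
    locus_names: list[str]
    codes: list[np.ndarray]
    counts: list[np.ndarray]

    def __post_init__(self) -> None:
        for l, (cd, ct) in enumerate(zip(self.codes, self.counts)):
            if len(cd) != len(ct):
                raise ValueError(f"locus {self.locus_names[l]}: code/count mismatch")
            if np.any(ct < 0):
                raise ValueError("negative allele count")

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def n_copies(self) -> np.ndarray:
        return np.array([int(c.sum()) for c in self.counts])

    def frequencies(self, locus: int) -> np.ndarray:
        total = self.counts[locus].sum()
        if total == 0:
            return np.zeros_like(self.counts[locus], dtype=float)
        return self.counts[locus] / total

    @classmethod
    def from_dataset(
        cls,
        dataset: GenotypeDataset,
        group: str | None = None,
        codes: list[np.ndarray] | None = None,
    ) -> "AlleleFrequencyTable":
        """Count gene copies for ``group`` (or everyone) on shared code axes.

        ``codes`` defaults to the pooled allele codes of ``dataset`` so that
        tables built for different groups of the same dataset align.
        """
        if codes is None:
            codes = [
                np.asarray(loc.allele_codes, dtype=np.int64) for loc in dataset.loci()
            ]
        sub = dataset if group is None else dataset.select_group(group)
        counts = []
        for l in range(dataset.n_loci):
            pairs = sub.alleles[:, l, :]
            called = pairs[pairs[:, 0] != MISSING].ravel()
            idx = np.searchsorted(codes[l], called)
            ok = (idx < len(codes[l])) & (codes[l][np.minimum(idx, len(codes[l]) - 1)] == called)
            if not np.all(ok):
                bad = np.unique(called[~ok])
                raise ValueError(
                    f"locus {dataset.locus_names[l]}: allele(s) {bad.tolist()} "
                    "absent from the supplied code space"
                )
            counts.append(np.bincount(idx, minlength=len(codes[l])).astype(np.int64))
        return cls(group=group, locus_names=list(dataset.locus_names), codes=codes, counts=counts)


def pooled_allele_counts(dataset: GenotypeDataset) -> AlleleFrequencyTable:
    """Allele counts pooled over every group of ``dataset``."""
    return AlleleFrequencyTable.from_dataset(dataset, group=None)


def bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> tuple[float, np.ndarray]:
    """Per-table Bonferroni: returns (alpha / k, significance flags)."""
    p = np.asarray(list(p_values), dtype=float)
    k = p.size
    if k == 0:
        return alpha, np.zeros(0, dtype=bool)
    corrected = alpha / k
    return corrected, p < corrected


# ----------------------------------------------------------------- HWE test


@dataclass
class HweResult:
    p_value: float
    monomorphic: bool
    log_prob: float  # log Levene probability of the observed array
    n: int           # individuals typed at the locus


def _levene_log_prob_terms(genotype_counts: np.ndarray, n_het: int) -> float:
    """The permutation-variable part of the Levene log-probability.

    For fixed allele counts only ``h * ln 2 - sum ln(n_g!)`` varies over
    re-pairings of the gene copies.
    """
    return n_het * np.log(2.0) - float(gammaln(genotype_counts + 1).sum())


def levene_log_prob(allele_counts: np.ndarray, genotype_counts: np.ndarray, n_het: int) -> float:
    """log P(genotype array | allele counts) under random pairing (Levene)."""
    n = int(genotype_counts.sum())
    const = (
        gammaln(n + 1)
        + float(gammaln(allele_counts + 1).sum())
        - gammaln(2 * n + 1)
    )
    return float(const + _levene_log_prob_terms(genotype_counts, n_het))


def hwe_test(
    dataset: GenotypeDataset,
    group: str,
    locus: str | int,
    n_perm: int = 20000,
    seed: int | None = None,
) -> HweResult:
    """Monte Carlo exact HWE test for one locus in one group.

    The statistic is the Levene conditional probability of the genotype
    array given the allele counts; the null distribution is sampled by
    randomly re-pairing the locus's gene copies.  A monomorphic locus
    returns p = 1 with ``monomorphic=True`` rather than an error.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    l = dataset.locus_index(locus)
    sub = dataset.select_group(group)
    pairs = sub.alleles[:, l, :]
    pairs = pairs[pairs[:, 0] != MISSING]
    n = len(pairs)
    if n < 2:
        raise ValueError(f"locus {locus!r} in group {group!r}: fewer than 2 typed individuals")
    codes, inverse = np.unique(pairs, return_inverse=True)
    K = len(codes)
    if K == 1:
        return HweResult(p_value=1.0, monomorphic=True, log_prob=0.0, n=n)
    idx_pairs = inverse.reshape(n, 2)
    allele_counts = np.bincount(idx_pairs.ravel(), minlength=K)

    def _terms(ip: np.ndarray) -> float:
        lo = ip.min(axis=1)
        hi = ip.max(axis=1)
        gcounts = np.bincount(lo * K + hi, minlength=K * K)
        n_het = int((lo != hi).sum())
        return _levene_log_prob_terms(gcounts, n_het)

    obs_terms = _terms(idx_pairs)
    copies = idx_pairs.ravel()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(copies).reshape(n, 2)
        if _terms(perm) <= obs_terms + _EPS:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    lo = idx_pairs.min(axis=1)
    hi = idx_pairs.max(axis=1)
    gcounts = np.bincount(lo * K + hi, minlength=K * K)
    log_prob = levene_log_prob(allele_counts, gcounts, int((lo != hi).sum()))
    return HweResult(p_value=float(p), monomorphic=False, log_prob=log_prob, n=n)


# ------------------------------------------------------------------ LD test


def ld_test(
    dataset: GenotypeDataset,
    group: str,
    locus_a: str | int,
    locus_b: str | int,
    n_perm: int = 20000,
    seed: int | None = None,
) -> float:
    """Permutation G-test of genotypic linkage disequilibrium.

    Builds the two-locus genotype contingency table over individuals typed
    at both loci, and permutes one locus's genotypes across individuals.
    Either locus monomorphic => p = 1 (no association possible).
    """
    la, lb = dataset.locus_index(locus_a), dataset.locus_index(locus_b)
    sub = dataset.select_group(group)
    pa = sub.alleles[:, la, :]
    pb = sub.alleles[:, lb, :]
    shared = (pa[:, 0] != MISSING) & (pb[:, 0] != MISSING)
    if int(shared.sum()) < 2:
        raise ValueError("fewer than 2 individuals typed at both loci")
    pa, pb = pa[shared], pb[shared]

    def _geno_ids(p: np.ndarray) -> tuple[np.ndarray, int]:
        _, inv = np.unique(p[:, 0] * 10_000 + p[:, 1], return_inverse=True)
        return inv, int(inv.max()) + 1

    ga, ka = _geno_ids(pa)
    gb, kb = _geno_ids(pb)
    if ka == 1 or kb == 1:
        return 1.0

    n = len(ga)
    row = np.bincount(ga, minlength=ka).astype(float)
    col = np.bincount(gb, minlength=kb).astype(float)
    expected = np.outer(row, col) / n

    def _g_stat(gb_perm: np.ndarray) -> float:
        obs = np.bincount(ga * kb + gb_perm, minlength=ka * kb).astype(float)
        nz = obs > 0
        return 2.0 * float(np.sum(obs[nz] * np.log(obs[nz] / expected.ravel()[nz])))

    g_obs = _g_stat(gb)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _g_stat(rng.permutation(gb)) >= g_obs - _EPS:
            hits += 1
    return float((1 + hits) / (n_perm + 1))


# --------------------------------------------------- Weir–Cockerham theta


@dataclass
class FstResult:
    per_locus_theta: pd.Series
    theta: float
    components: pd.DataFrame  # per-locus a, b, c sums over alleles
    p_value: float
    excluded_loci: list[str] = field(default_factory=list)


def _wc_locus_components(
    pairs_by_pop: list[np.ndarray],
) -> tuple[float, float, float] | None:
    """Weir & Cockerham (1984) variance components for one locus.

    ``pairs_by_pop``: per population, the (n_i, 2) called allele-code pairs.
    Returns summed-over-alleles (a, b, c), or None when the locus is
    unusable (fewer than two populations with data, or monomorphic).
    """
    pops = [p for p in pairs_by_pop if len(p) > 0]
    r = len(pops)
    if r < 2:
        return None
    all_codes = np.unique(np.concatenate([p.ravel() for p in pops]))
    if len(all_codes) < 2:
        return None
    K = len(all_codes)
    n_i = np.array([len(p) for p in pops], dtype=float)
    freqs = np.zeros((r, K))
    hets = np.zeros((r, K))  # per-pop proportion of individuals het for allele k
    for i, p in enumerate(pops):
        idx = np.searchsorted(all_codes, p)
        freqs[i] = np.bincount(idx.ravel(), minlength=K) / (2 * n_i[i])
        het_rows = p[:, 0] != p[:, 1]
        if het_rows.any():
            hk = np.bincount(idx[het_rows].ravel(), minlength=K)
        else:
            hk = np.zeros(K)
        hets[i] = hk / n_i[i]

    n_bar = n_i.mean()
    if n_bar <= 1:
        return None
    n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
    if n_c <= 0:
        return None
    p_bar = (n_i[:, None] * freqs).sum(axis=0) / (r * n_bar)
    s2 = (n_i[:, None] * (freqs - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i[:, None] * hets).sum(axis=0) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def _multilocus_theta(
    dataset: GenotypeDataset, masks: list[np.ndarray]
) -> tuple[float, pd.DataFrame, list[str]]:
    rows = []
    excluded = []
    for l, name in enumerate(dataset.locus_names):
        pairs_by_pop = []
        for m in masks:
            pr = dataset.alleles[m, l, :]
            pairs_by_pop.append(pr[pr[:, 0] != MISSING])
        comp = _wc_locus_components(pairs_by_pop)
        if comp is None or abs(sum(comp)) < 1e-300:
            excluded.append(name)
            continue
        rows.append((name, *comp))
    comps = pd.DataFrame(rows, columns=["locus", "a", "b", "c"]).set_index("locus")
    denom = float((comps["a"] + comps["b"] + comps["c"]).sum())
    theta = float(comps["a"].sum() / denom) if denom != 0 else np.nan
    return theta, comps, excluded


def weir_cockerham_fst(
    dataset: GenotypeDataset,
    group_a: str,
    group_b: str,
    n_perm: int = 0,
    seed: int | None = None,
) -> FstResult:
    """Weir & Cockerham theta between two groups with a permutation test.

    Per-locus theta is ``a / (a + b + c)`` (summed over alleles); the
    multilocus estimate is the ratio of the sums over loci.  Monomorphic
    loci (a + b + c = 0) are excluded from the sums and reported.
    Significance permutes individuals between the groups; negative per-locus
    estimates are kept as computed.
    """
    ma = dataset.group_mask(group_a)
    mb = dataset.group_mask(group_b)
    if not ma.any() or not mb.any():
        raise ValueError("both groups must be nonempty")
    theta, comps, excluded = _multilocus_theta(dataset, [ma, mb])
    if comps.empty:
        raise ValueError("no polymorphic locus shared by the two groups")
    per_locus = comps["a"] / (comps["a"] + comps["b"] + comps["c"])

    p_value = np.nan
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        idx = np.flatnonzero(ma | mb)
        na = int(ma.sum())
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(idx)
            pa = np.zeros(dataset.n_individuals, dtype=bool)
            pb = np.zeros(dataset.n_individuals, dtype=bool)
            pa[perm[:na]] = True
            pb[perm[na:]] = True
            t, _, _ = _multilocus_theta(dataset, [pa, pb])
            if not np.isnan(t) and t >= theta - _EPS:
                hits += 1
        p_value = (1 + hits) / (n_perm + 1)

    return FstResult(
        per_locus_theta=per_locus.rename("theta"),
        theta=theta,
        components=comps,
        p_value=float(p_value),
        excluded_loci=excluded,
    )


# ----------------------------------------- exact allelic differentiation


@dataclass
class ExactTestResult:
    per_locus_p: pd.Series
    combined_statistic: float  # -2 sum ln p_l
    combined_df: int
    combined_p: float


def exact_differentiation(
    dataset: GenotypeDataset,
    group_a: str,
    group_b: str,
    n_dememorization: int = 10000,
    n_perm: int = 20000,
    seed: int | None = None,
) -> ExactTestResult:
    """Monte Carlo exact test of allele-frequency differentiation per locus.

    The statistic is the multivariate-hypergeometric probability of the
    group x allele count table given its margins; p is the tail probability
    of tables as or less probable than observed, estimated by direct
    resampling (permuting gene copies between the groups).  The
    ``n_dememorization`` argument is accepted for interface parity with
    Markov-chain samplers and is a no-op for this direct sampler.
    Per-locus p-values are combined with Fisher's method (chi-square with
    2L degrees of freedom).
    """
    del n_dememorization  # direct sampler: burn-in is meaningless
    rng = np.random.default_rng(seed)
    ma = dataset.group_mask(group_a)
    mb = dataset.group_mask(group_b)
    if not ma.any() or not mb.any():
        raise ValueError("both groups must be nonempty")
    pvals = {}
    for l, name in enumerate(dataset.locus_names):
        pa = dataset.alleles[ma, l, :]
        pb = dataset.alleles[mb, l, :]
        ca = pa[pa[:, 0] != MISSING].ravel()
        cb = pb[pb[:, 0] != MISSING].ravel()
        if len(ca) == 0 or len(cb) == 0:
            pvals[name] = 1.0
            continue
        pooled = np.concatenate([ca, cb])
        codes, inv = np.unique(pooled, return_inverse=True)
        if len(codes) < 2:
            pvals[name] = 1.0  # monomorphic across both groups
            continue
        K = len(codes)
        na = len(ca)

        def _cell_term(inv_arr: np.ndarray) -> float:
            ta = np.bincount(inv_arr[:na], minlength=K)
            tb = np.bincount(inv_arr[na:], minlength=K)
            return float(gammaln(ta + 1).sum() + gammaln(tb + 1).sum())

        obs = _cell_term(inv)
        hits = 0
        for _ in range(n_perm):
            if _cell_term(rng.permutation(inv)) >= obs - _EPS:
                hits += 1
        pvals[name] = (1 + hits) / (n_perm + 1)

    series = pd.Series(pvals, name="p")
    stat = float(-2.0 * np.log(series.clip(lower=1e-300)).sum())
    df = 2 * len(series)
    combined_p = float(chi2_dist.sf(stat, df))
    return ExactTestResult(
        per_locus_p=series, combined_statistic=stat, combined_df=df, combined_p=combined_p
    )


# -------------------------------------------------------------------- AMOVA


@dataclass
class AmovaResult:
    table: pd.DataFrame  # index: level; columns: df, sigma2, percent, p
    phi_ct: float  # among years / total
    phi_sc: float  # among plumes within years / within-year
    phi_st: float  # (years + plumes) / total

    @property
    def percent(self) -> pd.Series:
        return self.table["percent"]


def _amova_components(
    alleles: np.ndarray,
    group_idx: np.ndarray,
    year_of_group: np.ndarray,
    n_groups: int,
    n_years: int,
) -> np.ndarray:
    """Summed-over-loci variance components (sigma_a, sigma_b, sigma_c).

    Distances between gene copies are allele-identity (0/1 per locus,
    summed over loci), so every sum of squared distances reduces to allele
    counts:  sum_{i<j in S} d_l = (N_S^2 - sum_a c_a^2) / 2.
    Components are estimated locus by locus from that locus's non-missing
    copy counts and summed.
    """
    n_loci = alleles.shape[1]
    sigma = np.zeros(3)
    for l in range(n_loci):
        pairs = alleles[:, l, :]
        called = pairs[:, 0] != MISSING
        if not called.any():
            continue
        gi = np.repeat(group_idx[called], 2)
        codes, inv = np.unique(pairs[called].ravel(), return_inverse=True)
        K = len(codes)
        if K < 2:
            continue
        flat = np.bincount(gi * K + inv, minlength=n_groups * K)
        counts_g = flat.reshape(n_groups, K).astype(float)
        n_g = counts_g.sum(axis=1)
        if (n_g > 0).sum() < 2:
            continue
        counts_y = np.zeros((n_years, K))
        for g in range(n_groups):
            counts_y[year_of_group[g]] += counts_g[g]
        n_y = counts_y.sum(axis=1)
        total = counts_g.sum(axis=0)
        n_tot = total.sum()

        def _ss(counts: np.ndarray, n: float) -> float:
            if n <= 0:
                return 0.0
            return (n * n - float((counts**2).sum())) / (2.0 * n)

        ss_total = _ss(total, n_tot)
        ss_groups = sum(_ss(counts_g[g], n_g[g]) for g in range(n_groups))
        ss_years = sum(_ss(counts_y[y], n_y[y]) for y in range(n_years))
        ss_wp = ss_groups                      # within plumes
        ss_ap = ss_years - ss_groups           # among plumes within years
        ss_ay = ss_total - ss_years            # among years

        G = int((n_g > 0).sum())
        Y = int((n_y > 0).sum())
        df_a, df_b, df_c = Y - 1, G - Y, n_tot - G
        if df_b <= 0 or df_c <= 0:
            continue
        ms_c = ss_wp / df_c
        ms_b = ss_ap / df_b
        # per-year sum of squared group sizes over year size
        s_y = 0.0
        for y_i in range(n_years):
            if n_y[y_i] > 0:
                sizes = n_g[year_of_group == y_i]
                s_y += float((sizes**2).sum()) / n_y[y_i]
        s1 = float((n_g**2).sum())
        n_coef = (n_tot - s_y) / df_b
        sigma_c = ms_c
        sigma_b = (ms_b - sigma_c) / n_coef if n_coef > 0 else 0.0
        if df_a > 0:
            ms_a = ss_ay / df_a
            n_p = (s_y - s1 / n_tot) / df_a
            n_pp = (n_tot - float((n_y**2).sum()) / n_tot) / df_a
            sigma_a = (ms_a - sigma_c - n_p * sigma_b) / n_pp if n_pp > 0 else 0.0
        else:
            sigma_a = 0.0
        sigma += np.array([sigma_a, sigma_b, sigma_c])
    return sigma


def amova(
    dataset: GenotypeDataset,
    year_of_group: Mapping[str, object],
    plume_of_group: Mapping[str, object],
    n_perm: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA: among years / among plumes within years / within.

    Gene copies are compared by allele identity (0 if the same allele code,
    1 otherwise, summed over loci) — the ``conventional F_ST`` distance.
    Negative variance components are reported as computed.  Permutation
    schemes per level: whole plume groups among years (sigma_a);
    individuals among plumes within years (sigma_b / Phi_SC); individuals
    among all groups (Phi_ST).
    """
    groups = dataset.group_names
    for g in groups:
        if g not in year_of_group or g not in plume_of_group:
            raise ValueError(f"group {g!r} lacks a year or plume label")
    years = sorted({year_of_group[g] for g in groups})
    if len(years) < 2:
        raise ValueError("AMOVA level 'among years' has zero df (need >= 2 years)")
    for y in years:
        plumes_y = {plume_of_group[g] for g in groups if year_of_group[g] == y}
        if len(plumes_y) < 2:
            raise ValueError(
                f"AMOVA level 'among plumes within years' has zero df in year {y!r}"
            )
    n_groups = len(groups)
    group_to_idx = {g: i for i, g in enumerate(groups)}
    group_idx = np.array([group_to_idx[g] for g in dataset.groups])
    year_idx_of_group = np.array([years.index(year_of_group[g]) for g in groups])
    n_years = len(years)

    obs = _amova_components(
        dataset.alleles, group_idx, year_idx_of_group, n_groups, n_years
    )
    total = float(obs.sum())
    percent = 100.0 * obs / total if total != 0 else np.full(3, np.nan)

    phi_ct = obs[0] / total if total != 0 else np.nan
    within_year = obs[1] + obs[2]
    phi_sc = obs[1] / within_year if within_year != 0 else np.nan
    phi_st = (obs[0] + obs[1]) / total if total != 0 else np.nan

    # design degrees of freedom (gene copies; missing handled per locus in
    # the component estimates)
    n_copies = 2 * dataset.n_individuals
    df = [n_years - 1, n_groups - n_years, n_copies - n_groups]

    rng = np.random.default_rng(seed)
    p_vals = [np.nan, np.nan, np.nan]
    if n_perm > 0:
        # level a: permute whole groups among years (keep per-year group counts)
        hits_a = 0
        for _ in range(n_perm):
            perm_years = rng.permutation(year_idx_of_group)
            comp = _amova_components(
                dataset.alleles, group_idx, perm_years, n_groups, n_years
            )
            if comp[0] >= obs[0] - _EPS:
                hits_a += 1
        p_vals[0] = (1 + hits_a) / (n_perm + 1)

        # level b: permute individuals among plumes within their year
        year_of_ind = year_idx_of_group[group_idx]
        hits_b = 0
        for _ in range(n_perm):
            perm_groups = group_idx.copy()
            for y in range(n_years):
                sel = np.flatnonzero(year_of_ind == y)
                perm_groups[sel] = group_idx[sel][rng.permutation(len(sel))]
            comp = _amova_components(
                dataset.alleles, perm_groups, year_idx_of_group, n_groups, n_years
            )
            wy = comp[1] + comp[2]
            stat = comp[1] / wy if wy != 0 else -np.inf
            ref = phi_sc if not np.isnan(phi_sc) else -np.inf
            if stat >= ref - _EPS:
                hits_b += 1
        p_vals[1] = (1 + hits_b) / (n_perm + 1)

        # level c (Phi_ST): permute individuals among all groups
        hits_c = 0
        for _ in range(n_perm):
            perm_groups = group_idx[rng.permutation(len(group_idx))]
            comp = _amova_components(
                dataset.alleles, perm_groups, year_idx_of_group, n_groups, n_years
            )
            t = comp.sum()
            stat = (comp[0] + comp[1]) / t if t != 0 else -np.inf
            ref = phi_st if not np.isnan(phi_st) else -np.inf
            if stat >= ref - _EPS:
                hits_c += 1
        p_vals[2] = (1 + hits_c) / (n_perm + 1)

    table = pd.DataFrame(
        {
            "df": df,
            "sigma2": obs,
            "percent": percent,
            "p": p_vals,
        },
        index=["among_years", "among_plumes_within_years", "within_plumes"],
    )
    return AmovaResult(
        table=table, phi_ct=float(phi_ct), phi_sc=float(phi_sc), phi_st=float(phi_st)
    )
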