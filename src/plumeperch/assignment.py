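"""Individual genotype assignment to candidate source populations.

Two likelihood criteria are provided:

* **Bayesian** (Rannala & Mountain): the posterior-predictive genotype
  probability under a per-locus Dirichlet(1/k, ..., 1/k) prior on the
  reference allele frequencies, where ``k`` is the number of alleles
  observed at the locus across all reference groups pooled.  With reference
  counts ``n_a`` and total gene copies ``n``::

      P(aa) = (n_a + 1/k)(n_a + 1 + 1/k) / ((n + 1)(n + 2))
      P(ab) = 2 (n_a + 1/k)(n_b + 1/k)  / ((n + 1)(n + 2))

* **Frequency** (Paetkau-style): plain Hardy–Weinberg genotype probability
  from the observed reference frequencies, with a floor frequency
  substituted for any allele unseen in the reference.

On top of these sit the leave-one-out self-assignment migrant screen, the
Monte Carlo exclusion test (likelihood of the focal genotype ranked against
genotypes simulated from the reference frequencies), and the two-step
juvenile assignment used for mixed-stock recruitment estimation: exclusion
from both candidate sources first, then rank-based assignment at a
normalized-probability threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .genotype_data import MISSING, GenotypeDataset
from .popgen import AlleleFrequencyTable, weir_cockerham_fst

_EPS = 1e-9


@dataclass
class AssignmentConfig:
    """Thresholds and likelihood choices for the assignment pipeline.

    ``migrant_threshold``: a reference individual whose normalized
    self-assignment probability falls below this is flagged a migrant.
    ``assign_threshold``: minimum normalized probability for a successful
    rank-based assignment (must exceed 0.5 so at most one group can pass).
    ``exclusion_alpha``: an unknown is excluded when its exclusion p-value
    is below this for *both* candidate sources; 0 disables exclusion.
    """

    migrant_method: str = "bayesian"
    assign_method: str = "frequency"
    exclusion_method: str = "bayesian"
    migrant_threshold: float = 0.60
    assign_threshold: float = 0.70
    exclusion_alpha: float = 0.10
    n_simulated: int = 10000
    rare_allele_floor: float = 0.01
    min_loci: int = 6
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("migrant_method", "assign_method", "exclusion_method"):
            if getattr(self, name) not in ("bayesian", "frequency"):
                raise ValueError(f"{name} must be 'bayesian' or 'frequency'")
        for name in ("migrant_threshold", "assign_threshold"):
            v = getattr(self, name)
            if not (0.5 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0.5, 1]")
        if not (0.0 <= self.exclusion_alpha < 1.0):
            raise ValueError("exclusion_alpha must lie in [0, 1)")
        if not (0.0 < self.rare_allele_floor < 1.0):
            raise ValueError("rare_allele_floor must lie in (0, 1)")
        if self.n_simulated < 100 and self.exclusion_alpha > 0:
            raise ValueError("n_simulated must be >= 100")


@dataclass
class AssignmentResult:
    id: str
    group: str  # collection group
    log_likelihoods: dict[str, float]
    probabilities: dict[str, float]
    exclusion_p: dict[str, float]
    category: str
    n_loci_used: int


def results_to_frame(results: Sequence[AssignmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row: dict[str, object] = {"id": r.id, "group": r.group}
        for g, v in r.log_likelihoods.items():
            row[f"ll_{g}"] = v
        for g, v in r.probabilities.items():
            row[f"p_{g}"] = v
        for g, v in r.exclusion_p.items():
            row[f"excl_p_{g}"] = v
        row["category"] = r.category
        row["n_loci"] = r.n_loci_used
        rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------- per-locus likelihoods


def _counts_for(table: AlleleFrequencyTable, locus: int, alleles: np.ndarray) -> np.ndarray:
    """Reference gene-copy counts for the queried allele codes (0 if unseen)."""
    codes, counts = table.codes[locus], table.counts[locus]
    if len(codes) == 0:
        return np.zeros(alleles.shape, dtype=float)
    idx = np.clip(np.searchsorted(codes, alleles), 0, len(codes) - 1)
    hit = codes[idx] == alleles
    return np.where(hit, counts[idx], 0).astype(float)


def locus_log_likelihoods(
    alleles: np.ndarray,
    table: AlleleFrequencyTable,
    k_per_locus: np.ndarray,
    method: str = "bayesian",
    floor: float = 0.01,
) -> np.ndarray:
    """Per-locus genotype log-likelihoods under one reference table.

    ``alleles``: ``(n, L, 2)`` codes, 0 = missing -> NaN in the output.
    """
    n_ind, n_loci, _ = alleles.shape
    out = np.full((n_ind, n_loci), np.nan)
    for l in range(n_loci):
        a = alleles[:, l, 0]
        b = alleles[:, l, 1]
        called = a != MISSING
        if not called.any():
            continue
        na = _counts_for(table, l, a[called])
        nb = _counts_for(table, l, b[called])
        n = float(table.counts[l].sum())
        het = a[called] != b[called]
        if method == "bayesian":
            k = float(k_per_locus[l])
            denom = (n + 1.0) * (n + 2.0)
            hom_p = (na + 1.0 / k) * (na + 1.0 + 1.0 / k) / denom
            het_p = 2.0 * (na + 1.0 / k) * (nb + 1.0 / k) / denom
        elif method == "frequency":
            pa = na / n if n > 0 else np.zeros_like(na)
            pb = nb / n if n > 0 else np.zeros_like(nb)
            pa = np.where(pa <= 0.0, floor, pa)
            pb = np.where(pb <= 0.0, floor, pb)
            hom_p = pa * pa
            het_p = 2.0 * pa * pb
        else:
            raise ValueError(f"unknown method {method!r}")
        out[called, l] = np.log(np.where(het, het_p, hom_p))
    return out


def genotype_log_likelihood(
    alleles: np.ndarray,
    table: AlleleFrequencyTable,
    k_per_locus: np.ndarray,
    method: str = "bayesian",
    floor: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Summed log-likelihood and loci-used count per individual.

    Missing loci are skipped.  An individual with zero usable loci raises.
    """
    per_locus = locus_log_likelihoods(alleles, table, k_per_locus, method, floor)
    used = (~np.isnan(per_locus)).sum(axis=1)
    if np.any(used == 0):
        raise ValueError("individual with zero usable loci")
    return np.nansum(per_locus, axis=1), used


def bayesian_genotype_likelihood(
    alleles: np.ndarray, table: AlleleFrequencyTable, k_per_locus: np.ndarray
) -> np.ndarray:
    """Rannala–Mountain multilocus log-likelihood (vectorized over rows)."""
    ll, _ = genotype_log_likelihood(alleles, table, k_per_locus, method="bayesian")
    return ll


def frequency_genotype_likelihood(
    alleles: np.ndarray, table: AlleleFrequencyTable, floor: float = 0.01
) -> np.ndarray:
    """HWE frequency-method multilocus log-likelihood with rare-allele floor."""
    k = np.ones(len(table.locus_names))  # unused by the frequency method
    ll, _ = genotype_log_likelihood(alleles, table, k, method="frequency", floor=floor)
    return ll


def reference_k(dataset: GenotypeDataset, groups: Sequence[str]) -> np.ndarray:
    """Alleles per locus pooled across the reference groups (the 1/k prior)."""
    sub = dataset.select_group(list(groups))
    k = []
    for l in range(sub.n_loci):
        pairs = sub.alleles[:, l, :]
        called = pairs[pairs[:, 0] != MISSING]
        k.append(len(np.unique(called)) if len(called) else 1)
    return np.asarray(k, dtype=float)


def _normalized_probabilities(ll_matrix: np.ndarray) -> np.ndarray:
    """Row-wise softmax over candidate groups via log-sum-exp."""
    return np.exp(ll_matrix - logsumexp(ll_matrix, axis=1, keepdims=True))


# ------------------------------------------------------- migrant screening


def self_assign(
    dataset: GenotypeDataset,
    reference_groups: Sequence[str],
    config: AssignmentConfig | None = None,
) -> list[AssignmentResult]:
    """Leave-one-out self-assignment of reference individuals.

    Each individual's own two gene copies per locus are removed from its
    home group's counts before computing its home likelihood, so its own
    alleles never inflate self-assignment.  An individual whose normalized
    home probability falls below ``migrant_threshold`` is flagged
    ``migrant``; others are ``resident``.
    """
    config = config or AssignmentConfig()
    groups = list(reference_groups)
    sub = dataset.select_group(groups)
    tables = {g: AlleleFrequencyTable.from_dataset(sub, g) for g in groups}
    k = reference_k(dataset, groups)
    method, floor = config.migrant_method, config.rare_allele_floor

    # cross-group likelihoods computed in bulk; home likelihoods corrected
    # individual-by-individual for the leave-one-out.
    ll = {
        g: locus_log_likelihoods(sub.alleles, tables[g], k, method, floor)
        for g in groups
    }
    results: list[AssignmentResult] = []
    for i in range(sub.n_individuals):
        home = str(sub.groups[i])
        lls: dict[str, float] = {}
        n_used = 0
        for g in groups:
            if g != home:
                vals = ll[g][i]
                lls[g] = float(np.nansum(vals))
                continue
            total = 0.0
            table = tables[g]
            for l in range(sub.n_loci):
                a, b = sub.alleles[i, l, :]
                if a == MISSING:
                    continue
                n_used += 1
                na = float(_counts_for(table, l, np.array([a]))[0])
                nb = float(_counts_for(table, l, np.array([b]))[0])
                n = float(table.counts[l].sum())
                # remove this individual's own copies
                if a == b:
                    na_adj = na - 2.0
                    nb_adj = na_adj
                else:
                    na_adj, nb_adj = na - 1.0, nb - 1.0
                n_adj = n - 2.0
                if method == "bayesian":
                    denom = (n_adj + 1.0) * (n_adj + 2.0)
                    if a == b:
                        term = (na_adj + 1.0 / k[l]) * (na_adj + 1.0 + 1.0 / k[l]) / denom
                    else:
                        term = 2.0 * (na_adj + 1.0 / k[l]) * (nb_adj + 1.0 / k[l]) / denom
                else:
                    pa = na_adj / n_adj if n_adj > 0 else 0.0
                    pb = nb_adj / n_adj if n_adj > 0 else 0.0
                    pa = floor if pa <= 0 else pa
                    pb = floor if pb <= 0 else pb
                    term = pa * pa if a == b else 2.0 * pa * pb
                total += float(np.log(term))
            lls[g] = total
        if n_used == 0:
            raise ValueError(f"individual {sub.ids[i]!r}: zero usable loci")
        ll_vec = np.array([lls[g] for g in groups])[None, :]
        probs = _normalized_probabilities(ll_vec)[0]
        prob_map = {g: float(p) for g, p in zip(groups, probs)}
        category = "migrant" if prob_map[home] < config.migrant_threshold else "resident"
        results.append(
            AssignmentResult(
                id=sub.ids[i],
                group=home,
                log_likelihoods=lls,
                probabilities=prob_map,
                exclusion_p={},
                category=category,
                n_loci_used=n_used,
            )
        )
    return results


def remove_migrants(
    dataset: GenotypeDataset,
    reference_groups: Sequence[str],
    config: AssignmentConfig | None = None,
) -> tuple[GenotypeDataset, list[AssignmentResult]]:
    """Drop flagged migrants from the reference groups; return both pieces."""
    results = self_assign(dataset, reference_groups, config)
    migrant_ids = {r.id for r in results if r.category == "migrant"}
    sub = dataset.select_group(list(reference_groups))
    keep = np.array([i not in migrant_ids for i in sub.ids])
    return sub.subset(keep), results


# --------------------------------------------------------- exclusion test


def simulate_reference_pool(
    table: AlleleFrequencyTable,
    k_per_locus: np.ndarray,
    n_simulated: int,
    method: str,
    floor: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-locus log-likelihoods of genotypes simulated from ``table``.

    Two alleles per locus are drawn iid from the reference frequencies
    (the Paetkau-style parametric simulation); the returned
    ``(n_simulated, L)`` matrix lets callers sum over any subset of loci,
    so unknowns with missing loci are ranked against simulated genotypes
    restricted to the same loci.
    """
    L = len(table.locus_names)
    out = np.zeros((n_simulated, L))
    for l in range(L):
        freqs = table.frequencies(l)
        if freqs.sum() <= 0:
            raise ValueError(
                f"locus {table.locus_names[l]}: empty reference, cannot simulate"
            )
        codes = table.codes[l]
        draws = rng.choice(len(codes), size=(n_simulated, 2), p=freqs)
        sim_alleles = np.sort(codes[draws], axis=1)[:, None, :]  # (n, 1, 2)
        sub_table = AlleleFrequencyTable(
            group=table.group,
            locus_names=[table.locus_names[l]],
            codes=[table.codes[l]],
            counts=[table.counts[l]],
        )
        out[:, l] = locus_log_likelihoods(
            sim_alleles, sub_table, k_per_locus[l : l + 1], method, floor
        )[:, 0]
    return out


def exclusion_pvalues(
    alleles: np.ndarray,
    table: AlleleFrequencyTable,
    k_per_locus: np.ndarray,
    config: AssignmentConfig,
    rng: np.random.Generator,
    pool: np.ndarray | None = None,
) -> np.ndarray:
    """Monte Carlo exclusion p-value of each row of ``alleles``.

    p = (1 + #{simulated genotypes with likelihood <= observed}) /
    (n_simulated + 1), with simulated likelihoods summed over exactly the
    loci the focal individual was typed at.
    """
    method, floor = config.exclusion_method, config.rare_allele_floor
    if pool is None:
        pool = simulate_reference_pool(
            table, k_per_locus, config.n_simulated, method, floor, rng
        )
    per_locus = locus_log_likelihoods(alleles, table, k_per_locus, method, floor)
    n_sim = pool.shape[0]
    p = np.empty(len(alleles))
    missing_patterns: dict[tuple[int, ...], np.ndarray] = {}
    for i in range(len(alleles)):
        used = tuple(np.flatnonzero(~np.isnan(per_locus[i])))
        if not used:
            raise ValueError("individual with zero usable loci")
        if used not in missing_patterns:
            missing_patterns[used] = pool[:, list(used)].sum(axis=1)
        sim_totals = missing_patterns[used]
        obs = float(np.nansum(per_locus[i]))
        p[i] = (1 + int((sim_totals <= obs + _EPS).sum())) / (n_sim + 1)
    return p


def exclusion_test(
    alleles_row: np.ndarray,
    table: AlleleFrequencyTable,
    k_per_locus: np.ndarray,
    config: AssignmentConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Exclusion p-value for a single ``(L, 2)`` genotype."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    return float(
        exclusion_pvalues(alleles_row[None, :, :], table, k_per_locus, config, rng)[0]
    )


# --------------------------------------------------- two-step assignment


@dataclass
class JuvenileAssignment:
    results: list[AssignmentResult]
    counts: pd.DataFrame  # per juvenile group: per-category counts
    reference_groups: tuple[str, str]

    # cached intermediates so threshold sweeps need not recompute the
    # 10k-genotype exclusion simulations
    _probabilities: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    _exclusion_p: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def _categorize(
    probs: np.ndarray,
    excl_p: np.ndarray,
    usable: np.ndarray,
    groups: tuple[str, str],
    assign_threshold: float,
    exclusion_alpha: float,
) -> list[str]:
    cats = []
    for i in range(len(probs)):
        if not usable[i]:
            cats.append("failed")
            continue
        if exclusion_alpha > 0 and bool(np.all(excl_p[i] < exclusion_alpha)):
            cats.append("excluded")
            continue
        j = int(np.argmax(probs[i]))
        if probs[i, j] >= assign_threshold - _EPS:
            cats.append(f"assigned-{groups[j]}")
        else:
            cats.append("failed")
    return cats


def _count_table(
    categories: Sequence[str], juv_groups: Sequence[str], groups: tuple[str, str]
) -> pd.DataFrame:
    df = pd.DataFrame({"group": list(juv_groups), "category": list(categories)})
    order = [f"assigned-{groups[0]}", f"assigned-{groups[1]}", "failed", "excluded"]
    table = (
        df.groupby(["group", "category"]).size().unstack(fill_value=0).reindex(
            columns=order, fill_value=0
        )
    )
    table["total"] = table.sum(axis=1)
    return table


def assign_juveniles(
    juveniles: GenotypeDataset,
    references: GenotypeDataset,
    config: AssignmentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> JuvenileAssignment:
    """Two-step assignment of unknowns to exactly two candidate sources.

    Step 1: exclusion test against each source; individuals with p below
    ``exclusion_alpha`` for *both* are ``excluded`` (putatively from an
    unsampled source).  Step 2: normalized rank-based probability between
    the two sources; >= ``assign_threshold`` to one side assigns it there,
    otherwise the assignment ``failed``.  References are expected to be
    migrant-screened already.
    """
    config = config or AssignmentConfig()
    groups = references.group_names
    if len(groups) != 2:
        raise ValueError(
            f"two-step assignment needs exactly 2 reference groups, got {len(groups)}"
        )
    if juveniles.n_individuals == 0:
        raise ValueError("no juveniles to assign")
    if juveniles.locus_names != references.locus_names:
        raise ValueError("juvenile and reference locus lists differ")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    g1, g2 = groups

    # shared code space covering reference AND juvenile alleles so lookups
    # are well-defined (unseen-in-reference codes simply count 0)
    combined_codes = []
    for l in range(references.n_loci):
        pooled = np.concatenate(
            [references.alleles[:, l, :].ravel(), juveniles.alleles[:, l, :].ravel()]
        )
        pooled = np.unique(pooled[pooled != MISSING])
        combined_codes.append(pooled.astype(np.int64))
    tables = {
        g: AlleleFrequencyTable.from_dataset(references, g, codes=combined_codes)
        for g in groups
    }
    k = reference_k(references, groups)

    used = (~juveniles.missing_mask()).sum(axis=1)
    usable = used >= config.min_loci
    if not usable.any():
        raise ValueError("no juvenile has enough typed loci to assign")

    excl_p = np.ones((juveniles.n_individuals, 2))
    if config.exclusion_alpha > 0:
        for j, g in enumerate(groups):
            excl_p[usable, j] = exclusion_pvalues(
                juveniles.alleles[usable], tables[g], k, config, rng
            )

    ll = np.full((juveniles.n_individuals, 2), -np.inf)
    for j, g in enumerate(groups):
        per_locus = locus_log_likelihoods(
            juveniles.alleles[usable],
            tables[g],
            k,
            config.assign_method,
            config.rare_allele_floor,
        )
        ll[usable, j] = np.nansum(per_locus, axis=1)
    probs = np.full_like(ll, np.nan)
    probs[usable] = _normalized_probabilities(ll[usable])

    cats = _categorize(
        probs, excl_p, usable, (g1, g2), config.assign_threshold, config.exclusion_alpha
    )
    results = [
        AssignmentResult(
            id=juveniles.ids[i],
            group=str(juveniles.groups[i]),
            log_likelihoods={g1: float(ll[i, 0]), g2: float(ll[i, 1])},
            probabilities={g1: float(probs[i, 0]), g2: float(probs[i, 1])},
            exclusion_p={g1: float(excl_p[i, 0]), g2: float(excl_p[i, 1])},
            category=cats[i],
            n_loci_used=int(used[i]),
        )
        for i in range(juveniles.n_individuals)
    ]
    counts = _count_table(cats, juveniles.groups, (g1, g2))
    return JuvenileAssignment(
        results=results,
        counts=counts,
        reference_groups=(g1, g2),
        _probabilities=probs,
        _exclusion_p=excl_p,
    )


def sensitivity_sweep(
    juveniles: GenotypeDataset,
    references: GenotypeDataset,
    thresholds: Sequence[float],
    config: AssignmentConfig | None = None,
    rng: np.random.Generator | None = None,
    base: JuvenileAssignment | None = None,
) -> pd.DataFrame:
    """Re-categorize at each assignment threshold; report ratio and theta.

    The exclusion simulations and likelihoods are computed once and reused
    across thresholds.  For each threshold the table reports the assigned
    counts, their first:second ratio (NaN when a side is empty), and the
    Weir–Cockerham theta between the two assigned juvenile sets.
    """
    config = config or AssignmentConfig()
    for t in thresholds:
        if not (0.5 < t < 1.0):
            raise ValueError(f"threshold {t} outside (0.5, 1)")
    if base is None:
        base = assign_juveniles(juveniles, references, config, rng)
    g1, g2 = base.reference_groups
    probs, excl_p = base._probabilities, base._exclusion_p
    used = (~juveniles.missing_mask()).sum(axis=1)
    usable = used >= config.min_loci

    rows = []
    for t in thresholds:
        cats = np.array(
            _categorize(probs, excl_p, usable, (g1, g2), t, config.exclusion_alpha)
        )
        n1 = int((cats == f"assigned-{g1}").sum())
        n2 = int((cats == f"assigned-{g2}").sum())
        ratio = n1 / n2 if (n1 > 0 and n2 > 0) else np.nan
        theta = np.nan
        if n1 >= 2 and n2 >= 2:
            mask = np.isin(cats, [f"assigned-{g1}", f"assigned-{g2}"])
            assigned = juveniles.subset(mask).relabel(
                [c.removeprefix("assigned-") for c in cats[mask]]
            )
            try:
                theta = weir_cockerham_fst(assigned, g1, g2, n_perm=0).theta
            except ValueError:
                pass
        rows.append(
            {
                "threshold": t,
                f"n_{g1}": n1,
                f"n_{g2}": n2,
                "n_assigned": n1 + n2,
                "n_failed": int((cats == "failed").sum()),
                "n_excluded": int((cats == "excluded").sum()),
                "ratio": ratio,
                "theta_assigned": theta,
            }
        )
    return pd.DataFrame(rows)
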