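"""Within-population diversity statistics for haploid sequence data.

Implements the classical summaries used to describe paternal lineage
variation within populations: Nei's unbiased haplotype (gene) diversity,
haplogroup diversity, the mean number of pairwise differences (MPD),
the number of segregating sites, and Tajima's D with a simulation-based
significance test conditioned on the observed number of segregating sites.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .io import (
    DegenerateInputError,
    HaplotypeAlignment,
    PopulationMetadata,
    collapse_haplotypes,
    complete_deletion,
    pairwise_difference_matrix,
)


@dataclass
class TajimaConstants:
    """The Tajima (1989) normalizing constants for sample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


@dataclass
class DiversitySummary:
    """Per-population diversity record.

    ``tajimas_d`` and ``p_tajima`` are NaN when undefined (S == 0 or n < 4);
    ``hg_div`` is NaN when no haplogroup labels were supplied.
    """

    population: str
    n: int
    n_haplotypes: int
    h: float
    hg_div: float
    mpd: float
    S: int
    tajimas_d: float
    p_tajima: float


def haplotype_diversity(counts, n: int | None = None) -> float:
    """Nei's unbiased haplotype diversity h = n(1 - sum p_i^2)/(n - 1).

    ``counts`` are the per-haplotype sample counts; ``n`` defaults to their
    sum.  The n/(n-1) correction makes the estimator unbiased under
    multinomial sampling.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if n is None:
        n = int(total)
    if n < 2:
        raise DegenerateInputError("haplotype diversity needs n >= 2")
    if not math.isclose(total, n):
        raise ValueError(f"counts sum to {total}, expected n={n}")
    p = counts / n
    return float(n * (1.0 - np.sum(p**2)) / (n - 1))


def haplogroup_diversity(haplogroup_counts, n: int | None = None) -> float:
    """Nei's unbiased diversity applied to haplogroup frequencies."""
    return haplotype_diversity(haplogroup_counts, n)


def mpd(
    alignment: HaplotypeAlignment, missing_policy: str = "complete_deletion"
) -> float:
    """Mean number of pairwise differences over all C(n,2) sample pairs."""
    if alignment.n_samples < 2:
        raise DegenerateInputError("MPD needs n >= 2")
    d = pairwise_difference_matrix(alignment, missing_policy).values
    n = alignment.n_samples
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean())


def segregating_sites(
    alignment: HaplotypeAlignment, missing_policy: str = "complete_deletion"
) -> int:
    """Number of polymorphic columns (after missing-data handling)."""
    aln = (
        complete_deletion(alignment)
        if missing_policy == "complete_deletion"
        else alignment
    )
    sites = aln.sites
    if sites.shape[1] == 0:
        return 0
    S = 0
    for j in range(sites.shape[1]):
        col = sites[:, j]
        col = col[col != "N"]
        if len(np.unique(col)) > 1:
            S += 1
    return S


def tajima_constants(n: int) -> TajimaConstants:
    """Normalizing constants a1, a2, b1, b2, c1, c2, e1, e2 for sample size n."""
    if n < 2:
        raise DegenerateInputError("Tajima constants need n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d(S: int, pi: float, n: int) -> tuple[float, TajimaConstants]:
    """Tajima's D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)).

    ``pi`` is the mean pairwise difference (MPD) and ``S`` the number of
    segregating sites counted on the same site set, so the two theta
    estimators being contrasted are internally consistent.  Returns NaN
    (flagged, not raised) when S == 0.
    """
    if n < 4:
        raise DegenerateInputError("Tajima's D needs n >= 4")
    if S < 0:
        raise ValueError("S must be >= 0")
    const = tajima_constants(n)
    if S == 0:
        return float("nan"), const
    var = const.e1 * S + const.e2 * S * (S - 1)
    return float((pi - S / const.a1) / math.sqrt(var)), const


def _coalescent_tree_branch_stats(n: int, rng: np.random.Generator):
    """Simulate a neutral constant-size coalescent tree topology.

    Returns (branch_lengths, n_descendants) per branch, lengths in units of
    2N generations (the scale cancels in fixed-S resampling).
    """
    # active lineages carry their number of descendant tips
    desc = [1] * n
    t = 0.0
    lengths: list[float] = []
    ndesc: list[int] = []
    birth = [0.0] * n  # time each active lineage started
    k = n
    while k > 1:
        rate = k * (k - 1) / 2.0
        t += rng.exponential(1.0 / rate)
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        for idx in (i, j):
            lengths.append(t - birth[idx])
            ndesc.append(desc[idx])
        merged = desc[i] + desc[j]
        # remove j first (j > i)
        del desc[j], birth[j]
        del desc[i], birth[i]
        desc.append(merged)
        birth.append(t)
        k -= 1
    return np.asarray(lengths), np.asarray(ndesc)


def tajima_significance(
    D_obs: float,
    n: int,
    S: int,
    n_sims: int = 10_000,
    seed: int | None = None,
) -> float:
    """Two-sided p-value for Tajima's D under the fixed-S coalescent null.

    Neutral constant-size coalescent genealogies are simulated; exactly S
    mutations are placed on branches with probability proportional to branch
    length (infinite sites), and D is recomputed for each replicate.  p is
    the add-one-corrected fraction of replicates with \\|D\\| >= \\|D_obs\\|.
    """
    if S <= 0:
        raise DegenerateInputError("fixed-S null needs S > 0")
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    rng = np.random.default_rng(seed)
    null = simulate_tajima_null(n, S, n_sims, rng)
    b = int(np.sum(np.abs(null) >= abs(D_obs)))
    return (b + 1) / (n_sims + 1)


def simulate_tajima_null(
    n: int, S: int, n_sims: int, rng: np.random.Generator
) -> np.ndarray:
    """Null distribution of D for (n, S) under fixed-S coalescent resampling."""
    out = np.empty(n_sims)
    for r in range(n_sims):
        lengths, ndesc = _coalescent_tree_branch_stats(n, rng)
        probs = lengths / lengths.sum()
        muts = rng.multinomial(S, probs)
        # pi = sum over sites of 2*i*(n-i)/(n*(n-1)) with i = derived count
        i_counts = ndesc
        pi = float(
            np.sum(muts * 2.0 * i_counts * (n - i_counts)) / (n * (n - 1))
        )
        out[r], _ = tajimas_d(S, pi, n)
    return out


def population_summaries(
    alignment: HaplotypeAlignment,
    metadata: list[PopulationMetadata] | None = None,
    haplogroups: dict[str, str] | None = None,
    missing_policy: str = "complete_deletion",
    n_sims: int = 10_000,
    seed: int | None = None,
) -> list[DiversitySummary]:
    """One DiversitySummary per population.

    Populations with n < 2 are reported with NaN statistics rather than
    skipped.  ``haplogroups`` maps sample id -> haplogroup label; haplogroup
    diversity is NaN when absent.  Tajima p-values use a fixed-S coalescent
    null with ``n_sims`` replicates, seeded for reproducibility.
    """
    rng = np.random.default_rng(seed)
    known = {m.code for m in metadata} if metadata else None
    results = []
    for pop in alignment.population_codes():
        if known is not None and pop not in known:
            warnings.warn(f"population {pop} absent from metadata", stacklevel=2)
        sub = alignment.restrict_to_population(pop)
        n = sub.n_samples
        hg = float("nan")
        if haplogroups is not None and n >= 2:
            labels = [haplogroups[s] for s in sub.sample_ids]
            _, counts = np.unique(labels, return_counts=True)
            hg = haplogroup_diversity(counts, n)
        if n < 2:
            results.append(
                DiversitySummary(pop, n, 1 if n else 0, float("nan"), hg,
                                 float("nan"), 0, float("nan"), float("nan"))
            )
            continue
        table = collapse_haplotypes(sub, missing_policy="complete_deletion")
        counts = table.population_counts(pop)
        h = haplotype_diversity(counts, n)
        pi = mpd(sub, missing_policy)
        S = segregating_sites(sub, "complete_deletion")
        if n >= 4 and S > 0:
            D, _ = tajimas_d(S, mpd(sub, "complete_deletion"), n)
            p = tajima_significance(
                D, n, S, n_sims=n_sims, seed=int(rng.integers(2**31 - 1))
            )
        else:
            D, p = float("nan"), float("nan")
        results.append(
            DiversitySummary(pop, n, table.n_haplotypes, h, hg, pi, S, D, p)
        )
    return results


def summaries_to_rows(summaries: list[DiversitySummary]) -> list[dict]:
    return [vars(s).copy() for s in summaries]
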