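"""Between-population structure: AMOVA, Phi-st, Mantel, NMDS, rank contrasts.

AMOVA decomposes the sum of squared molecular distances between haplotypes
into hierarchical variance components (among groups, among populations within
groups, within populations) by the nested moment estimators of Excoffier,
Smouse & Quattro (1992).  Phi-statistics are ratios of those components and
are tested by the permutation schemes appropriate to each level.  Negative
variance components are reported as-is, and percentages are computed on the
signed sum, so the decomposition always totals 100%.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.isotonic import IsotonicRegression

from .io import (
    DegenerateInputError,
    DistanceMatrix,
    HaplotypeAlignment,
    HaplotypeTable,
    PopulationMetadata,
    ValidationError,
    pairwise_difference_matrix,
)

EARTH_RADIUS_KM = 6371.0088

MODEL_ORDER = ("demic", "cultural", "continuous_migration")


# ---------------------------------------------------------------------------
# Result containers


@dataclass
class AmovaResult:
    """Nested AMOVA variance components, Phi-statistics and permutation p's.

    For a 2-level design (populations only) the components are
    ``among_populations`` / ``within_populations`` and the only Phi statistic
    is Phi_st.  For 3-level designs Phi_ct, Phi_sc and Phi_st are reported.
    """

    levels: int
    variance_components: dict[str, float]
    percentages: dict[str, float]
    phi_stats: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int


@dataclass
class RankTestResult:
    U: float
    Z: float
    p: float
    n1: int
    n2: int
    exact: bool = False


@dataclass
class OrdinationResult:
    coordinates: np.ndarray
    stress: float
    converged: bool
    seed: int | None
    labels: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# AMOVA machinery


def _delta_sq(alignment: HaplotypeAlignment, distance: str) -> np.ndarray:
    """Squared molecular distance matrix used in AMOVA sums of squares.

    ``distance="squared"`` squares the pairwise difference count;
    ``distance="plain"`` uses the count itself as the squared distance.
    """
    d = pairwise_difference_matrix(alignment, "complete_deletion").values
    if distance == "squared":
        return d**2
    if distance == "plain":
        return d
    raise ValueError(f"unknown distance convention {distance!r}")


def _ssd(M: np.ndarray, idx: np.ndarray) -> float:
    """Sum over unordered pairs within idx of squared distances."""
    sub = M[np.ix_(idx, idx)]
    return float(sub.sum()) / 2.0


class _AmovaEngine:
    """Variance-component computation over a fixed squared-distance matrix.

    Populations are index arrays into the matrix; the engine recomputes
    components for arbitrary (permuted) assignments, which is what the
    permutation tests need.
    """

    def __init__(self, M: np.ndarray, pop_sizes: list[int]):
        self.M = M
        self.N = M.shape[0]
        self.pop_sizes = list(pop_sizes)
        self.P = len(pop_sizes)

    def _split(self, order: np.ndarray) -> list[np.ndarray]:
        out, start = [], 0
        for n in self.pop_sizes:
            out.append(order[start : start + n])
            start += n
        return out

    def two_level(self, pops: list[np.ndarray]) -> dict[str, float]:
        M, P = self.M, len(pops)
        sizes = np.array([len(p) for p in pops], dtype=float)
        N = int(sizes.sum())
        ssd_wp = sum(_ssd(M, p) / len(p) for p in pops)
        all_idx = np.concatenate(pops)
        ssd_t = _ssd(M, all_idx) / N
        ssd_ap = ssd_t - ssd_wp
        df_ap, df_wp = P - 1, N - P
        sigma_c = ssd_wp / df_wp
        n_c = (N - np.sum(sizes**2) / N) / df_ap
        sigma_a = (ssd_ap / df_ap - sigma_c) / n_c
        total = sigma_a + sigma_c
        phi_st = sigma_a / total if total != 0 else float("nan")
        return {
            "sigma_a": sigma_a,
            "sigma_c": sigma_c,
            "phi_st": phi_st,
            "ssd_ap": ssd_ap,
            "ssd_wp": ssd_wp,
        }

    def three_level(
        self, pops: list[np.ndarray], groups: list[list[int]]
    ) -> dict[str, float]:
        """``groups`` lists, per group, the indices of its populations."""
        M = self.M
        P = len(pops)
        G = len(groups)
        sizes = np.array([len(p) for p in pops], dtype=float)
        N = int(sizes.sum())
        ssd_wp = sum(_ssd(M, p) / len(p) for p in pops)
        ssd_t = _ssd(M, np.concatenate(pops)) / N
        # within-group totals
        ssd_wg = 0.0
        group_sizes = []
        sum_nsq_over_Ng = 0.0
        for g in groups:
            gidx = np.concatenate([pops[p] for p in g])
            Ng = len(gidx)
            group_sizes.append(Ng)
            ssd_wg += _ssd(M, gidx) / Ng
            sum_nsq_over_Ng += float(np.sum(sizes[g] ** 2)) / Ng
        ssd_ag = ssd_t - ssd_wg
        ssd_ap_wg = ssd_wg - ssd_wp
        group_sizes = np.asarray(group_sizes, dtype=float)
        df_ag, df_ap, df_wp = G - 1, P - G, N - P
        sigma_c = ssd_wp / df_wp
        n1 = (N - sum_nsq_over_Ng) / df_ap if df_ap > 0 else float("nan")
        n2 = (sum_nsq_over_Ng - float(np.sum(sizes**2)) / N) / df_ag
        n3 = (N - float(np.sum(group_sizes**2)) / N) / df_ag
        ms_ag = ssd_ag / df_ag
        if df_ap == 0:  # every population its own group: empty stratum
            sigma_b = 0.0
        else:
            sigma_b = (ssd_ap_wg / df_ap - sigma_c) / n1
        sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
        total = sigma_a + sigma_b + sigma_c
        phi_st = (sigma_a + sigma_b) / total if total != 0 else float("nan")
        phi_ct = sigma_a / total if total != 0 else float("nan")
        denom_sc = sigma_b + sigma_c
        phi_sc = sigma_b / denom_sc if denom_sc != 0 else float("nan")
        return {
            "sigma_a": sigma_a,
            "sigma_b": sigma_b,
            "sigma_c": sigma_c,
            "phi_st": phi_st,
            "phi_ct": phi_ct,
            "phi_sc": phi_sc,
        }


def _pop_index_arrays(alignment: HaplotypeAlignment) -> tuple[list[str], list[np.ndarray]]:
    pops = alignment.population_codes()
    arr = np.asarray(alignment.populations)
    return pops, [np.flatnonzero(arr == p) for p in pops]


def amova(
    alignment: HaplotypeAlignment,
    grouping: dict[str, str] | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    distance: str = "squared",
) -> AmovaResult:
    """Hierarchical AMOVA on squared pairwise sequence differences.

    ``grouping`` maps population code -> group label for a 3-level design;
    ``None`` runs the 2-level (populations within total) design.  Permutation
    schemes follow the standard hierarchy: within-population component —
    individuals permuted among populations across all groups; among
    populations within groups — individuals permuted among populations within
    their group; among groups — whole populations permuted among groups.
    """
    codes, pops = _pop_index_arrays(alignment)
    if len(pops) < 2:
        raise DegenerateInputError("AMOVA needs >= 2 populations")
    M = _delta_sq(alignment, distance)
    rng = np.random.default_rng(seed)
    engine = _AmovaEngine(M, [len(p) for p in pops])

    if grouping is None:
        obs = engine.two_level(pops)
        sigma = {
            "among_populations": obs["sigma_a"],
            "within_populations": obs["sigma_c"],
        }
        total = sum(sigma.values())
        perc = {k: 100.0 * v / total for k, v in sigma.items()}
        # permute individuals among populations
        all_idx = np.concatenate(pops)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(all_idx)
            if engine.two_level(engine._split(perm))["phi_st"] >= obs["phi_st"]:
                count += 1
        p = (count + 1) / (n_perm + 1)
        return AmovaResult(
            levels=2,
            variance_components=sigma,
            percentages=perc,
            phi_stats={"phi_st": obs["phi_st"]},
            p_values={"phi_st": p},
            n_permutations=n_perm,
        )

    unknown = [c for c in codes if c not in grouping]
    if unknown:
        raise ValidationError(f"populations missing from grouping: {unknown}")
    group_labels: dict[str, list[int]] = {}
    for i, c in enumerate(codes):
        group_labels.setdefault(grouping[c], []).append(i)
    groups = list(group_labels.values())
    if len(groups) < 2:
        raise DegenerateInputError("3-level AMOVA needs >= 2 groups")
    for glab, members in group_labels.items():
        if len(members) == 1:
            warnings.warn(
                f"group {glab!r} contains a single population", stacklevel=2
            )

    obs = engine.three_level(pops, groups)
    sigma = {
        "among_groups": obs["sigma_a"],
        "among_populations_within_groups": obs["sigma_b"],
        "within_populations": obs["sigma_c"],
    }
    total = sum(sigma.values())
    perc = {k: 100.0 * v / total for k, v in sigma.items()}

    group_sizes = [len(g) for g in groups]
    counts = {"phi_st": 0, "phi_sc": 0, "phi_ct": 0}
    all_idx = np.concatenate(pops)
    pop_of = np.empty(len(pops), dtype=int)  # population -> group id
    for gi, g in enumerate(groups):
        for p in g:
            pop_of[p] = gi
    for _ in range(n_perm):
        # phi_st: individuals among populations across all groups
        perm = rng.permutation(all_idx)
        st = engine.three_level(engine._split(perm), groups)
        if st["phi_st"] >= obs["phi_st"]:
            counts["phi_st"] += 1
        # phi_sc: individuals among populations within groups
        permuted_pops: list[np.ndarray | None] = [None] * len(pops)
        for g in groups:
            gidx = np.concatenate([pops[p] for p in g])
            gperm = rng.permutation(gidx)
            start = 0
            for p in g:
                n_p = len(pops[p])
                permuted_pops[p] = gperm[start : start + n_p]
                start += n_p
        sc = engine.three_level(permuted_pops, groups)  # type: ignore[arg-type]
        if sc["phi_sc"] >= obs["phi_sc"]:
            counts["phi_sc"] += 1
        # phi_ct: whole populations among groups
        pop_perm = rng.permutation(len(pops))
        shuffled_groups, start = [], 0
        for gs in group_sizes:
            shuffled_groups.append(list(pop_perm[start : start + gs]))
            start += gs
        ct = engine.three_level(pops, shuffled_groups)
        if ct["phi_ct"] >= obs["phi_ct"]:
            counts["phi_ct"] += 1

    p_values = {k: (v + 1) / (n_perm + 1) for k, v in counts.items()}
    return AmovaResult(
        levels=3,
        variance_components=sigma,
        percentages=perc,
        phi_stats={k: obs[k] for k in ("phi_ct", "phi_sc", "phi_st")},
        p_values=p_values,
        n_permutations=n_perm,
    )


def phist_pairwise(
    alignment: HaplotypeAlignment,
    populations: list[str] | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    distance: str = "squared",
) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Pairwise Phi-st matrix with permutation p-values.

    Each entry is the among-population variance fraction from the
    two-population AMOVA; its p-value permutes individuals between the two
    populations.  Populations with n < 2 are skipped with a warning and
    their rows left NaN.
    """
    codes, pops = _pop_index_arrays(alignment)
    if populations is not None:
        keep = [i for i, c in enumerate(codes) if c in set(populations)]
        codes = [codes[i] for i in keep]
        pops = [pops[i] for i in keep]
    M = _delta_sq(alignment, distance)
    rng = np.random.default_rng(seed)
    k = len(codes)
    phi = np.full((k, k), np.nan)
    pvals = np.full((k, k), np.nan)
    np.fill_diagonal(phi, 0.0)
    np.fill_diagonal(pvals, 0.0)
    usable = [len(p) >= 2 for p in pops]
    for i, ok in enumerate(usable):
        if not ok:
            warnings.warn(
                f"population {codes[i]} has n < 2; Phi-st undefined", stacklevel=2
            )
    for i in range(k):
        for j in range(i + 1, k):
            if not (usable[i] and usable[j]):
                continue
            engine = _AmovaEngine(M, [len(pops[i]), len(pops[j])])
            obs = engine.two_level([pops[i], pops[j]])
            phi[i, j] = phi[j, i] = obs["phi_st"]
            both = np.concatenate([pops[i], pops[j]])
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(both)
                if (
                    engine.two_level(engine._split(perm))["phi_st"]
                    >= obs["phi_st"]
                ):
                    count += 1
            pvals[i, j] = pvals[j, i] = (count + 1) / (n_perm + 1)
    return (
        DistanceMatrix(codes, phi, kind="phist"),
        DistanceMatrix(codes, pvals, kind="similarity"),
    )


def corrected_pairwise_difference(
    alignment: HaplotypeAlignment, pop_i: str, pop_j: str
) -> float:
    """Nei's net divergence dA = pi_XY - (pi_X + pi_Y)/2.

    pi_XY is the mean difference over between-population pairs and pi_X,
    pi_Y the within-population means; dA can be slightly negative for very
    similar populations.
    """
    codes, pops = _pop_index_arrays(alignment)
    lookup = dict(zip(codes, pops))
    for p in (pop_i, pop_j):
        if p not in lookup or len(lookup[p]) < 2:
            raise DegenerateInputError(f"population {p} missing or n < 2")
    d = pairwise_difference_matrix(alignment, "complete_deletion").values
    ix, jx = lookup[pop_i], lookup[pop_j]
    pi_between = float(d[np.ix_(ix, jx)].mean())
    pi_x = float(d[np.ix_(ix, ix)].sum() / (len(ix) * (len(ix) - 1)))
    pi_y = float(d[np.ix_(jx, jx)].sum() / (len(jx) * (len(jx) - 1)))
    return pi_between - (pi_x + pi_y) / 2.0


def corrected_pairwise_matrix(alignment: HaplotypeAlignment) -> DistanceMatrix:
    codes = [
        c
        for c in alignment.population_codes()
        if alignment.populations.count(c) >= 2
    ]
    k = len(codes)
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            m[i, j] = m[j, i] = corrected_pairwise_difference(
                alignment, codes[i], codes[j]
            )
    return DistanceMatrix(codes, m, kind="dA")


# ---------------------------------------------------------------------------
# Shared haplotypes, geography, Mantel


def shared_haplotype_matrix(
    table: HaplotypeTable, normalize: str = "none"
) -> DistanceMatrix:
    """Counts of distinct haplotypes shared between population pairs.

    ``per_pair`` normalization divides by the number of distinct haplotypes
    present in either population of the pair (Jaccard-style), since the
    relative sharing of common paternal lineages is what heat maps of shared
    haplotypes display.
    """
    present = table.counts.to_numpy() > 0
    inter = (present[:, None, :] & present[None, :, :]).sum(axis=2).astype(float)
    if normalize == "per_pair":
        union = (present[:, None, :] | present[None, :, :]).sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            inter = np.where(union > 0, inter / union, 0.0)
    elif normalize != "none":
        raise ValueError(f"unknown normalize {normalize!r}")
    np.fill_diagonal(inter, 0.0)
    return DistanceMatrix(
        list(table.counts.index), inter, kind="similarity"
    )


def great_circle_distance(
    lat1: float, lon1: float, lat2: float, lon2: float
) -> float:
    """Haversine great-circle distance in km on a sphere of R = 6371.0088 km."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(
        dlam / 2
    ) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def geographic_distance_matrix(
    metadata: list[PopulationMetadata],
) -> DistanceMatrix:
    codes = [m.code for m in metadata]
    k = len(codes)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = great_circle_distance(
                metadata[i].latitude,
                metadata[i].longitude,
                metadata[j].latitude,
                metadata[j].longitude,
            )
    return DistanceMatrix(codes, d, kind="geographic")


def mantel(
    matrix_a: DistanceMatrix,
    matrix_b: DistanceMatrix,
    n_perm: int = 9_999,
    seed: int | None = None,
    tail: str = "one_sided_positive",
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation over the off-diagonal upper triangles; the
    p-value jointly permutes rows and columns of the second matrix, with
    add-one correction.
    """
    if matrix_a.labels != matrix_b.labels:
        raise ValidationError("Mantel matrices must share labels and order")
    n = len(matrix_a.labels)
    if n < 4:
        raise DegenerateInputError("Mantel needs >= 4 labels")
    iu = np.triu_indices(n, k=1)
    va = matrix_a.values[iu]
    B = matrix_b.values
    vb = B[iu]
    if np.std(va) == 0 or np.std(vb) == 0:
        raise DegenerateInputError("constant matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = B[np.ix_(perm, perm)][iu]
        r_p = float(np.corrcoef(va, vp)[0, 1])
        if tail == "one_sided_positive":
            extreme = r_p >= r_obs
        elif tail == "two_sided":
            extreme = abs(r_p) >= abs(r_obs)
        else:
            raise ValueError(f"unknown tail {tail!r}")
        if extreme:
            count += 1
    return MantelResult(r=r_obs, p=(count + 1) / (n_perm + 1), n_permutations=n_perm)


# ---------------------------------------------------------------------------
# Nonmetric MDS (Kruskal stress-1, SMACOF with monotone regression)


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(d**2))
    if denom == 0:
        return 0.0
    return math.sqrt(float(np.sum((d - dhat) ** 2)) / denom)


def nmds(
    distance_matrix: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-9,
    seed: int | None = None,
) -> OrdinationResult:
    """Nonmetric MDS minimizing Kruskal stress-1.

    Uses iterative majorization (Guttman transform) alternated with isotonic
    regression of configuration distances on the input dissimilarities.
    Negative input values (possible for Phi-st) are clamped to zero with a
    warning.  Returns the best of ``n_restarts`` random initializations;
    deterministic given ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = distance_matrix.values.copy()
    if (D < 0).any():
        warnings.warn("negative dissimilarities clamped to 0", stacklevel=2)
        D = np.clip(D, 0.0, None)
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    dvec = D[iu]
    rng = np.random.default_rng(seed)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")

    best_X, best_stress, best_conv = None, math.inf, False
    for _ in range(max(1, n_restarts)):
        X = rng.normal(size=(n, k))
        X -= X.mean(axis=0)
        prev = math.inf
        converged = False
        stress = math.inf
        for _it in range(max_iter):
            diff = X[:, None, :] - X[None, :, :]
            dconf = np.sqrt((diff**2).sum(axis=2))
            dc = dconf[iu]
            dhat = iso.fit(dvec, dc).predict(dvec)
            stress = _stress1(dc, dhat)
            if abs(prev - stress) < tol:
                converged = True
                break
            prev = stress
            # Guttman transform with disparities dhat
            W = np.zeros((n, n))
            W[iu] = np.where(dc > 0, dhat / dc, 0.0)
            W = W + W.T
            Bm = -W
            np.fill_diagonal(Bm, W.sum(axis=1))
            X = Bm @ X / n
            X -= X.mean(axis=0)
        if stress < best_stress:
            best_X, best_stress, best_conv = X, stress, converged
    best_X -= best_X.mean(axis=0)
    return OrdinationResult(
        coordinates=best_X,
        stress=best_stress,
        converged=best_conv,
        seed=seed,
        labels=list(distance_matrix.labels),
    )


# ---------------------------------------------------------------------------
# Rank contrasts (Mann-Whitney U with tie-corrected Z)


def rank_contrast(values_group1, values_group2) -> RankTestResult:
    """Mann-Whitney U test between two groups of values.

    Reports U for group 1, the tie-corrected normal Z, and a two-sided
    p-value (exact when n1*n2 <= 400 and there are no ties, normal
    approximation otherwise).  All-tied input returns Z = 0, p = 1.
    """
    x = np.asarray(values_group1, dtype=float)
    y = np.asarray(values_group2, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DegenerateInputError("both groups must be nonempty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    R1 = float(ranks[:n1].sum())
    U1 = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return RankTestResult(U=U1, Z=0.0, p=1.0, n1=n1, n2=n2, exact=False)
    Z = (U1 - mu) / math.sqrt(var)
    has_ties = bool((tie_counts > 1).any())
    if n1 * n2 <= 400 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return RankTestResult(
            U=float(res.statistic), Z=Z, p=float(res.pvalue), n1=n1, n2=n2, exact=True
        )
    p = 2.0 * (1.0 - sps.norm.cdf(abs(Z)))
    return RankTestResult(U=U1, Z=Z, p=min(1.0, p), n1=n1, n2=n2, exact=False)


def residence_contrast_report(
    summaries,
    phist: DistanceMatrix,
    metadata: list[PopulationMetadata],
) -> list[dict]:
    """Patrilocal-vs-matrilocal contrasts of diversity and differentiation.

    Applies the rank test to haplotype diversity, MPD and haplogroup
    diversity across residence classes, and to the off-diagonal Phi-st
    entries within each class.  Patrilocality predicts lower within-
    population MSY diversity and higher among-population differentiation.
    """
    residence = {m.code: m.residence for m in metadata}
    classes: dict[str, list] = {"patrilocal": [], "matrilocal": []}
    for s in summaries:
        r = residence.get(s.population)
        if r in classes:
            classes[r].append(s)
        elif r is None:
            warnings.warn(
                f"population {s.population} lacks residence label; excluded",
                stacklevel=2,
            )
    if not classes["patrilocal"] or not classes["matrilocal"]:
        raise DegenerateInputError(
            "need at least one patrilocal and one matrilocal population"
        )
    rows = []
    for metric in ("h", "mpd", "hg_div"):
        g1 = [getattr(s, metric) for s in classes["patrilocal"]]
        g2 = [getattr(s, metric) for s in classes["matrilocal"]]
        g1 = [v for v in g1 if not math.isnan(v)]
        g2 = [v for v in g2 if not math.isnan(v)]
        if not g1 or not g2:
            continue
        res = rank_contrast(g1, g2)
        rows.append(
            {
                "contrast": f"{metric}_patrilocal_vs_matrilocal",
                "n_patrilocal": len(g1),
                "n_matrilocal": len(g2),
                "U": res.U,
                "Z": res.Z,
                "p": res.p,
                "direction": (
                    "matrilocal_higher"
                    if float(np.mean(g2)) > float(np.mean(g1))
                    else "patrilocal_higher"
                ),
            }
        )
    # within-class Phi-st off-diagonal entries
    label_idx = {c: i for i, c in enumerate(phist.labels)}
    phis = {}
    for cls, members in classes.items():
        idx = [label_idx[s.population] for s in members if s.population in label_idx]
        if len(idx) >= 2:
            sub = phist.values[np.ix_(idx, idx)]
            phis[cls] = sub[np.triu_indices(len(idx), k=1)]
    if len(phis) == 2:
        res = rank_contrast(phis["patrilocal"], phis["matrilocal"])
        rows.append(
            {
                "contrast": "phist_patrilocal_vs_matrilocal",
                "n_patrilocal": len(phis["patrilocal"]),
                "n_matrilocal": len(phis["matrilocal"]),
                "U": res.U,
                "Z": res.Z,
                "p": res.p,
                "direction": (
                    "patrilocal_higher"
                    if float(np.mean(phis["patrilocal"]))
                    > float(np.mean(phis["matrilocal"]))
                    else "matrilocal_higher"
                ),
            }
        )
    return rows
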