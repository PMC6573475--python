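"""Structured Hudson coalescent for one non-recombining haploid locus.

Simulates genealogies under three-deme demographic scenarios describing the
origin of a target population from either a migrant (Dai-like, "demic
diffusion") or a resident (Austroasiatic-like, "cultural diffusion") source,
with an optional continuous-migration variant, and drops infinite-sites
mutations to produce polarized alignments and per-deme unfolded site
frequency spectra.

The process runs backward in time in units of generations.  Within deme d
holding k lineages, pairwise coalescence occurs at rate k(k-1)/(2*Ne_d) per
generation (haploid Ne); a lineage in deme d migrates to deme e at rate
m[d,e].  At fixed split times all lineages of the daughter deme relocate to
the parent deme, which keeps its own size.  Because the locus does not
recombine, each simulation produces a single binary genealogy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import HaplotypeAlignment

SCENARIOS = ("demic", "cultural", "continuous_migration")

#: fixed mutation rate for the male-specific Y region, substitutions/bp/year
DEFAULT_MU = 8.71e-10
#: total surveyed locus length in bp
DEFAULT_LOCUS_LENGTH = 2_364_048
DEFAULT_GENERATION_TIME = 30.0


@dataclass
class DemographicModel:
    """A three-deme scenario with fixed split times and uniform priors.

    Demes are AA (resident source), DAI (migrant source) and TARGET (the
    population whose origin is questioned).  Under ``demic`` and
    ``continuous_migration`` the TARGET splits from DAI at ``t_target_years``
    ago; under ``cultural`` it splits from AA.  AA and DAI split at
    ``t_root_years``.  ``continuous_migration`` additionally allows symmetric
    TARGET<->AA migration at per-generation rate m, active only more recently
    than the target split.
    """

    scenario: str
    t_target_years: float = 2000.0
    t_root_years: float = 4500.0
    generation_time_years: float = DEFAULT_GENERATION_TIME
    size_priors: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "AA": (1e3, 1e5),
            "DAI": (1e3, 1e5),
            "TARGET": (1e3, 1e5),
        }
    )
    migration_prior: tuple[float, float] | None = None
    mutation_rate_per_bp_year: float = DEFAULT_MU
    locus_length_bp: int = DEFAULT_LOCUS_LENGTH
    sample_sizes: dict[str, int] = field(
        default_factory=lambda: {"AA": 10, "DAI": 10, "TARGET": 10}
    )

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0 < self.t_target_years < self.t_root_years:
            raise ValueError("need 0 < t_target_years < t_root_years")
        for deme, (lo, hi) in self.size_priors.items():
            if not 0 < lo <= hi:
                raise ValueError(f"bad size prior for {deme}: ({lo}, {hi})")
        if self.scenario == "continuous_migration":
            if self.migration_prior is None:
                self.migration_prior = (1e-5, 1e-2)
            lo, hi = self.migration_prior
            if not 0 <= lo <= hi < 1:
                raise ValueError("migration prior must satisfy 0 <= lo <= hi < 1")
        if self.generation_time_years <= 0:
            raise ValueError("generation_time_years must be > 0")
        if sum(self.sample_sizes.values()) < 2:
            raise ValueError("need at least 2 sampled lineages in total")

    @property
    def t_target_gen(self) -> float:
        return self.t_target_years / self.generation_time_years

    @property
    def t_root_gen(self) -> float:
        return self.t_root_years / self.generation_time_years

    @property
    def demes(self) -> tuple[str, ...]:
        return ("AA", "DAI", "TARGET")


@dataclass
class ParameterDraw:
    """One draw from the model priors."""

    ne: dict[str, float]
    m: float | None = None
    seed: int | None = None

    def as_row(self) -> dict[str, float]:
        row = {f"ne_{k}": v for k, v in self.ne.items()}
        if self.m is not None:
            row["m"] = self.m
        return row


@dataclass
class Genealogy:
    """Binary coalescent tree with deme-labelled leaves.

    Nodes 0..n-1 are leaves; internal nodes follow in coalescence order; the
    last node is the root.  Times are in generations before present.
    """

    times: np.ndarray
    children: list[tuple[int, int] | None]
    leaf_demes: list[str]
    n_migrations: int = 0

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_demes)

    @property
    def n_nodes(self) -> int:
        return len(self.times)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tmrca(self) -> float:
        return float(self.times[self.root])

    def parent_array(self) -> np.ndarray:
        parent = np.full(self.n_nodes, -1, dtype=int)
        for node, ch in enumerate(self.children):
            if ch is not None:
                parent[ch[0]] = node
                parent[ch[1]] = node
        return parent

    def branch_lengths(self) -> np.ndarray:
        """Length in generations of the branch above each non-root node."""
        parent = self.parent_array()
        lengths = np.zeros(self.n_nodes)
        nonroot = parent >= 0
        lengths[nonroot] = self.times[parent[nonroot]] - self.times[nonroot]
        return lengths

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaf_counts_by_deme(self, demes: list[str]) -> np.ndarray:
        """(n_nodes, n_demes) matrix of descendant-leaf counts per deme."""
        idx = {d: i for i, d in enumerate(demes)}
        counts = np.zeros((self.n_nodes, len(demes)), dtype=int)
        for leaf, d in enumerate(self.leaf_demes):
            counts[leaf, idx[d]] = 1
        for node in range(self.n_leaves, self.n_nodes):
            c1, c2 = self.children[node]
            counts[node] = counts[c1] + counts[c2]
        return counts

    def clade_leaves(self, node: int) -> list[int]:
        stack, out = [node], []
        while stack:
            v = stack.pop()
            ch = self.children[v]
            if ch is None:
                out.append(v)
            else:
                stack.extend(ch)
        return sorted(out)


@dataclass
class SFSVector:
    """Per-deme unfolded site frequency spectra plus the total S.

    ``deme_sfs[d][i-1]`` counts sites whose derived allele occurs in exactly
    i of deme d's n_d sampled chromosomes, for i = 1..n_d-1; sites fixed
    ancestral or fixed derived within a deme contribute nothing to that
    deme's vector.  ``total_S`` is the number of sites segregating in the
    total sample.
    """

    deme_sfs: dict[str, np.ndarray]
    total_S: int

    def flatten(self) -> np.ndarray:
        parts = [np.asarray(self.deme_sfs[d], dtype=float) for d in sorted(self.deme_sfs)]
        return np.concatenate(parts + [np.array([float(self.total_S)])])

    def column_names(self) -> list[str]:
        names = []
        for d in sorted(self.deme_sfs):
            names.extend(
                f"sfs_{d}_{i + 1}" for i in range(len(self.deme_sfs[d]))
            )
        names.append("total_S")
        return names


# ---------------------------------------------------------------------------
# Prior sampling


def sample_prior(model: DemographicModel, rng: np.random.Generator) -> ParameterDraw:
    """Independent uniform draws of per-deme Ne (and m when applicable)."""
    ne = {
        d: float(rng.uniform(lo, hi)) for d, (lo, hi) in model.size_priors.items()
    }
    m = None
    if model.scenario == "continuous_migration":
        lo, hi = model.migration_prior
        m = float(rng.uniform(lo, hi))
    return ParameterDraw(ne=ne, m=m)


# ---------------------------------------------------------------------------
# Core structured-coalescent engine


def simulate_structured_genealogy(
    sample_sizes: dict[str, int],
    deme_ne: dict[str, float],
    migration: dict[tuple[str, str], float],
    merge_events: list[tuple[float, str, str]],
    rng: np.random.Generator,
    migration_end: float | None = None,
) -> Genealogy:
    """Run the structured coalescent backward in time until one lineage.

    ``merge_events`` is a list of (time_gen, source_deme, dest_deme): at that
    time every lineage of the source relocates to the destination, which
    keeps its own Ne.  ``migration`` maps ordered deme pairs to per-lineage,
    per-generation rates, active only while t < ``migration_end`` (always
    active when None).  Termination is guaranteed because all lineages
    eventually share one deme.
    """
    demes = [d for d in sample_sizes if sample_sizes[d] > 0]
    leaf_demes: list[str] = []
    lineages: dict[str, list[int]] = {d: [] for d in deme_ne}
    nid = 0
    for d in demes:
        for _ in range(sample_sizes[d]):
            lineages[d].append(nid)
            leaf_demes.append(d)
            nid += 1
    n = nid
    times = [0.0] * n
    children: list[tuple[int, int] | None] = [None] * n
    events = sorted(merge_events)
    ev_i = 0
    t = 0.0
    n_mig = 0
    active = {d for d in lineages if lineages[d]}

    def n_active() -> int:
        return sum(len(v) for v in lineages.values())

    while n_active() > 1:
        mig_on = migration_end is None or t < migration_end
        coal_rates = {}
        mig_rates = {}
        for d in list(lineages):
            k = len(lineages[d])
            if k >= 2:
                coal_rates[d] = k * (k - 1) / (2.0 * deme_ne[d])
            if k >= 1 and mig_on:
                for (src, dst), m in migration.items():
                    if src == d and m > 0 and dst in deme_ne:
                        mig_rates[(src, dst)] = k * m
        total = sum(coal_rates.values()) + sum(mig_rates.values())
        next_ev = events[ev_i][0] if ev_i < len(events) else math.inf
        if migration_end is not None and t < migration_end:
            next_ev = min(next_ev, migration_end)
        if total <= 0:
            if next_ev is math.inf:
                raise RuntimeError(
                    "coalescent cannot terminate: isolated lineages with no "
                    "migration and no merge events"
                )
            t = next_ev
        else:
            dt = rng.exponential(1.0 / total)
            if t + dt >= next_ev:
                t = next_ev
            else:
                t += dt
                # choose among competing exponential clocks
                u = rng.uniform(0, total)
                acc = 0.0
                chosen = None
                for d, r in coal_rates.items():
                    acc += r
                    if u < acc:
                        chosen = ("coal", d)
                        break
                if chosen is None:
                    for pair, r in mig_rates.items():
                        acc += r
                        if u < acc:
                            chosen = ("mig", pair)
                            break
                if chosen is None:  # numerical edge
                    chosen = ("coal", next(iter(coal_rates)))
                if chosen[0] == "coal":
                    d = chosen[1]
                    k = len(lineages[d])
                    i, j = rng.choice(k, size=2, replace=False)
                    i, j = (int(i), int(j)) if i < j else (int(j), int(i))
                    c2 = lineages[d].pop(j)
                    c1 = lineages[d].pop(i)
                    times.append(t)
                    children.append((c1, c2))
                    lineages[d].append(nid)
                    nid += 1
                else:
                    src, dst = chosen[1]
                    k = len(lineages[src])
                    pick = int(rng.integers(k))
                    lineages[dst].append(lineages[src].pop(pick))
                    n_mig += 1
                continue
        # arrived at a scheduled event time
        while ev_i < len(events) and events[ev_i][0] <= t:
            _, src, dst = events[ev_i]
            lineages[dst].extend(lineages.pop(src, []))
            active.discard(src)
            ev_i += 1

    return Genealogy(
        times=np.asarray(times),
        children=children,
        leaf_demes=leaf_demes,
        n_migrations=n_mig,
    )


def simulate_genealogy(
    model: DemographicModel, draw: ParameterDraw, rng: np.random.Generator
) -> Genealogy:
    """Simulate one genealogy under a three-deme scenario and parameter draw."""
    t_t, t_r = model.t_target_gen, model.t_root_gen
    if model.scenario == "cultural":
        merges = [(t_t, "TARGET", "AA"), (t_r, "DAI", "AA")]
    else:
        merges = [(t_t, "TARGET", "DAI"), (t_r, "DAI", "AA")]
    migration: dict[tuple[str, str], float] = {}
    migration_end = None
    if model.scenario == "continuous_migration" and draw.m:
        migration = {("TARGET", "AA"): draw.m, ("AA", "TARGET"): draw.m}
        migration_end = t_t
    return simulate_structured_genealogy(
        sample_sizes=model.sample_sizes,
        deme_ne=dict(draw.ne),
        migration=migration,
        merge_events=merges,
        rng=rng,
        migration_end=migration_end,
    )


# ---------------------------------------------------------------------------
# Infinite-sites mutation


def _mutation_counts_per_branch(
    genealogy: Genealogy,
    mu_per_bp_year: float,
    locus_length_bp: int,
    generation_time_years: float,
    rng: np.random.Generator,
) -> np.ndarray:
    lengths = genealogy.branch_lengths()
    total = lengths.sum()
    mu_locus_gen = mu_per_bp_year * generation_time_years * locus_length_bp
    n_mut = rng.poisson(total * mu_locus_gen)
    if n_mut == 0 or total == 0:
        return np.zeros(genealogy.n_nodes, dtype=int)
    return rng.multinomial(n_mut, lengths / total)


def _sfs_from_branch_mutations(
    genealogy: Genealogy, muts: np.ndarray, demes: list[str]
) -> SFSVector:
    counts = genealogy.leaf_counts_by_deme(demes)
    n_per_deme = counts[genealogy.root]
    sfs = {
        d: np.zeros(max(0, int(n_per_deme[i]) - 1), dtype=int)
        for i, d in enumerate(demes)
    }
    total_S = int(muts[: genealogy.root].sum())  # root branch carries none
    for node in range(genealogy.root):
        k = int(muts[node])
        if k == 0:
            continue
        for i, d in enumerate(demes):
            c = int(counts[node, i])
            if 0 < c < n_per_deme[i]:
                sfs[d][c - 1] += k
    return SFSVector(deme_sfs=sfs, total_S=total_S)


def drop_mutations(
    genealogy: Genealogy,
    mu_per_bp_year: float,
    locus_length_bp: int,
    generation_time_years: float,
    rng: np.random.Generator,
) -> tuple[HaplotypeAlignment, SFSVector]:
    """Place infinite-sites mutations and return alignment plus unfolded SFS.

    The number of mutations is Poisson with mean (total branch length in
    generations) x (mu * g * L); each mutation hits a fresh site on a branch
    chosen proportionally to its length.  The alignment holds 0/1
    ancestral/derived states with ancestral state "0" recorded per site.
    """
    demes = sorted(set(genealogy.leaf_demes))
    muts = _mutation_counts_per_branch(
        genealogy, mu_per_bp_year, locus_length_bp, generation_time_years, rng
    )
    muts[genealogy.root] = 0
    sfs = _sfs_from_branch_mutations(genealogy, muts, demes)
    n = genealogy.n_leaves
    S = int(muts.sum())
    mat = np.full((n, S), "0", dtype="<U1")
    col = 0
    for node in range(genealogy.n_nodes):
        for _ in range(int(muts[node])):
            for leaf in genealogy.clade_leaves(node):
                mat[leaf, col] = "1"
            col += 1
    deme_counter: dict[str, int] = {}
    sample_ids = []
    for d in genealogy.leaf_demes:
        deme_counter[d] = deme_counter.get(d, 0) + 1
        sample_ids.append(f"{d}_{deme_counter[d]:03d}")
    aln = HaplotypeAlignment(
        sample_ids=sample_ids,
        populations=list(genealogy.leaf_demes),
        sites=mat,
        locus_length_bp=max(locus_length_bp, S),
        ancestral_states=np.full(S, "0", dtype="<U1"),
    )
    return aln, sfs


def simulate_sfs(
    model: DemographicModel, draw: ParameterDraw, rng: np.random.Generator
) -> SFSVector:
    """Genealogy + mutations, returning only the SFS (no alignment built)."""
    gen = simulate_genealogy(model, draw, rng)
    muts = _mutation_counts_per_branch(
        gen,
        model.mutation_rate_per_bp_year,
        model.locus_length_bp,
        model.generation_time_years,
        rng,
    )
    muts[gen.root] = 0
    demes = sorted(set(gen.leaf_demes))
    return _sfs_from_branch_mutations(gen, muts, demes)


def simulate_sfs_batch(
    model: DemographicModel, n_sims: int, base_seed: int
) -> list[tuple[ParameterDraw, SFSVector]]:
    """n_sims independent prior-predictive simulations.

    Row i is reproducible from seed ``base_seed + i`` alone, so batches can
    be regenerated or extended without re-running earlier rows.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rows = []
    for i in range(n_sims):
        rng = np.random.default_rng(base_seed + i)
        draw = sample_prior(model, rng)
        draw.seed = base_seed + i
        rows.append((draw, simulate_sfs(model, draw, rng)))
    return rows


# ---------------------------------------------------------------------------
# Observed SFS


def observed_sfs(
    alignment: HaplotypeAlignment,
    sample_sizes: dict[str, int],
    seed: int | None = None,
) -> SFSVector:
    """Unfolded SFS of a polarized alignment, subsampled to model sizes.

    Each deme is subsampled without replacement to ``sample_sizes[deme]``
    (matching the simulated design, which uses the lowest sample size among
    the populations in the model).  Sites whose ancestral state is missing
    are dropped; a site enters ``total_S`` if it segregates within the
    retained sample, and deme vectors exclude frequency classes 0 and n_d.
    """
    if alignment.ancestral_states is None:
        raise ValueError("observed SFS requires ancestral states")
    rng = np.random.default_rng(seed)
    pops = np.asarray(alignment.populations)
    keep_idx: list[int] = []
    for d, nd in sample_sizes.items():
        avail = np.flatnonzero(pops == d)
        if len(avail) < nd:
            raise ValueError(
                f"deme {d} has {len(avail)} samples, need {nd} for the model"
            )
        chosen = rng.choice(avail, size=nd, replace=False)
        keep_idx.extend(int(i) for i in np.sort(chosen))
    sub = alignment.subset(keep_idx)
    anc = alignment.ancestral_states
    polarizable = anc != "N"
    n_dropped = int((~polarizable).sum())
    if n_dropped:
        import warnings

        warnings.warn(f"dropped {n_dropped} unpolarizable sites", stacklevel=2)
    sites = sub.sites[:, polarizable]
    anc = anc[polarizable]
    derived = (sites != anc[None, :]) & (sites != "N")
    total_counts = derived.sum(axis=0)
    n_total = sub.n_samples
    seg = (total_counts > 0) & (total_counts < n_total)
    total_S = int(seg.sum())
    demes = sorted(sample_sizes)
    subpops = np.asarray(sub.populations)
    deme_sfs = {}
    for d in demes:
        nd = sample_sizes[d]
        rows = subpops == d
        c = derived[rows][:, seg].sum(axis=0)
        vec = np.zeros(max(0, nd - 1), dtype=int)
        for i in range(1, nd):
            vec[i - 1] = int(np.sum(c == i))
        deme_sfs[d] = vec
    return SFSVector(deme_sfs=deme_sfs, total_S=total_S)
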