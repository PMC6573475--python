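"""Independent brute-force oracles used to verify the statistics.

Everything here is deliberately written with explicit loops and from the
textbook definitions, sharing no code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y and x != "N" and y != "N")


def h_oracle(counts) -> float:
    n = sum(counts)
    s = 0.0
    for c in counts:
        s += (c / n) ** 2
    return n * (1.0 - s) / (n - 1)


def mpd_oracle(seqs: list[str]) -> float:
    total, npairs = 0, 0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            total += hamming(seqs[i], seqs[j])
            npairs += 1
    return total / npairs


def tajima_d_oracle(S: int, pi: float, n: int) -> float:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def _ssd(seq_group: list[str], squared: bool) -> float:
    """Sum over unordered pairs of delta^2, divided by group size."""
    tot = 0.0
    for a, b in itertools.combinations(seq_group, 2):
        d = hamming(a, b)
        tot += d * d if squared else d
    return tot / len(seq_group)


def phist_2pop_oracle(
    pop1: list[str], pop2: list[str], squared: bool = True
) -> float:
    """Two-population AMOVA Phi-st from explicit sums of squares."""
    n1, n2 = len(pop1), len(pop2)
    N, P = n1 + n2, 2
    ssd_wp = _ssd(pop1, squared) + _ssd(pop2, squared)
    ssd_t = 0.0
    allseq = pop1 + pop2
    for a, b in itertools.combinations(allseq, 2):
        d = hamming(a, b)
        ssd_t += (d * d if squared else d)
    ssd_t /= N
    ssd_ap = ssd_t - ssd_wp
    sigma_c = ssd_wp / (N - P)
    n_c = (N - (n1 * n1 + n2 * n2) / N) / (P - 1)
    sigma_a = (ssd_ap / (P - 1) - sigma_c) / n_c
    return sigma_a / (sigma_a + sigma_c)


def amova3_oracle(
    groups: list[list[list[str]]], squared: bool = True
) -> dict[str, float]:
    """Three-level AMOVA variance components by explicit computation.

    ``groups`` is a list of groups, each a list of populations, each a list
    of sequences.
    """
    pops = [p for g in groups for p in g]
    allseq = [s for p in pops for s in p]
    N = len(allseq)
    P = len(pops)
    G = len(groups)
    sizes = [len(p) for p in pops]

    def ssd_set(seqs):
        tot = 0.0
        for a, b in itertools.combinations(seqs, 2):
            d = hamming(a, b)
            tot += d * d if squared else d
        return tot / len(seqs)

    ssd_wp = sum(ssd_set(p) for p in pops)
    ssd_t = ssd_set(allseq)
    ssd_wg = sum(ssd_set([s for p in g for s in p]) for g in groups)
    ssd_ag = ssd_t - ssd_wg
    ssd_ap_wg = ssd_wg - ssd_wp

    sigma_c = ssd_wp / (N - P)
    sum_nsq_over_Ng = 0.0
    for g in groups:
        Ng = sum(len(p) for p in g)
        sum_nsq_over_Ng += sum(len(p) ** 2 for p in g) / Ng
    n1 = (N - sum_nsq_over_Ng) / (P - G)
    n2 = (sum_nsq_over_Ng - sum(s * s for s in sizes) / N) / (G - 1)
    n3 = (N - sum((sum(len(p) for p in g)) ** 2 for g in groups) / N) / (G - 1)
    sigma_b = (ssd_ap_wg / (P - G) - sigma_c) / n1
    sigma_a = (ssd_ag / (G - 1) - sigma_c - n2 * sigma_b) / n3
    total = sigma_a + sigma_b + sigma_c
    return {
        "sigma_a": sigma_a,
        "sigma_b": sigma_b,
        "sigma_c": sigma_c,
        "phi_st": (sigma_a + sigma_b) / total,
        "phi_ct": sigma_a / total,
        "phi_sc": sigma_b / (sigma_b + sigma_c),
        "percentages": [
            100 * sigma_a / total,
            100 * sigma_b / total,
            100 * sigma_c / total,
        ],
    }


def da_oracle(pop1: list[str], pop2: list[str]) -> float:
    """Nei's net divergence from the three mean-difference terms."""
    between = [hamming(a, b) for a in pop1 for b in pop2]
    within1 = [hamming(a, b) for a, b in itertools.combinations(pop1, 2)]
    within2 = [hamming(a, b) for a, b in itertools.combinations(pop2, 2)]
    return (
        sum(between) / len(between)
        - (sum(within1) / len(within1) + sum(within2) / len(within2)) / 2.0
    )


def mantel_r_oracle(A: np.ndarray, B: np.ndarray) -> float:
    n = A.shape[0]
    va, vb = [], []
    for i in range(n):
        for j in range(i + 1, n):
            va.append(A[i, j])
            vb.append(B[i, j])
    return float(np.corrcoef(va, vb)[0, 1])


def mwu_u_oracle(x, y) -> float:
    """U for group x by counting pairwise wins (ties count half)."""
    u = 0.0
    for a in x:
        for b in y:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u
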