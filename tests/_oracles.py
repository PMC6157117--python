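"""Independent oracles used by the tests.

These deliberately avoid the package's own algorithms: kinship comes from
Wright's path-counting formula over explicitly enumerated ancestor paths, and
pedigree sizes from a literal replay of the documented mating rules against
the same random stream.
"""

from __future__ import annotations

import numpy as np

from famblup._rng import stage_rng
from famblup.pedigree import Pedigree


def path_counting_relationship(pedigree: Pedigree) -> np.ndarray:
    """Additive relationship matrix via common-ancestor path counting.

    A_ij = 2 Φ_ij with Φ_ij = Σ over common ancestors A and pairs of upward
    paths (i→A, j→A) sharing no individual but A of (1/2)^(len1+len2-1) ·
    (1 + F_A); diagonal A_ii = 1 + F_i, F_i = Φ(father_i, mother_i).
    Exponential in pedigree size; intended for pedigrees of ~20 individuals.
    """
    parents = {r.individual_id: (r.father_id, r.mother_id)
               for r in pedigree.records}

    def paths_up(i: str) -> list[list[str]]:
        out = [[i]]
        stack = [[i]]
        while stack:
            p = stack.pop()
            for par in parents[p[-1]]:
                if par is not None:
                    q = p + [par]
                    out.append(q)
                    stack.append(q)
        return out

    def inbreeding(i: str) -> float:
        fa, mo = parents[i]
        if fa is None:
            return 0.0
        return phi(fa, mo)

    def phi(i: str, j: str) -> float:
        if i == j:
            return 0.5 * (1.0 + inbreeding(i))
        total = 0.0
        for p1 in paths_up(i):
            for p2 in paths_up(j):
                if p1[-1] != p2[-1]:
                    continue
                if set(p1) & set(p2) != {p1[-1]}:
                    continue
                total += 0.5 ** (len(p1) + len(p2) - 1) * \
                    (1.0 + inbreeding(p1[-1]))
        return total

    ids = pedigree.ids
    n = len(ids)
    A = np.empty((n, n))
    for a in range(n):
        A[a, a] = 1.0 + inbreeding(ids[a])
        for b in range(a):
            A[a, b] = A[b, a] = 2.0 * phi(ids[a], ids[b])
    return A


def replay_pedigree_count(seed: int, n_families: int, generations: int,
                          mean_sibship: float) -> int:
    """Total individual count by replaying the documented mating rules.

    Stream order (must match the simulator's contract): per family, per
    generation, per couple in creation order: one Poisson sibship draw, then
    one uniform sex draw per child.  Couples: founder couple in generation 0;
    each non-terminal child and an immigrant spouse form the next couple.
    """
    rng = stage_rng(seed, "pedigree")
    total = 0
    for _fam in range(n_families):
        total += 2  # founder couple
        n_couples = 1
        for gen in range(1, generations + 1):
            next_couples = 0
            for _c in range(n_couples):
                nsib = 1 + int(rng.poisson(mean_sibship - 1.0))
                for _k in range(nsib):
                    rng.random()  # sex draw
                    total += 1
                    if gen < generations:
                        total += 1  # immigrant spouse
                        next_couples += 1
            n_couples = next_couples
    return total
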