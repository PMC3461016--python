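"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written with naive loops and a different
algorithmic route than the package code it checks.
"""

from __future__ import annotations

import math
from itertools import combinations, product

import numpy as np

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def reverse_complement_oracle(seq: str) -> str:
    out = []
    for ch in seq:
        out.append(_COMP[ch])
    out.reverse()
    return "".join(out)


def triplet_counts_oracle(sequences, stop_codons) -> dict[str, int]:
    """Count codons by walking triplets, start included, stops dropped."""
    counts: dict[str, int] = {}
    for seq in sequences:
        triplets = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        for t in triplets:
            if t in stop_codons:
                continue
            counts[t] = counts.get(t, 0) + 1
    return counts


def entropy_oracle(seq: str, codon_table) -> float:
    """Direct summation of the amino-acid-weighted synonymous codon entropy."""
    triplets = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if triplets[-1] in codon_table.stop_codons:
        triplets = triplets[:-1]
    N = len(triplets)
    total = 0.0
    for aa in set(codon_table.forward.values()):
        family = [c for c, a in codon_table.forward.items() if a == aa]
        n_a = sum(1 for t in triplets if t in family)
        if n_a == 0:
            continue
        h = 0.0
        for c in family:
            n_c = sum(1 for t in triplets if t == c)
            p = n_c / n_a
            if p > 0.0:
                h += -p * math.log(p)
        total += n_a * h
    return total / N


def lp_vertex_enumeration(S: np.ndarray, lb: np.ndarray, ub: np.ndarray, c: np.ndarray) -> float:
    """Max of c·v over {S v = 0, lb <= v <= ub} by enumerating basic solutions.

    All bounds must be finite.  Every choice of n - rank(S) variables pinned
    to one of their bounds gives a candidate vertex; the maximum objective
    over the feasible candidates is the LP optimum.
    """
    m, n = S.shape
    r = np.linalg.matrix_rank(S) if m else 0
    k = n - r
    best = -math.inf
    for idx in combinations(range(n), k):
        free = [i for i in range(n) if i not in idx]
        A = S[:, free]
        for vals in product(*[(lb[i], ub[i]) for i in idx]):
            b = -S[:, list(idx)] @ np.array(vals)
            if free:
                sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
                if rank < len(free):
                    continue
            else:
                sol = np.zeros(0)
            v = np.zeros(n)
            v[list(idx)] = vals
            v[free] = sol
            if np.abs(S @ v).max(initial=0.0) > 1e-8:
                continue
            if (v < lb - 1e-9).any() or (v > ub + 1e-9).any():
                continue
            best = max(best, float(c @ v))
    return best


def gpr_truth_oracle(expression: str, present: set[str], all_genes: list[str]) -> bool:
    """Evaluate a GPR string directly with Python's and/or semantics."""
    env = {g: (g in present) for g in all_genes}
    return bool(eval(expression, {"__builtins__": {}}, env))  # noqa: S307 - test oracle
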