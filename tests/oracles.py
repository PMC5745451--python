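"""Independent brute-force oracles used across the test suite.

Each oracle recomputes a quantity by exhaustive enumeration, staying
deliberately independent of the package's implementation path.
"""

from __future__ import annotations

import itertools

import numpy as np

from boolstab.infer import BooleanFunction
from boolstab.network import BooleanNetwork, decode_state, encode_state


def brute_min_sse(u: np.ndarray, d: int) -> float:
    """Minimum SSE over all placements of d breaks in the sorted vector u."""
    n = len(u)
    best = np.inf
    for combo in itertools.combinations(range(1, n), d):
        bounds = [0, *combo, n]
        sse = sum(
            float(np.sum((u[a:b] - np.mean(u[a:b])) ** 2))
            for a, b in zip(bounds[:-1], bounds[1:])
        )
        best = min(best, sse)
    return best


def brute_best_fit_error(pairs, target: int, n_genes: int, max_k: int) -> int:
    """Minimal misclassification count over ALL input sets and ALL functions.

    For every input set of size 0..max_k and every Boolean function on
    it, counts the observed transitions the function gets wrong; returns
    the global minimum.  Exponential — for tiny problems only.
    """
    best = None
    for k in range(max_k + 1):
        for inputs in itertools.combinations(range(n_genes), k):
            for table in itertools.product((0, 1), repeat=2**k):
                wrong = 0
                for state, nxt in pairs:
                    idx = 0
                    for g in inputs:
                        idx = (idx << 1) | int(state[g])
                    if table[idx] != int(nxt[target]):
                        wrong += 1
                if best is None or wrong < best:
                    best = wrong
                if best == 0:
                    return 0
    assert best is not None
    return best


def brute_successors(net: BooleanNetwork) -> dict[int, int]:
    """Integer successor map over the full state space by direct evaluation."""
    n = net.n
    out = {}
    for code in range(2**n):
        x = decode_state(code, n)
        y = [f.evaluate(x) for f in net.functions]
        out[code] = encode_state(y)
    return out


def exhaustive_attractor_cycles(net: BooleanNetwork) -> set[frozenset[int]]:
    """All attractor cycles, as state sets, from the full transition graph."""
    succ = brute_successors(net)
    cycles: set[frozenset[int]] = set()
    for start in range(2**net.n):
        seen: dict[int, int] = {}
        code = start
        t = 0
        while code not in seen:
            seen[code] = t
            code = succ[code]
            t += 1
        entry = seen[code]
        cycles.add(frozenset(c for c, step in seen.items() if step >= entry))
    return cycles


def exact_expected_damage(net: BooleanNetwork, horizon: int, n_flip: int = 1) -> float:
    """Exact mean normalized Hamming damage over all states x flip choices."""
    n = net.n
    succ = brute_successors(net)

    def advance(code: int) -> int:
        for _ in range(horizon):
            code = succ[code]
        return code

    total = 0.0
    count = 0
    for code in range(2**n):
        for flip_bits in itertools.combinations(range(n), n_flip):
            flipped = code
            for b in flip_bits:
                flipped ^= 1 << (n - 1 - b)
            a, b2 = advance(code), advance(flipped)
            total += bin(a ^ b2).count("1") / n
            count += 1
    return total / count


def random_small_network(rng: np.random.Generator, n: int, k: int) -> BooleanNetwork:
    """Seeded random network built directly, independent of the generator module."""
    funcs = []
    for _ in range(n):
        inputs = tuple(int(i) for i in rng.choice(n, size=k, replace=False))
        table = tuple(int(b) for b in rng.integers(0, 2, size=2**k))
        funcs.append(BooleanFunction(inputs, table))
    return BooleanNetwork(tuple(f"x{i}" for i in range(n)), tuple(funcs))
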