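"""Best-fit inference of Boolean functions from binarized time series.

For each target gene the inference searches over candidate regulator sets
X' of size k = 0..max_k.  Observed transitions (state at t, target bit at
t+1) populate a partially defined Boolean function (pdBf): input patterns
seen with target 1 go to the true set T, patterns seen with target 0 to
the false set F.  The error of a regulator set is the number of examples
that any single Boolean function must misclassify,

    error = sum over patterns of min(count_T, count_F),

which reduces to |T n F| when every pattern occurs once — the regime of
short series.  Regulator sets achieving the global minimum error at the
smallest cardinality are kept; each yields one or more concrete Boolean
functions by completing the unobserved (don't-care) truth-table entries.

The per-gene candidate lists form a probabilistic-Boolean-network-style
function set with equal weight per candidate.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

DONT_CARE = -1  # truth-table entry for an unobserved input pattern


@dataclass(frozen=True)
class BooleanFunction:
    """A Boolean update rule as an explicit truth table.

    ``inputs`` are gene indices; ``inputs[0]`` is the most significant bit
    of the truth-table index, so the pattern (b0, b1, ..) of the input
    genes indexes entry ``b0*2^(k-1) + b1*2^(k-2) + ..``.  Table entries
    are 0, 1 or ``DONT_CARE`` (-1) for an undefined pattern.
    """

    inputs: tuple[int, ...]
    table: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.table) != 2 ** len(self.inputs):
            raise ValueError("truth table length must be 2^k")
        if any(t not in (0, 1, DONT_CARE) for t in self.table):
            raise ValueError("truth table entries must be 0, 1 or -1 (don't-care)")
        if len(set(self.inputs)) != len(self.inputs):
            raise ValueError("duplicate input indices")

    @property
    def k(self) -> int:
        return len(self.inputs)

    @property
    def is_constant(self) -> bool:
        return len(self.inputs) == 0

    @property
    def is_fully_defined(self) -> bool:
        return DONT_CARE not in self.table

    def evaluate(self, state) -> int:
        """Apply the rule to a full network state (0/1 sequence)."""
        idx = 0
        for g in self.inputs:
            idx = (idx << 1) | int(state[g])
        out = self.table[idx]
        if out == DONT_CARE:
            raise ValueError("pattern hits a don't-care entry")
        return out


@dataclass(frozen=True)
class PdBf:
    """Partially defined Boolean function extracted from transitions."""

    target: int
    inputs: tuple[int, ...]
    true_counts: Counter = field(repr=False)
    false_counts: Counter = field(repr=False)
    error: int


@dataclass
class FunctionSet:
    """Per-gene candidate Boolean functions, each with equal probability."""

    gene_ids: list[str]
    functions: list[list[BooleanFunction]]
    errors: list[int]

    def __post_init__(self) -> None:
        if not all(len(f) >= 1 for f in self.functions):
            raise ValueError("every gene needs at least one candidate function")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def function_counts(self) -> pd.Series:
        return pd.Series([len(f) for f in self.functions], index=self.gene_ids, name="n_functions")

    def dependencies(self) -> set[tuple[str, str]]:
        """Union over candidates of (regulator, target) gene-id pairs."""
        deps: set[tuple[str, str]] = set()
        for tgt, funcs in enumerate(self.functions):
            for f in funcs:
                for reg in f.inputs:
                    deps.add((self.gene_ids[reg], self.gene_ids[tgt]))
        return deps

    def mean_inputs_per_function(self) -> float:
        """Mean regulator count over all candidates of all genes."""
        sizes = [f.k for funcs in self.functions for f in funcs]
        return float(np.mean(sizes))


def transition_pairs(matrix) -> list[tuple[np.ndarray, np.ndarray]]:
    """Consecutive (state(t), state(t+1)) column pairs of a genes x time matrix.

    m timepoints yield m-1 pairs.  Pass each group's series separately:
    pairs never span a group boundary.
    """
    M = np.asarray(matrix, dtype=np.int8)
    if M.ndim != 2:
        raise ValueError("expected a genes x timepoints matrix")
    if M.shape[1] < 2:
        raise ValueError("need at least 2 timepoints")
    if not np.isin(M, (0, 1)).all():
        raise ValueError("matrix entries must be 0/1")
    return [(M[:, t].copy(), M[:, t + 1].copy()) for t in range(M.shape[1] - 1)]


def _pattern_index(state: np.ndarray, inputs: tuple[int, ...]) -> int:
    idx = 0
    for g in inputs:
        idx = (idx << 1) | int(state[g])
    return idx


def build_pdbf(pairs, target: int, input_set) -> PdBf:
    """Fill T/F pattern multisets for one candidate regulator set."""
    inputs = tuple(int(i) for i in input_set)
    if len(set(inputs)) != len(inputs):
        raise ValueError("duplicate indices in input set")
    T: Counter = Counter()
    F: Counter = Counter()
    for state, nxt in pairs:
        idx = _pattern_index(state, inputs)
        if int(nxt[target]):
            T[idx] += 1
        else:
            F[idx] += 1
    error = sum(min(T[p], F[p]) for p in T.keys() & F.keys())
    return PdBf(target=target, inputs=inputs, true_counts=T, false_counts=F, error=int(error))


def best_fit_inputs(
    pairs, target: int, max_k: int, n_genes: int
) -> tuple[int, list[tuple[int, ...]]]:
    """All minimal-error regulator sets of smallest cardinality.

    Examines every input set of size 0..max_k; returns (min_error, sets)
    where the sets are exactly those of the smallest size attaining the
    global minimum error.  Search stops early once a zero-error size is
    found, since supersets of a zero-error set are excluded anyway.
    """
    if max_k < 0:
        raise ValueError("max_k must be >= 0")
    if max_k > n_genes:
        warnings.warn(f"max_k={max_k} exceeds gene count {n_genes}; clamping", stacklevel=2)
        max_k = n_genes

    best_err: int | None = None
    best_sets: list[tuple[int, ...]] = []
    for k in range(max_k + 1):
        k_err: int | None = None
        k_sets: list[tuple[int, ...]] = []
        for combo in itertools.combinations(range(n_genes), k):
            err = build_pdbf(pairs, target, combo).error
            if k_err is None or err < k_err:
                k_err, k_sets = err, [combo]
            elif err == k_err:
                k_sets.append(combo)
        if k_err is not None and (best_err is None or k_err < best_err):
            best_err, best_sets = k_err, k_sets
        if best_err == 0:
            break
    assert best_err is not None
    return best_err, best_sets


def enumerate_functions(pdbf: PdBf, expansion_cap: int = 1024) -> list[BooleanFunction]:
    """Concrete Boolean functions consistent with a pdBf.

    Observed patterns get their majority label (ties resolve to 0, the
    deterministic conflict rule); unobserved patterns are don't-cares.
    When the number of completions 2^q is at most ``expansion_cap``, all
    completions are returned; otherwise the all-zero canonical completion
    plus the don't-care template are returned and the template's ?
    entries are instantiated later, at network-sampling time.
    """
    k = len(pdbf.inputs)
    size = 2**k
    table = np.full(size, DONT_CARE, dtype=np.int8)
    for p in pdbf.true_counts.keys() | pdbf.false_counts.keys():
        t, f = pdbf.true_counts[p], pdbf.false_counts[p]
        table[p] = 1 if t > f else 0  # majority; tie -> 0
    undef = np.flatnonzero(table == DONT_CARE)
    q = undef.size
    if q == 0:
        return [BooleanFunction(pdbf.inputs, tuple(int(x) for x in table))]
    if 2**q <= expansion_cap:
        out = []
        for bits in itertools.product((0, 1), repeat=q):
            filled = table.copy()
            filled[undef] = bits
            out.append(BooleanFunction(pdbf.inputs, tuple(int(x) for x in filled)))
        return out
    canonical = table.copy()
    canonical[undef] = 0
    return [
        BooleanFunction(pdbf.inputs, tuple(int(x) for x in canonical)),
        BooleanFunction(pdbf.inputs, tuple(int(x) for x in table)),
    ]


def reconstruct(
    matrix,
    gene_ids=None,
    max_k: int = 5,
    expansion_cap: int = 1024,
) -> FunctionSet:
    """Best-fit reconstruction of a function set from one group's series.

    ``matrix`` is genes x timepoints with 0/1 entries.  Per gene, all
    smallest minimal-error regulator sets are found and expanded into
    concrete candidate functions, deduplicated.
    """
    M = np.asarray(matrix, dtype=np.int8)
    if gene_ids is None:
        if isinstance(matrix, pd.DataFrame):
            gene_ids = [str(g) for g in matrix.index]
        else:
            gene_ids = [f"g{i}" for i in range(M.shape[0])]
    pairs = transition_pairs(M)
    n = M.shape[0]
    functions: list[list[BooleanFunction]] = []
    errors: list[int] = []
    for target in range(n):
        err, sets = best_fit_inputs(pairs, target, max_k, n)
        seen: dict[tuple, BooleanFunction] = {}
        for s in sets:
            pdbf = build_pdbf(pairs, target, s)
            for f in enumerate_functions(pdbf, expansion_cap):
                seen.setdefault((f.inputs, f.table), f)
        functions.append(list(seen.values()))
        errors.append(err)
    return FunctionSet(gene_ids=list(gene_ids), functions=functions, errors=errors)


class BestFitInferrer(BaseEstimator):
    """Scikit-learn-style estimator wrapping best-fit network inference.

    ``fit`` expects a binary matrix of shape (n_timepoints, n_genes) —
    rows are consecutive observations — and exposes the reconstruction as
    fitted attributes.

    Parameters
    ----------
    max_k : int
        Largest regulator-set size examined per gene.
    expansion_cap : int
        Maximum number of don't-care completions expanded per regulator
        set; beyond it a canonical completion plus template are kept.

    Attributes
    ----------
    function_set_ : FunctionSet
    errors_ : list of int
        Minimal best-fit error per gene (0 = series replayed exactly).
    dependencies_ : set of (regulator, target) gene-id pairs
    function_counts_ : pandas Series, candidates per gene
    """

    def __init__(self, max_k: int = 5, expansion_cap: int = 1024):
        self.max_k = max_k
        self.expansion_cap = expansion_cap

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            gene_ids = [str(c) for c in X.columns]
            M = X.to_numpy().T
        else:
            M = np.asarray(X).T
            gene_ids = None
        fs = reconstruct(M, gene_ids=gene_ids, max_k=self.max_k, expansion_cap=self.expansion_cap)
        self.function_set_ = fs
        self.errors_ = fs.errors
        self.dependencies_ = fs.dependencies()
        self.function_counts_ = fs.function_counts()
        self.n_features_in_ = fs.n_genes
        return self
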