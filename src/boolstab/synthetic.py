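"""Ground-truth studies: random networks, binary series, expression matrices.

Emulates the structure of the two-group human muscle time-series study:
two short expression time series (7 young and 8 aged samples by default)
over a gene panel in which only a subset of genes is genuinely
binarizable.  Each group's binary dynamics come from a known synchronous
Boolean network; real values are emitted from a two-component location
model (low mean for bit 0, high mean for bit 1) for binarizable genes
and from a single overlapping unimodal distribution for the rest, so the
full pipeline — binarization, inference, stability — can be tested
against known truth without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import EMISSION, NETWORK_SAMPLING, START_STATES, derive_rng
from .infer import BooleanFunction
from .network import BooleanNetwork, simulate


@dataclass(frozen=True)
class ExpressionParams:
    """Two-component emission on a log2-like microarray scale.

    Bit 1 emits near ``high_mean``, bit 0 near ``low_mean`` with Gaussian
    ``spread``; non-binarizable genes emit from one unimodal component at
    the midpoint with ``unimodal_spread``.  All outputs are clipped to a
    small positive floor so geometric-mean aggregation stays defined.
    """

    low_mean: float = 6.0
    high_mean: float = 10.0
    spread: float = 0.3
    unimodal_spread: float = 0.7

    def __post_init__(self) -> None:
        if self.low_mean <= 0 or self.high_mean <= 0:
            raise ValueError("means must be positive")
        if self.high_mean - self.low_mean <= 0:
            raise ValueError("separation (high_mean - low_mean) must be positive")

    @property
    def separation(self) -> float:
        return self.high_mean - self.low_mean


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Conditions of a generated two-group study (defaults = study scale)."""

    n_genes: int = 86
    n_binarizable: int = 22
    timepoints_young: int = 7
    timepoints_aged: int = 8
    in_degree: int = 2
    bias: float = 0.5
    flip_noise: float = 0.0
    n_constant_aged: int = 0
    params: ExpressionParams = field(default_factory=ExpressionParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_binarizable > self.n_genes:
            raise ValueError("n_binarizable cannot exceed n_genes")
        if not 0 <= self.flip_noise <= 1:
            raise ValueError("flip_noise must be a probability")
        if self.n_constant_aged > self.n_binarizable:
            raise ValueError("cannot plant more constant genes than binarizable genes")


def random_network(
    n: int,
    k: int,
    seed: int | None = None,
    bias: float = 0.5,
    rng: np.random.Generator | None = None,
    gene_ids=None,
) -> BooleanNetwork:
    """Random Kauffman-style network: k distinct inputs per node, random tables."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < bias < 1:
        raise ValueError("bias must be in (0, 1)")
    if rng is None:
        rng = derive_rng(0 if seed is None else seed, NETWORK_SAMPLING)
    if gene_ids is None:
        gene_ids = tuple(f"g{i:03d}" for i in range(n))
    funcs = []
    for _ in range(n):
        inputs = tuple(int(i) for i in rng.choice(n, size=k, replace=False)) if k else ()
        table = tuple(int(b) for b in (rng.random(2**k) < bias).astype(int))
        funcs.append(BooleanFunction(inputs, table))
    return BooleanNetwork(gene_ids=tuple(gene_ids), functions=tuple(funcs))


def generate_binary_series(
    net: BooleanNetwork,
    length: int,
    x0=None,
    flip_noise: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Observed binary series (genes x timepoints) from a synchronous trajectory.

    The trajectory starts at ``x0`` (uniform random when omitted); each
    observed bit is then flipped independently with ``flip_noise``.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    if rng is None:
        rng = derive_rng(0 if seed is None else seed, START_STATES)
    if x0 is None:
        x0 = rng.integers(0, 2, size=net.n, dtype=np.int8)
    traj = simulate(net, x0, length - 1).T  # genes x timepoints
    if flip_noise > 0:
        flips = (rng.random(traj.shape) < flip_noise).astype(np.int8)
        traj = traj ^ flips
    return traj.astype(np.int8)


def generate_expression(
    binary: np.ndarray,
    params: ExpressionParams = ExpressionParams(),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    binarizable_mask=None,
) -> np.ndarray:
    """Emit real values from a binary matrix (inverse of binarization).

    Rows where ``binarizable_mask`` is False ignore their bits and draw
    from the single overlapping component.  Values are clipped to a small
    positive floor.
    """
    B = np.asarray(binary, dtype=np.int8)
    if rng is None:
        rng = derive_rng(0 if seed is None else seed, EMISSION)
    if binarizable_mask is None:
        binarizable_mask = np.ones(B.shape[0], dtype=bool)
    mask = np.asarray(binarizable_mask, dtype=bool)
    means = np.where(B == 1, params.high_mean, params.low_mean).astype(float)
    mid = (params.low_mean + params.high_mean) / 2.0
    means[~mask, :] = mid
    sd = np.where(mask[:, None], params.spread, params.unimodal_spread)
    values = rng.normal(means, sd)
    return np.maximum(values, 1e-6)


@dataclass
class StudyBundle:
    """A generated study plus its ground truth, for recovery tests."""

    spec: SyntheticStudySpec
    expression: pd.DataFrame  # genes x (young samples + aged samples)
    sample_sheet: pd.DataFrame  # sample, group, age
    gene_ids: list[str]
    binarizable_genes: list[str]
    constant_aged_genes: list[str]
    network_young: BooleanNetwork
    network_aged: BooleanNetwork
    binary_young: pd.DataFrame  # binarizable genes x young timepoints
    binary_aged: pd.DataFrame


def generate_study(spec: SyntheticStudySpec) -> StudyBundle:
    """Generate a full two-group study per the spec, deterministically.

    Binarizable genes occupy a seeded random subset of rows; the two true
    networks act on those genes only.  ``n_constant_aged`` genes of the
    aged network are overridden with constant-0 rules (and a 0 start
    bit), mimicking genes that drop below threshold with age.
    """
    rng = derive_rng(spec.seed, EMISSION, 0)
    gene_ids = [f"g{i:03d}" for i in range(spec.n_genes)]
    bin_rows = np.sort(rng.choice(spec.n_genes, size=spec.n_binarizable, replace=False))
    bin_genes = [gene_ids[i] for i in bin_rows]

    net_young = random_network(
        spec.n_binarizable, spec.in_degree, bias=spec.bias,
        rng=derive_rng(spec.seed, NETWORK_SAMPLING, 1), gene_ids=bin_genes,
    )
    net_aged = random_network(
        spec.n_binarizable, spec.in_degree, bias=spec.bias,
        rng=derive_rng(spec.seed, NETWORK_SAMPLING, 2), gene_ids=bin_genes,
    )
    const_rows = list(range(spec.n_constant_aged))
    if const_rows:
        funcs = list(net_aged.functions)
        for i in const_rows:
            funcs[i] = BooleanFunction((), (0,))
        net_aged = replace(net_aged, functions=tuple(funcs))
    const_genes = [bin_genes[i] for i in const_rows]

    def group_series(net, length, stream):
        g_rng = derive_rng(spec.seed, START_STATES, stream)
        x0 = g_rng.integers(0, 2, size=net.n, dtype=np.int8)
        x0[const_rows] = 0 if net is net_aged else x0[const_rows]
        return generate_binary_series(net, length, x0=x0, flip_noise=spec.flip_noise, rng=g_rng)

    bits_young = group_series(net_young, spec.timepoints_young, 3)
    bits_aged = group_series(net_aged, spec.timepoints_aged, 4)

    young_cols = [f"Y{i+1}" for i in range(spec.timepoints_young)]
    aged_cols = [f"A{i+1}" for i in range(spec.timepoints_aged)]
    ages = list(range(21, 21 + spec.timepoints_young)) + list(
        range(67, 67 + spec.timepoints_aged)
    )

    mask = np.zeros(spec.n_genes, dtype=bool)
    mask[bin_rows] = True

    def emit(bits, n_cols, stream):
        full = np.zeros((spec.n_genes, n_cols), dtype=np.int8)
        full[bin_rows, :] = bits
        return generate_expression(
            full, spec.params, rng=derive_rng(spec.seed, EMISSION, stream), binarizable_mask=mask
        )

    expr = np.concatenate(
        [emit(bits_young, spec.timepoints_young, 5), emit(bits_aged, spec.timepoints_aged, 6)],
        axis=1,
    )
    expression = pd.DataFrame(expr, index=gene_ids, columns=young_cols + aged_cols)
    sheet = pd.DataFrame(
        {
            "sample": young_cols + aged_cols,
            "group": ["young"] * spec.timepoints_young + ["aged"] * spec.timepoints_aged,
            "age": ages,
        }
    )
    return StudyBundle(
        spec=spec,
        expression=expression,
        sample_sheet=sheet,
        gene_ids=gene_ids,
        binarizable_genes=bin_genes,
        constant_aged_genes=const_genes,
        network_young=net_young,
        network_aged=net_aged,
        binary_young=pd.DataFrame(bits_young, index=bin_genes, columns=young_cols),
        binary_aged=pd.DataFrame(bits_aged, index=bin_genes, columns=aged_cols),
    )
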