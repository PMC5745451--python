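"""Perturbation experiments: damage spread under single-bit flips.

The robustness of a network is probed by flipping bits of a start state
x(t), advancing both the original and the perturbed state synchronously
for h transitions, and measuring the normalized Hamming distance

    Hn(x, x') = (1/n) * sum_i |x_i - x'_i|

between the two resulting states.  The flip is temporary: nothing is
re-flipped along the walk, so the distance reflects how far the initial
damage spreads (or heals) through the update rules.

The full protocol samples many concrete networks from a function set,
and for each network averages the damage over many trials in three
start-state classes — uniform random states, successors of random
states, and random members of attractors reached from random states —
at one or more horizons.  Per-network averages are retained so the two
phenotype groups can be compared with a Wilcoxon rank-sum test.

Randomness is organized as counter-based streams derived from one master
seed, so every (network, class) cell is reproducible independently of
execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import BIT_FLIPS, NETWORK_SAMPLING, START_STATES, derive_rng
from .infer import FunctionSet
from .network import (
    BooleanNetwork,
    _node_tables,
    decode_state,
    find_attractor,
    sample_network,
    successor_map,
    transition,
    transition_batch,
)

STATE_CLASSES = ("random", "successor", "attractor")


@dataclass(frozen=True)
class PerturbationConfig:
    """Knobs of the perturbation protocol (defaults = full study scale)."""

    n_networks: int = 1000
    n_states: int = 1000
    n_flip_bits: int = 1
    horizons: tuple[int, ...] = (1, 5)
    state_classes: tuple[str, ...] = STATE_CLASSES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_networks < 1 or self.n_states < 1 or self.n_flip_bits < 1:
            raise ValueError("counts must be >= 1")
        if any(h < 1 for h in self.horizons):
            raise ValueError("horizons must be >= 1")
        for cls in self.state_classes:
            if cls not in STATE_CLASSES:
                raise ValueError(f"unknown state class {cls!r}")


def hamming_normalized(x, y) -> float:
    """Fraction of differing bits between two equal-length 0/1 vectors."""
    a = np.asarray(x, dtype=np.int8)
    b = np.asarray(y, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError("state lengths differ")
    return float(np.abs(a - b).sum() / a.size)


def perturb(x, n_bits: int, rng: np.random.Generator) -> np.ndarray:
    """Flip ``n_bits`` distinct random positions of a copy of x."""
    a = np.asarray(x, dtype=np.int8).copy()
    if not 1 <= n_bits <= a.size:
        raise ValueError("n_bits out of range")
    pos = rng.choice(a.size, size=n_bits, replace=False)
    a[pos] ^= 1
    return a


def damage_at_horizon(
    net: BooleanNetwork, x, n_bits: int, horizon: int, rng: np.random.Generator
) -> float:
    """Hn between the h-step successors of x and a randomly perturbed x."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    a = np.asarray(x, dtype=np.int8)
    b = perturb(a, n_bits, rng)
    for _ in range(horizon):
        a = transition(net, a)
        b = transition(net, b)
    return hamming_normalized(a, b)


def start_states(
    net: BooleanNetwork,
    state_class: str,
    n_states: int,
    rng: np.random.Generator,
    _step=None,
) -> np.ndarray:
    """Draw start states of one class as an (n_states, n) 0/1 matrix.

    random: uniform over all 2^n states.  successor: one synchronous
    update of a uniform draw.  attractor: a uniformly chosen member of
    the cycle reached from a uniform draw.
    """
    if state_class not in STATE_CLASSES:
        raise ValueError(f"unknown state class {state_class!r}")
    n = net.n
    states = rng.integers(0, 2, size=(n_states, n), dtype=np.int8)
    if state_class == "random":
        return states
    if state_class == "successor":
        return transition_batch(net, states)
    step = _step if _step is not None else successor_map(net)
    out = np.empty_like(states)
    for i in range(n_states):
        att = find_attractor(net, states[i], _step=step)
        pick = att.states[int(rng.integers(att.length))]
        out[i] = decode_state(pick, n)
    return out


def _batch_damage(
    net: BooleanNetwork,
    states: np.ndarray,
    n_flip_bits: int,
    horizons: tuple[int, ...],
    rng: np.random.Generator,
    prepared,
) -> dict[int, float]:
    """Mean normalized Hamming distance per horizon over a batch of trials."""
    m, n = states.shape
    flips = np.zeros((m, n), dtype=np.int8)
    if n_flip_bits == 1:
        flips[np.arange(m), rng.integers(0, n, size=m)] = 1
    else:
        for i in range(m):
            flips[i, rng.choice(n, size=n_flip_bits, replace=False)] = 1
    orig = states
    pert = states ^ flips
    out: dict[int, float] = {}
    last = max(horizons)
    for h in range(1, last + 1):
        orig = transition_batch(net, orig, _prepared=prepared)
        pert = transition_batch(net, pert, _prepared=prepared)
        if h in horizons:
            out[h] = float(np.abs(orig - pert).sum(axis=1).mean() / n)
    return out


@dataclass
class StabilitySummary:
    """Per-network average damages and their min/max/mean aggregation.

    ``per_network[cls][h]`` is the vector (length n_networks) of
    per-network mean normalized Hamming distances for one start-state
    class and horizon; ``pooled[h]`` averages the classes per network
    (the mean over all trials when classes share ``n_states``).
    """

    config: PerturbationConfig
    per_network: dict[str, dict[int, np.ndarray]] = field(repr=False)

    def cell(self, state_class: str, horizon: int) -> np.ndarray:
        return self.per_network[state_class][horizon]

    @property
    def pooled(self) -> dict[int, np.ndarray]:
        out = {}
        for h in self.config.horizons:
            out[h] = np.mean(
                [self.per_network[cls][h] for cls in self.config.state_classes], axis=0
            )
        return out

    def summary_frame(self) -> pd.DataFrame:
        """Table-1-shaped frame: rows = state classes, columns = (horizon, stat)."""
        rows = {}
        for cls in self.config.state_classes:
            row = {}
            for h in self.config.horizons:
                v = self.per_network[cls][h]
                row[(f"h{h}", "min")] = float(v.min())
                row[(f"h{h}", "max")] = float(v.max())
                row[(f"h{h}", "mean")] = float(v.mean())
            rows[cls] = row
        return pd.DataFrame(rows).T


def stability_experiment(fs: FunctionSet, cfg: PerturbationConfig) -> StabilitySummary:
    """Run the full perturbation protocol on a function set.

    For each of ``cfg.n_networks`` sampled networks and each start-state
    class, ``cfg.n_states`` single-trial damages are averaged at every
    horizon.  Seed streams are derived per network, so cells are
    independent of iteration order.
    """
    classes = tuple(cfg.state_classes)
    horizons = tuple(sorted(cfg.horizons))
    per_network = {cls: {h: np.empty(cfg.n_networks) for h in horizons} for cls in classes}
    for i in range(cfg.n_networks):
        net = sample_network(fs, rng=derive_rng(cfg.seed, NETWORK_SAMPLING, i))
        prepared = _node_tables(net)
        step = successor_map(net) if "attractor" in classes else None
        for ci, cls in enumerate(classes):
            s_rng = derive_rng(cfg.seed, START_STATES, i, ci)
            f_rng = derive_rng(cfg.seed, BIT_FLIPS, i, ci)
            states = start_states(net, cls, cfg.n_states, s_rng, _step=step)
            means = _batch_damage(net, states, cfg.n_flip_bits, horizons, f_rng, prepared)
            for h in horizons:
                per_network[cls][h][i] = means[h]
    return StabilitySummary(config=cfg, per_network=per_network)


def compare_groups(a: StabilitySummary, b: StabilitySummary) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of per-network damages, per cell.

    Two-sided test on the two samples of per-network averages (normal
    approximation with tie correction).  Rows: (state class, horizon);
    columns: statistic, p_value, median_a, median_b.
    """
    if a.config.state_classes != b.config.state_classes or a.config.horizons != b.config.horizons:
        raise ValueError("summaries have different cell structure")
    records = []
    for cls in a.config.state_classes:
        for h in a.config.horizons:
            xa, xb = a.cell(cls, h), b.cell(cls, h)
            if xa.size == 0 or xb.size == 0:
                raise ValueError("empty sample in comparison")
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic")
            records.append(
                {
                    "state_class": cls,
                    "horizon": h,
                    "statistic": float(res.statistic),
                    "p_value": float(res.pvalue),
                    "median_a": float(np.median(xa)),
                    "median_b": float(np.median(xb)),
                }
            )
    return pd.DataFrame(records).set_index(["state_class", "horizon"])
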