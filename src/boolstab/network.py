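"""Synchronous Boolean networks: transition, simulation, attractors, sampling.

A network holds exactly one fully defined Boolean function per gene.  The
state x(t) is a 0/1 vector ordered like the gene list; a synchronous
transition applies every function to the same source state:
x(t+1) = (f1(x(t)), .., fn(x(t))).  Because the state space is finite,
every trajectory eventually enters a recurrent cycle (attractor), found
here by a forward walk with a visited map.

States serialize to unsigned integers with gene 0 as the most significant
bit; this encoding is fixed so seeded runs and logs are reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from ._rng import NETWORK_SAMPLING, derive_rng
from .infer import DONT_CARE, BooleanFunction, FunctionSet


@dataclass(frozen=True)
class BooleanNetwork:
    gene_ids: tuple[str, ...]
    functions: tuple[BooleanFunction, ...]

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if len(self.functions) != n:
            raise ValueError("need exactly one function per gene")
        for f in self.functions:
            if not f.is_fully_defined:
                raise ValueError("network functions must be fully defined (no don't-cares)")
            if any(i >= n or i < 0 for i in f.inputs):
                raise ValueError("function input index out of range")

    @property
    def n(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class Attractor:
    """A recurrent cycle of states plus the transient length to reach it."""

    states: tuple[int, ...]  # integer-encoded cycle, in transition order
    transient: int

    @property
    def length(self) -> int:
        return len(self.states)


def encode_state(bits) -> int:
    """Pack a 0/1 vector into an int, gene 0 as most significant bit."""
    out = 0
    for b in bits:
        out = (out << 1) | int(b)
    return out


def decode_state(code: int, n: int) -> np.ndarray:
    return np.array([(code >> (n - 1 - i)) & 1 for i in range(n)], dtype=np.int8)


def transition(net: BooleanNetwork, state) -> np.ndarray:
    """One synchronous update: all genes read the same source state."""
    x = np.asarray(state, dtype=np.int8)
    if x.shape != (net.n,):
        raise ValueError(f"state length {x.shape} does not match network size {net.n}")
    return np.array([f.evaluate(x) for f in net.functions], dtype=np.int8)


def _node_tables(net: BooleanNetwork):
    """Per-node (input index array, MSB-first weights, table array)."""
    prepared = []
    for f in net.functions:
        k = f.k
        idx = np.asarray(f.inputs, dtype=np.intp)
        w = (1 << np.arange(k - 1, -1, -1)).astype(np.intp) if k else np.zeros(0, dtype=np.intp)
        prepared.append((idx, w, np.asarray(f.table, dtype=np.int8)))
    return prepared


def transition_batch(net: BooleanNetwork, states: np.ndarray, _prepared=None) -> np.ndarray:
    """Synchronous update of many states at once (rows of ``states``)."""
    S = np.asarray(states, dtype=np.int8)
    if S.ndim != 2 or S.shape[1] != net.n:
        raise ValueError("states must be (m, n)")
    prepared = _prepared if _prepared is not None else _node_tables(net)
    out = np.empty_like(S)
    for i, (idx, w, table) in enumerate(prepared):
        if idx.size == 0:
            out[:, i] = table[0]
        else:
            out[:, i] = table[S[:, idx].astype(np.intp) @ w]
    return out


def simulate(net: BooleanNetwork, x0, steps: int) -> np.ndarray:
    """Trajectory of steps+1 states starting at x0 (deterministic)."""
    if steps < 0:
        raise ValueError("steps must be >= 0")
    traj = np.empty((steps + 1, net.n), dtype=np.int8)
    traj[0] = np.asarray(x0, dtype=np.int8)
    for t in range(steps):
        traj[t + 1] = transition(net, traj[t])
    return traj


def successor_map(net: BooleanNetwork):
    """Memoized integer-state successor function for repeated walks."""
    prepared = _node_tables(net)
    n = net.n
    cache: dict[int, int] = {}

    def step(code: int) -> int:
        nxt = cache.get(code)
        if nxt is None:
            x = decode_state(code, n)
            y = transition_batch(net, x[None, :], _prepared=prepared)[0]
            nxt = encode_state(y)
            cache[code] = nxt
        return nxt

    return step


def find_attractor(net: BooleanNetwork, x0, max_steps: int | None = None, _step=None) -> Attractor:
    """Walk forward from x0 until a state repeats; return cycle + transient.

    ``max_steps`` defaults to 2^n, which guarantees a revisit.
    """
    if max_steps is None:
        max_steps = 2**net.n
    step = _step if _step is not None else successor_map(net)
    code = encode_state(np.asarray(x0, dtype=np.int8))
    seen: dict[int, int] = {code: 0}
    order = [code]
    for t in range(1, max_steps + 1):
        code = step(code)
        if code in seen:
            entry = seen[code]
            return Attractor(states=tuple(order[entry:]), transient=entry)
        seen[code] = t
        order.append(code)
    raise RuntimeError("no revisit within max_steps; increase max_steps")


def sample_network(
    fs: FunctionSet,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BooleanNetwork:
    """Draw one concrete network from a function set, uniformly per gene.

    Every candidate of a gene has equal probability.  If the drawn
    candidate still carries don't-care entries (a template kept under the
    expansion cap), each ? entry is instantiated by an independent fair
    coin, preserving the uniform semantics over completions.
    """
    if rng is None:
        rng = derive_rng(0 if seed is None else seed, NETWORK_SAMPLING)
    chosen: list[BooleanFunction] = []
    for gene, candidates in enumerate(fs.functions):
        if not candidates:
            raise ValueError(f"gene {fs.gene_ids[gene]} has no candidate functions")
        f = candidates[int(rng.integers(len(candidates)))]
        if not f.is_fully_defined:
            table = np.asarray(f.table, dtype=np.int8)
            undef = np.flatnonzero(table == DONT_CARE)
            table[undef] = rng.integers(0, 2, size=undef.size)
            f = BooleanFunction(f.inputs, tuple(int(x) for x in table))
        chosen.append(f)
    return BooleanNetwork(gene_ids=tuple(fs.gene_ids), functions=tuple(chosen))


# ---------------------------------------------------------------------------
# rule files:  `target, expression`  with operators ! & | and parentheses

def function_to_expression(f: BooleanFunction, gene_ids) -> str:
    """Full-support disjunctive normal form of a fully defined function.

    Every minterm names all inputs, so the input set survives a
    round-trip; the all-zero table canonicalizes to the constant ``0``.
    """
    if not f.is_fully_defined:
        raise ValueError("cannot serialize a don't-care template")
    if f.k == 0:
        return str(f.table[0])
    ones = [i for i, v in enumerate(f.table) if v == 1]
    if not ones:
        return "0"
    terms = []
    for pattern in ones:
        lits = []
        for pos, g in enumerate(f.inputs):
            bit = (pattern >> (f.k - 1 - pos)) & 1
            name = gene_ids[g]
            lits.append(name if bit else f"!{name}")
        terms.append("(" + " & ".join(lits) + ")")
    return " | ".join(terms)


_TOKEN = re.compile(r"\s*(\(|\)|!|&|\||[A-Za-z0-9_.\-]+)")


class _ExprParser:
    """Recursive-descent parser for ! & | expressions over gene names."""

    def __init__(self, text: str):
        self.tokens = _TOKEN.findall(text)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self):
        node = self.parse_or()
        if self.peek() is not None:
            raise ValueError(f"trailing tokens in expression: {self.tokens[self.pos:]}")
        return node

    def parse_or(self):
        node = self.parse_and()
        while self.peek() == "|":
            self.next()
            node = ("or", node, self.parse_and())
        return node

    def parse_and(self):
        node = self.parse_not()
        while self.peek() == "&":
            self.next()
            node = ("and", node, self.parse_not())
        return node

    def parse_not(self):
        tok = self.peek()
        if tok == "!":
            self.next()
            return ("not", self.parse_not())
        if tok == "(":
            self.next()
            node = self.parse_or()
            if self.next() != ")":
                raise ValueError("unbalanced parentheses")
            return node
        if tok in ("0", "1"):
            self.next()
            return ("const", int(tok))
        if tok is None or tok in (")", "&", "|"):
            raise ValueError(f"unexpected token {tok!r}")
        self.next()
        return ("var", tok)


def _expr_vars(node, acc: list[str]) -> None:
    op = node[0]
    if op == "var":
        if node[1] not in acc:
            acc.append(node[1])
    elif op == "not":
        _expr_vars(node[1], acc)
    elif op in ("and", "or"):
        _expr_vars(node[1], acc)
        _expr_vars(node[2], acc)


def _expr_eval(node, env: dict[str, int]) -> int:
    op = node[0]
    if op == "const":
        return node[1]
    if op == "var":
        return env[node[1]]
    if op == "not":
        return 1 - _expr_eval(node[1], env)
    if op == "and":
        return _expr_eval(node[1], env) & _expr_eval(node[2], env)
    return _expr_eval(node[1], env) | _expr_eval(node[2], env)


def expression_to_function(expr: str, gene_index: dict[str, int]) -> BooleanFunction:
    """Parse an expression into a truth table over its variables.

    Input order is the order of first appearance in the expression; the
    first input is the most significant truth-table bit.
    """
    tree = _ExprParser(expr).parse()
    names: list[str] = []
    _expr_vars(tree, names)
    for name in names:
        if name not in gene_index:
            raise ValueError(f"unknown gene {name!r} in rule expression")
    k = len(names)
    table = []
    for pattern in range(2**k):
        env = {name: (pattern >> (k - 1 - pos)) & 1 for pos, name in enumerate(names)}
        table.append(_expr_eval(tree, env))
    return BooleanFunction(tuple(gene_index[nm] for nm in names), tuple(table))


def write_rules(path, gene_ids, functions_per_gene) -> None:
    """Write a rule file: header then one `target, expression` line per candidate."""
    gene_ids = list(gene_ids)
    with open(path, "w") as fh:
        fh.write("targets, factors\n")
        for gene, funcs in zip(gene_ids, functions_per_gene):
            for f in funcs:
                fh.write(f"{gene}, {function_to_expression(f, gene_ids)}\n")


def read_rules(path) -> tuple[list[str], dict[str, list[BooleanFunction]]]:
    """Read a rule file back into per-target candidate lists.

    Returns the target order of first appearance and a mapping
    target -> candidate functions.  Gene indices refer to that order.
    """
    lines = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.lower().startswith("targets"):
                continue
            target, expr = line.split(",", 1)
            lines.append((target.strip(), expr.strip()))
    order: list[str] = []
    for target, _ in lines:
        if target not in order:
            order.append(target)
    gene_index = {g: i for i, g in enumerate(order)}
    rules: dict[str, list[BooleanFunction]] = {g: [] for g in order}
    for target, expr in lines:
        rules[target].append(expression_to_function(expr, gene_index))
    return order, rules


def network_to_rules(net: BooleanNetwork, path) -> None:
    write_rules(path, net.gene_ids, [[f] for f in net.functions])


def rules_to_network(path) -> BooleanNetwork:
    order, rules = read_rules(path)
    funcs = []
    for g in order:
        if len(rules[g]) != 1:
            raise ValueError(f"target {g} has {len(rules[g])} rules; expected exactly 1")
        funcs.append(rules[g][0])
    return BooleanNetwork(gene_ids=tuple(order), functions=tuple(funcs))


def rules_to_function_set(path) -> FunctionSet:
    order, rules = read_rules(path)
    return FunctionSet(
        gene_ids=order,
        functions=[rules[g] for g in order],
        errors=[0] * len(order),
    )
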