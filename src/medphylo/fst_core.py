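"""Minimal weighted finite-state transducer engine over the tropical semiring.

Weights are non-negative integers combined by (min, +); ``INF`` marks the
absence of an accepting path and is a first-class value.  The engine
supports exactly what the event model needs: eager composition, inversion,
output projection, n-fold self-composition, shortest distance on an
explicit machine, and a lazy best-first shortest path over a chain of
machines whose composition is never materialized.

No epsilon transitions, no determinization, no generic semiring: the event
machines are epsilon-free by construction and only the tropical semiring is
used.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

INF = float("inf")


@dataclass(frozen=True)
class Transition:
    src: int
    ilabel: object
    olabel: object
    weight: int
    dst: int


@dataclass
class Transducer:
    """T = (Sigma, Q, E, i, F, lambda, rho) with integer tropical weights."""

    n_states: int
    initial: int
    transitions: list[Transition] = field(default_factory=list)
    finals: dict[int, int] = field(default_factory=dict)  # state -> final weight rho
    initial_weight: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.initial < self.n_states):
            raise ValueError("initial state out of range")
        for t in self.transitions:
            if not (0 <= t.src < self.n_states and 0 <= t.dst < self.n_states):
                raise ValueError("transition endpoint out of range")
            if t.weight < 0:
                raise ValueError("negative weight")

    def add(self, src: int, ilabel, olabel, weight: int, dst: int) -> None:
        self.transitions.append(Transition(src, ilabel, olabel, weight, dst))

    def arcs_from(self) -> dict[int, list[Transition]]:
        out: dict[int, list[Transition]] = {q: [] for q in range(self.n_states)}
        for t in self.transitions:
            out[t.src].append(t)
        return out

    def dump(self) -> str:
        """One transition per line: src ilabel olabel weight dst."""
        lines = [
            f"{t.src}\t{t.ilabel}\t{t.olabel}\t{t.weight}\t{t.dst}"
            for t in self.transitions
        ]
        lines += [f"final\t{q}\t{w}" for q, w in sorted(self.finals.items())]
        return "\n".join(lines)


@dataclass
class PathResult:
    weight: float  # non-negative integer, or INF if no accepting path
    transitions: list[tuple[object, object, int]]  # (ilabel, olabel, weight)


def linear_acceptor(symbols) -> Transducer:
    """Unweighted acceptor of exactly one string (a linear chain)."""
    n = len(symbols)
    t = Transducer(n_states=n + 1, initial=0, finals={n: 0})
    for i, s in enumerate(symbols):
        t.add(i, s, s, 0, i + 1)
    return t


def identity_transducer(alphabet) -> Transducer:
    t = Transducer(n_states=1, initial=0, finals={0: 0})
    for s in alphabet:
        t.add(0, s, s, 0, 0)
    return t


def invert(t: Transducer) -> Transducer:
    """Swap input and output labels."""
    out = Transducer(t.n_states, t.initial, finals=dict(t.finals),
                     initial_weight=t.initial_weight)
    for tr in t.transitions:
        out.add(tr.src, tr.olabel, tr.ilabel, tr.weight, tr.dst)
    return out


def project_output(t: Transducer) -> Transducer:
    """Copy output labels onto both labels, preserving weights."""
    out = Transducer(t.n_states, t.initial, finals=dict(t.finals),
                     initial_weight=t.initial_weight)
    for tr in t.transitions:
        out.add(tr.src, tr.olabel, tr.olabel, tr.weight, tr.dst)
    return out


def compose(t1: Transducer, t2: Transducer) -> Transducer:
    """Eager epsilon-free composition; states are reachable pairs."""
    arcs1, arcs2 = t1.arcs_from(), t2.arcs_from()
    start = (t1.initial, t2.initial)
    index = {start: 0}
    order = [start]
    out = Transducer(n_states=1, initial=0,
                     initial_weight=t1.initial_weight + t2.initial_weight)
    stack = [start]
    while stack:
        q1, q2 = pair = stack.pop()
        src = index[pair]
        by_out: dict[object, list[Transition]] = {}
        for a in arcs1[q1]:
            by_out.setdefault(a.olabel, []).append(a)
        for b in arcs2[q2]:
            for a in by_out.get(b.ilabel, ()):
                nxt = (a.dst, b.dst)
                if nxt not in index:
                    index[nxt] = len(order)
                    order.append(nxt)
                    out.n_states += 1
                    stack.append(nxt)
                out.add(src, a.ilabel, b.olabel, a.weight + b.weight, index[nxt])
    for pair, idx in index.items():
        q1, q2 = pair
        if q1 in t1.finals and q2 in t2.finals:
            out.finals[idx] = t1.finals[q1] + t2.finals[q2]
    return out


def self_compose(t: Transducer, n: int) -> Transducer:
    """Compose ``t`` with itself ``n`` times (n >= 1)."""
    if n < 1:
        raise ValueError("self_compose requires n >= 1")
    out = t
    for _ in range(n - 1):
        out = compose(out, t)
    return out


def shortest_distance(machine_or_chain, x=None, y=None) -> float:
    """Tropical weight of ``x o chain o y`` (or of an explicit machine).

    With a single explicit machine and no sequences, returns the minimum
    weight of any accepting path.  With sequences ``x`` and ``y`` (iterables
    of symbols), they are wrapped as linear acceptors and composed eagerly
    around the chain.
    """
    if isinstance(machine_or_chain, Transducer):
        chain = [machine_or_chain]
    else:
        chain = list(machine_or_chain)
    if x is not None:
        chain = [linear_acceptor(list(x))] + chain
    if y is not None:
        chain = chain + [linear_acceptor(list(y))]
    machine = chain[0]
    for nxt in chain[1:]:
        machine = compose(machine, nxt)
    return _dijkstra_explicit(machine)


def _dijkstra_explicit(t: Transducer) -> float:
    arcs = t.arcs_from()
    dist = {t.initial: t.initial_weight}
    heap = [(t.initial_weight, t.initial)]
    best = INF
    while heap:
        d, q = heapq.heappop(heap)
        if d > dist.get(q, INF):
            continue
        if q in t.finals:
            best = min(best, d + t.finals[q])
        for a in arcs[q]:
            nd = d + a.weight
            if nd < dist.get(a.dst, INF):
                dist[a.dst] = nd
                heapq.heappush(heap, (nd, a.dst))
    return best


def lazy_shortest_path(chain, x, y) -> PathResult:
    """Best-first search over the implicit composition of a machine chain.

    The product automaton of ``x o chain[0] o ... o chain[-1] o y`` is
    expanded only along visited states (all weights are non-negative, so
    Dijkstra-style expansion is admissible).  Ties are broken by insertion
    order, which makes the reported path deterministic.
    """
    machines = [linear_acceptor(list(x))] + list(chain) + [linear_acceptor(list(y))]
    arcs = [m.arcs_from() for m in machines]
    lam = sum(m.initial_weight for m in machines)
    start = tuple(m.initial for m in machines)

    def successors(state):
        """All one-symbol product moves: machine k reads what k-1 emitted."""
        results = []
        for a0 in arcs[0][state[0]]:
            # (input symbol, output symbol) of the overall transduction
            def extend(k, prev, dsts, weight, first=a0):
                if k == len(machines):
                    results.append((tuple(dsts), weight, (first.ilabel, prev)))
                    return
                for a in arcs[k][state[k]]:
                    if a.ilabel == prev:
                        extend(k + 1, a.olabel, dsts + [a.dst], weight + a.weight)

            extend(1, a0.olabel, [a0.dst], a0.weight)
        return results

    counter = 0
    heap = [(lam, 0, start, None)]
    seen: dict[tuple, tuple] = {}  # state -> (dist, parent_state, labels, weight)
    best_final = None
    while heap:
        d, _, state, parent = heapq.heappop(heap)
        if state in seen and seen[state][0] <= d:
            continue
        seen[state] = (d, *(parent or (None, None, 0)))
        if all(q in m.finals for q, m in zip(state, machines)):
            rho = sum(m.finals[q] for q, m in zip(state, machines))
            best_final = (state, d + rho)
            break
        for nxt, w, labels in successors(state):
            nd = d + w
            if nxt not in seen or seen[nxt][0] > nd:
                counter += 1
                heapq.heappush(heap, (nd, counter, nxt, (state, labels, w)))
    if best_final is None:
        return PathResult(INF, [])
    state, total = best_final
    # reconstruct the path
    path = []
    while state is not None:
        d, parent, labels, w = seen[state]
        if labels is not None:
            path.append((labels[0], labels[1], w))
        state = parent
    path.reverse()
    return PathResult(total, path)
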