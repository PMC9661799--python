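"""Independent brute-force oracles for the MED tests.

These deliberately share no code with the production distance kernels:
they enumerate phase-ordered event sequences directly on small profiles
(uniform-cost search over (phase, genome-state) pairs), so they are slow
but transparently correct for tiny inputs.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np

from medphylo.genome_model import CopyNumberProfile, GenomeLayout, profile_units

# phases in the canonical order
LOH, WGD, LOSS, GAIN = 0, 1, 2, 3


def _units_key(units):
    return tuple(tuple(int(v) for v in u) for u in units)


def _runs(unit, lo_value, delta, cap):
    """All results of applying one run event to one unit.

    A run covers a contiguous span, changes every value >= lo_value by
    delta (capped), skips zeros, and must change at least one position.
    """
    n = len(unit)
    seen = set()
    for a in range(n):
        for b in range(a, n):
            new = list(unit)
            changed = False
            ok = True
            for i in range(a, b + 1):
                v = new[i]
                if v == 0:
                    continue
                if v < lo_value or not (0 <= v + delta <= cap):
                    ok = False
                    break
                new[i] = v + delta
                changed = True
            if ok and changed:
                key = tuple(new)
                if key not in seen:
                    seen.add(key)
                    yield key


def _apply_wgd(units, cap, double):
    out = []
    for u in units:
        nu = []
        for v in u:
            if v == 0:
                nu.append(0)
            else:
                nv = 2 * v if double else v + 1
                if nv > cap:
                    return None
                nu.append(nv)
        out.append(tuple(nu))
    return tuple(out)


def oracle_med_asymmetric(
    x: CopyNumberProfile,
    y: CopyNumberProfile,
    layout: GenomeLayout,
    cap: int = 3,
    wgd: bool = True,
    wgd_double: bool = False,
    max_cost: int = 30,
) -> float:
    """Phase-ordered BFS: min #events transforming x into y, or inf.

    States are (phase, genome); moves are single events within the current
    phase (cost 1) or advancing to the next phase (cost 0).
    """
    xu = _units_key(profile_units(x, layout))
    yu = _units_key(profile_units(y, layout))
    start = (LOH, xu)
    dist = {start: 0}
    heap = [(0, 0, start)]
    tick = 0
    while heap:
        d, _, (phase, units) = heapq.heappop(heap)
        if d > dist.get((phase, units), max_cost + 1):
            continue
        if phase == GAIN and units == yu:
            return d
        if d >= max_cost:
            continue
        moves = []
        if phase in (LOH, LOSS):
            lo = 1 if phase == LOH else 2
            for ui, u in enumerate(units):
                for nu in _runs(u, lo, -1, cap):
                    moves.append((1, (phase, units[:ui] + (nu,) + units[ui + 1:])))
        elif phase == GAIN:
            for ui, u in enumerate(units):
                for nu in _runs(u, 1, +1, cap):
                    moves.append((1, (phase, units[:ui] + (nu,) + units[ui + 1:])))
        if phase == WGD and wgd:
            doubled = _apply_wgd(units, cap, wgd_double)
            if doubled is not None:
                moves.append((1, (WGD, doubled)))
        if phase < GAIN:
            nxt = phase + 1
            if nxt == WGD and not wgd:
                nxt = LOSS
            moves.append((0, (nxt, units)))
        for w, state in moves:
            nd = d + w
            if nd < dist.get(state, max_cost + 1):
                dist[state] = nd
                tick += 1
                heapq.heappush(heap, (nd, tick, state))
    return float("inf")


def oracle_med_symmetric(
    x: CopyNumberProfile,
    y: CopyNumberProfile,
    layout: GenomeLayout,
    cap: int = 3,
    wgd: bool = True,
    wgd_double: bool = False,
) -> tuple[float, CopyNumberProfile]:
    """Brute force over every ancestor profile with values <= cap."""
    n = layout.n_segments
    haploid = x.haploid
    width = n if haploid else 2 * n
    best = float("inf")
    best_anc = None
    for values in itertools.product(range(cap + 1), repeat=width):
        if haploid:
            anc = CopyNumberProfile("z", np.array(values))
        else:
            anc = CopyNumberProfile("z", np.array(values[:n]), np.array(values[n:]))
        d = oracle_med_asymmetric(anc, x, layout, cap, wgd, wgd_double, max_cost=int(best) if best != float("inf") else 30)
        if d >= best:
            continue
        d += oracle_med_asymmetric(anc, y, layout, cap, wgd, wgd_double, max_cost=int(best - d) if best != float("inf") else 30)
        if d < best:
            best = d
            best_anc = anc
    return best, best_anc
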