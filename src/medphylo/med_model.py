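"""The minimum-event distance (MED) model.

Four evolutionary event classes act on encoded copy-number genomes, in a
fixed phase order that makes the distance well defined:

1. LOH-phase losses: -1 runs that may drive segments to zero (irreversible,
   since zero-copy segments cannot be regained);
2. whole-genome doublings (WGD): one event changes every non-zero segment
   of both haplotypes, ignoring chromosome boundaries;
3. segmental losses: -1 runs that keep every affected segment >= 1;
4. segmental gains: +1 runs on non-zero segments.

Runs are contiguous within one (haplotype, chromosome) unit, pass over
zero-copy segments at no cost ("ignored"), and terminate at the chromosome
separator.  Each one-step machine is self-composed a fixed number of times
(``|Sigma| - 1`` for LOH, ``|Sigma| - 2`` for the rest) so that the full
copy-number range is reachable, and the asymmetric machine is the phase
chain ``T_LOH o T_WGD o T_L o T_G``.  The symmetric distance between two
profiles is the minimum over common ancestors of the summed asymmetric
distances, i.e. the kernel ``x o T^-1 o T o y``.

Distances are exact integers (infinite when a zero-copy segment would have
to be regained); the production path evaluates the lazy composition as a
per-unit dynamic program over phase-machine run depths (see ``_dpcore``),
which is equivalence-tested against the explicit transducer engine in
``fst_core`` and against a brute-force oracle.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from . import _dpcore, fst_core
from .genome_model import (
    SEP,
    Cohort,
    CopyNumberProfile,
    GenomeLayout,
    profile_units,
    unit_labels,
)

INF = math.inf


@dataclass(frozen=True)
class EventModelConfig:
    """Tunable parameters of the event model.

    cap: maximum representable copy number (alphabet is {0..cap, X}).
    wgd_enabled: whether the WGD phase is part of the chain.
    max_wgd: composition count of the WGD phase (defaults to |Sigma| - 2).
    loh_steps / seg_steps: self-composition counts of the LOH and
        segmental phases (defaults |Sigma| - 1 and |Sigma| - 2).
    wgd_mode: "increment" applies +1 to every non-zero segment per WGD;
        "double" doubles every non-zero segment per WGD.
    """

    cap: int = 8
    wgd_enabled: bool = True
    max_wgd: int | None = None
    loh_steps: int | None = None
    seg_steps: int | None = None
    wgd_mode: str = "increment"

    def __post_init__(self) -> None:
        if self.cap < 1:
            raise ValueError("cap must be >= 1")
        if self.wgd_mode not in ("increment", "double"):
            raise ValueError("wgd_mode must be 'increment' or 'double'")
        n_sigma = self.cap + 2  # copy numbers 0..cap plus the separator X
        object.__setattr__(self, "loh_steps", self.loh_steps or n_sigma - 1)
        object.__setattr__(self, "seg_steps", self.seg_steps or n_sigma - 2)
        if self.max_wgd is None:
            object.__setattr__(self, "max_wgd", n_sigma - 2 if self.wgd_enabled else 0)
        if self.loh_steps < self.cap:
            raise ValueError("loh_steps must be >= cap")
        if self.seg_steps < self.cap - 1:
            raise ValueError("seg_steps must be >= cap - 1")


@dataclass(frozen=True)
class EventRecord:
    """One inferred evolutionary event.

    Non-WGD events lie within one chromosome of one haplotype and change
    the covered non-zero segments by ``delta`` = +/-1; a WGD changes every
    non-zero segment of the genome (haplotype "both", chromosome None).
    Segment indices are 0-based within the chromosome, end inclusive.
    """

    kind: str  # loh_loss | loss | gain | wgd
    haplotype: str  # A | B | both
    chromosome: str | None
    start_segment: int
    end_segment: int
    delta: int


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.matrix < 0).any():
            raise ValueError("distances must be non-negative")

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="sample_id"
        )


class EventModel:
    """Event transducers plus the fast distance kernels and their caches."""

    def __init__(self, config: EventModelConfig):
        self.config = config
        cap = config.cap
        self.alphabet = list(range(cap + 1)) + [SEP]
        self.t1_loh = _one_step_loh(cap)
        self.t1_loss = _one_step_loss(cap)
        self.t1_gain = _one_step_gain(cap)
        self.t1_wgd = _one_step_wgd(cap, config.wgd_mode)
        self._asym_cache: dict = {}
        self._sym_cache: dict = {}

    # -- explicit engine route (small inputs; the equivalence oracle) -------

    def chain(self, wgd: bool | None = None, max_wgd: int | None = None) -> list:
        """The phase chain as a list of one-step machines for the lazy engine."""
        cfg = self.config
        use_wgd = cfg.wgd_enabled if wgd is None else wgd
        n_wgd = (cfg.max_wgd if max_wgd is None else max_wgd) if use_wgd else 0
        machines = [self.t1_loh] * cfg.loh_steps
        machines += [self.t1_wgd] * n_wgd
        machines += [self.t1_loss] * cfg.seg_steps
        machines += [self.t1_gain] * cfg.seg_steps
        return machines

    # -- fast production route ---------------------------------------------

    @property
    def _double(self) -> bool:
        return self.config.wgd_mode == "double"

    def jmax_for(self, target: CopyNumberProfile) -> int:
        """Largest WGD count that can be part of an optimal explanation."""
        if not self.config.wgd_enabled:
            return 0
        cap = self.config.cap
        if self._double:
            return min(self.config.max_wgd, int(math.log2(cap)))
        return min(self.config.max_wgd, cap - 1, max(0, target.max_value() - 1))

    def unit_cost_asym(self, x_unit: np.ndarray, y_unit: np.ndarray, j: int) -> int:
        key = (x_unit.tobytes(), y_unit.tobytes(), j)
        hit = self._asym_cache.get(key)
        if hit is not None:
            return hit
        cfg = self.config
        dims = _dpcore.asym_dims(
            x_unit, y_unit, j, cfg.cap, cfg.loh_steps, cfg.seg_steps, self._double
        )
        cost = int(
            _dpcore.asym_cost(x_unit, y_unit, j, cfg.cap, *dims, self._double)
        )
        self._asym_cache[key] = cost
        return cost

    def unit_cost_sym(
        self, x_unit: np.ndarray, y_unit: np.ndarray, j1: int, j2: int
    ) -> int:
        key = (x_unit.tobytes(), y_unit.tobytes(), j1, j2)
        hit = self._sym_cache.get(key)
        if hit is not None:
            return hit
        cfg = self.config
        dims = _dpcore.sym_dims(
            x_unit, y_unit, j1, j2, cfg.cap, cfg.loh_steps, cfg.seg_steps, self._double
        )
        cost = int(
            _dpcore.sym_cost(x_unit, y_unit, j1, j2, cfg.cap, *dims, self._double)
        )
        self._sym_cache[key] = cost
        return cost


def build_event_model(config: EventModelConfig | None = None, **kwargs) -> EventModel:
    """Build the event model (one-step machines, phase chain, kernels)."""
    if config is None:
        config = EventModelConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config or keyword arguments, not both")
    return EventModel(config)


# ---------------------------------------------------------------------------
# one-step machines (explicit transducers over {0..cap, X})
# ---------------------------------------------------------------------------

_IDLE, _RUN = 0, 1


def _segmental_one_step(cap: int, lo: int, delta: int) -> fst_core.Transducer:
    """One-step run machine changing values in [lo..] by delta (+/-1).

    State 0 (idle) passes symbols unchanged; opening a run costs 1; a run
    must change every covered non-zero symbol, passes zeros for free, and
    closes (for free) on any unchanged symbol, including the separator.
    """
    t = fst_core.Transducer(n_states=2, initial=_IDLE, finals={_IDLE: 0, _RUN: 0})
    for k in range(cap + 1):
        t.add(_IDLE, k, k, 0, _IDLE)
        t.add(_RUN, k, k, 0, _IDLE)
    t.add(_IDLE, SEP, SEP, 0, _IDLE)
    t.add(_RUN, SEP, SEP, 0, _IDLE)
    for k in range(lo, cap + 1):
        if 0 <= k + delta <= cap:
            t.add(_IDLE, k, k + delta, 1, _RUN)
            t.add(_RUN, k, k + delta, 0, _RUN)
    t.add(_RUN, 0, 0, 0, _RUN)  # zero-copy segments are skipped inside a run
    return t


def _one_step_loh(cap: int) -> fst_core.Transducer:
    return _segmental_one_step(cap, lo=1, delta=-1)


def _one_step_loss(cap: int) -> fst_core.Transducer:
    return _segmental_one_step(cap, lo=2, delta=-1)


def _one_step_gain(cap: int) -> fst_core.Transducer:
    return _segmental_one_step(cap, lo=1, delta=+1)


def _one_step_wgd(cap: int, mode: str) -> fst_core.Transducer:
    """One WGD or nothing: +1 (or x2) on every non-zero symbol, X unchanged."""
    START, ID, WGD = 2, 0, 1
    t = fst_core.Transducer(n_states=3, initial=START, finals={START: 0, ID: 0, WGD: 0})

    def wgd_image(k: int) -> int | None:
        if k == 0:
            return 0
        img = 2 * k if mode == "double" else k + 1
        return img if img <= cap else None

    for src, dst, w in ((START, ID, 0), (ID, ID, 0)):
        for k in range(cap + 1):
            t.add(src, k, k, w, dst)
        t.add(src, SEP, SEP, w, dst)
    for src, dst, w in ((START, WGD, 1), (WGD, WGD, 0)):
        for k in range(cap + 1):
            img = wgd_image(k)
            if img is not None:
                t.add(src, k, img, w, dst)
        t.add(src, SEP, SEP, w, dst)  # WGD does not terminate at X
    return t


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def _check_layout(x: CopyNumberProfile, y: CopyNumberProfile) -> None:
    if x.haploid != y.haploid:
        raise ValueError("cannot mix haploid and diploid profiles")
    if x.hapA.shape != y.hapA.shape:
        raise ValueError("profiles are on different layouts")


def med_wgd_curve(
    x: CopyNumberProfile, y: CopyNumberProfile, model: EventModel, layout: GenomeLayout
) -> list[float]:
    """MED(x -> y) allowing at most n WGDs, for n = 0..jmax (cumulative min).

    Entry 0 is the WGD-free MED; the last entry equals the unbounded
    MED-WGD.  Infinite distances are represented as ``math.inf``.
    """
    _check_layout(x, y)
    xu = profile_units(x, layout)
    yu = profile_units(y, layout)
    jmax = model.jmax_for(y)
    totals = []
    for j in range(jmax + 1):
        tot = j
        for a, b in zip(xu, yu):
            c = model.unit_cost_asym(a, b, j)
            if c >= _dpcore.INF:
                tot = INF
                break
            tot += c
        totals.append(tot)
    curve = []
    best = INF
    for t in totals:
        best = min(best, t)
        curve.append(best)
    return curve


def med_asymmetric(
    x: CopyNumberProfile, y: CopyNumberProfile, model: EventModel, layout: GenomeLayout
) -> float:
    """Minimum number of phase-ordered events transforming x into y.

    Returns ``math.inf`` when y has a positive copy number where x has
    zero (gains of zero-copy segments are not permitted).
    """
    curve = med_wgd_curve(x, y, model, layout)
    return curve[-1]


def med_symmetric(
    x: CopyNumberProfile,
    y: CopyNumberProfile,
    model: EventModel,
    layout: GenomeLayout,
    return_ancestor: bool = False,
):
    """Symmetric MED via the best common ancestor (the kernel x o T^-1 o T o y).

    Always finite: an ancestor exists for every pair (LOH can delete
    whatever only one side carries).  With ``return_ancestor`` the
    intermediate symbols of one optimal path are decoded into a witnessing
    ancestor profile.
    """
    _check_layout(x, y)
    xu = profile_units(x, layout)
    yu = profile_units(y, layout)
    j1max = model.jmax_for(x)
    j2max = model.jmax_for(y)
    best = INF
    best_j = (0, 0)
    combos = sorted(
        ((j1, j2) for j1 in range(j1max + 1) for j2 in range(j2max + 1)),
        key=lambda t: (t[0] + t[1], t),
    )
    for j1, j2 in combos:
        tot = j1 + j2
        if tot >= best:
            continue
        for a, b in zip(xu, yu):
            tot += model.unit_cost_sym(a, b, j1, j2)
            if tot >= best:
                break
        if tot < best:
            best = tot
            best_j = (j1, j2)
    if not return_ancestor:
        return best
    ancestor = _sym_ancestor(x, y, model, layout, *best_j)
    return best, ancestor


def _sym_ancestor(x, y, model, layout, j1, j2) -> CopyNumberProfile:
    """Decode a witnessing ancestor from one optimal symmetric path."""
    cfg = model.config
    xu = profile_units(x, layout)
    yu = profile_units(y, layout)
    anc_units = []
    for a, b in zip(xu, yu):
        zmax, *dims = _dpcore.sym_dims(
            a, b, j1, j2, cfg.cap, cfg.loh_steps, cfg.seg_steps, model._double
        )
        K, L1, H1, L2, H2 = dims
        tables = _dpcore.sym_tables(
            a, b, j1, j2, cfg.cap, zmax, K, L1, H1, L2, H2, model._double
        )
        states = _trace(tables, (K, L1, H1, K, L2, H2))
        z_unit = np.empty(len(a), dtype=np.int64)
        for i, (k1, l1, h1, k2, l2, h2) in enumerate(states):
            for z in range(zmax + 1):
                if _feas_py(z, k1, l1, h1, int(a[i]), j1, cfg.cap, model._double) and _feas_py(
                    z, k2, l2, h2, int(b[i]), j2, cfg.cap, model._double
                ):
                    z_unit[i] = z
                    break
            else:  # pragma: no cover - states come from a feasible path
                raise AssertionError("no feasible ancestor value on optimal path")
        anc_units.append(z_unit)
    return _profile_from_units(anc_units, layout, x.haploid, "ancestor")


def _profile_from_units(units, layout, haploid, sample_id) -> CopyNumberProfile:
    k = len(layout.chromosomes)
    hapA = np.concatenate(units[:k])
    if haploid:
        return CopyNumberProfile(sample_id, hapA)
    return CopyNumberProfile(sample_id, hapA, np.concatenate(units[k:]))


def _feas_py(z, k, l, h, c, j, cap, double) -> bool:
    u = max(0, z - k)
    if u > 0:
        v = (u << j) if (double and j) else (u + j if j else u)
        if v > cap:
            return False
        m = v - l
        return m >= 1 and m == c - h
    return c == 0


def _trace(tables: np.ndarray, dims: tuple[int, ...]) -> list[tuple[int, ...]]:
    """Backtrace one optimal depth-state sequence through the DP layers.

    Ties are broken toward the smallest flat state index (smallest depths
    first), which makes event extraction deterministic.
    """
    n = tables.shape[0] - 1
    flat = tables[n]
    s = int(np.argmin(flat))
    if flat[s] >= _dpcore.INF:
        raise ValueError("no accepting path (infinite distance)")
    states = []
    for i in range(n, 0, -1):
        target = np.unravel_index(s, dims)
        states.append(tuple(int(v) for v in target))
        cost = tables[i - 1].reshape(dims).astype(np.float64)
        for ax, (D, t) in enumerate(zip(dims, target)):
            shape = [1] * len(dims)
            shape[ax] = D
            cost = cost + np.maximum(0, t - np.arange(D)).reshape(shape)
        s = int(np.argmin(cost.reshape(-1)))
    states.reverse()
    return states


# ---------------------------------------------------------------------------
# event extraction and replay
# ---------------------------------------------------------------------------


def _runs_from_depths(depths: list[int], active: list[bool]) -> list[tuple[int, int, int]]:
    """Decompose a pending-depth profile into (level, start, end) runs.

    A level-t run covers the maximal stretch with depth >= t; endpoints are
    trimmed to active (non-skipped) positions, since runs cannot open or
    close meaningfully on zero-copy segments.
    """
    runs = []
    top = max(depths, default=0)
    for level in range(1, top + 1):
        i, n = 0, len(depths)
        while i < n:
            if depths[i] >= level:
                jx = i
                while jx + 1 < n and depths[jx + 1] >= level:
                    jx += 1
                lo, hi = i, jx
                while lo <= hi and not active[lo]:
                    lo += 1
                while hi >= lo and not active[hi]:
                    hi -= 1
                if lo <= hi:
                    runs.append((level, lo, hi))
                i = jx + 1
            else:
                i += 1
    return runs


def extract_events(
    x: CopyNumberProfile, y: CopyNumberProfile, model: EventModel, layout: GenomeLayout
) -> list[EventRecord]:
    """Events of one optimal phase-ordered path from x to y.

    The number of records equals ``med_asymmetric(x, y)``; replaying them
    in phase order maps x to y exactly.
    """
    _check_layout(x, y)
    curve = med_wgd_curve(x, y, model, layout)
    if math.isinf(curve[-1]):
        xu = profile_units(x, layout)
        yu = profile_units(y, layout)
        bad = [
            (lab, [int(i) for i in np.flatnonzero((a == 0) & (b > 0))])
            for lab, a, b in zip(unit_labels(layout, x.haploid), xu, yu)
            if ((a == 0) & (b > 0)).any()
        ]
        raise ValueError(
            f"infinite distance: zero-copy segments would need regaining at {bad}"
        )
    j = int(np.argmin([c if not math.isinf(c) else _dpcore.INF for c in curve]))
    cfg = model.config
    xu = profile_units(x, layout)
    yu = profile_units(y, layout)
    labels = unit_labels(layout, x.haploid)
    loh_events, loss_events, gain_events = [], [], []
    for (hap, chrom), a, b in zip(labels, xu, yu):
        dims = _dpcore.asym_dims(
            a, b, j, cfg.cap, cfg.loh_steps, cfg.seg_steps, model._double
        )
        tables = _dpcore.asym_tables(a, b, j, cfg.cap, *dims, model._double)
        states = _trace(tables, dims)
        ks = [s[0] for s in states]
        ls = [s[1] for s in states]
        hs = [s[2] for s in states]
        u = [max(0, int(ai) - k) for ai, k in zip(a, ks)]
        v = [_wgd_py(ui, j, model._double) for ui in u]
        for level, lo, hi in _runs_from_depths(ks, [ai > 0 for ai in a]):
            loh_events.append(EventRecord("loh_loss", hap, chrom, lo, hi, -1))
        for level, lo, hi in _runs_from_depths(ls, [vi > 0 for vi in v]):
            loss_events.append(EventRecord("loss", hap, chrom, lo, hi, -1))
        for level, lo, hi in _runs_from_depths(hs, [bi > 0 for bi in b]):
            gain_events.append(EventRecord("gain", hap, chrom, lo, hi, +1))
    wgd_events = [
        EventRecord("wgd", "both", None, 0, layout.n_segments - 1, +1) for _ in range(j)
    ]
    events = [*loh_events, *wgd_events, *loss_events, *gain_events]
    assert len(events) == curve[-1], "event count must equal the MED"
    return events


def _wgd_py(u: int, j: int, double: bool) -> int:
    if u == 0 or j == 0:
        return u
    return u << j if double else u + j


def replay_events(
    x: CopyNumberProfile,
    events: list[EventRecord],
    model: EventModel,
    layout: GenomeLayout,
) -> CopyNumberProfile:
    """Apply extracted events to x in phase order (LOH, WGD, losses, gains)."""
    units = [u.copy() for u in profile_units(x, layout)]
    labels = unit_labels(layout, x.haploid)
    index = {lab: i for i, lab in enumerate(labels)}
    phase_rank = {"loh_loss": 0, "wgd": 1, "loss": 2, "gain": 3}
    ordered = sorted(enumerate(events), key=lambda t: (phase_rank[t[1].kind], t[0]))
    for _, ev in ordered:
        if ev.kind == "wgd":
            for u in units:
                nz = u > 0
                if model._double:
                    u[nz] *= 2
                else:
                    u[nz] += 1
        else:
            u = units[index[(ev.haplotype, ev.chromosome)]]
            seg = slice(ev.start_segment, ev.end_segment + 1)
            vals = u[seg]
            nz = vals > 0
            vals[nz] += ev.delta
            u[seg] = vals
    return _profile_from_units(units, layout, x.haploid, f"{x.sample_id}+events")


# ---------------------------------------------------------------------------
# pairwise distances with p^2 + p scheduling
# ---------------------------------------------------------------------------


def _smallest_prime_with_square_at_least(n: int) -> int:
    def is_prime(q: int) -> bool:
        if q < 2:
            return False
        for d in range(2, int(q**0.5) + 1):
            if q % d == 0:
                return False
        return True

    p = 2
    while p * p < n or not is_prime(p):
        p += 1
    return p


def pair_groups(n: int) -> list[list[int]]:
    """Split n items into p^2 + p groups of size <= p covering each pair once.

    Items are laid out on the p x p grid of the affine plane AG(2, p)
    (p the smallest prime with p^2 >= n); groups are the plane's lines, so
    two distinct items share exactly one group.
    """
    if n < 2:
        return []
    p = _smallest_prime_with_square_at_least(n)
    groups = []
    for slope in range(p):
        for intercept in range(p):
            line = [x * p + ((slope * x + intercept) % p) for x in range(p)]
            groups.append([i for i in line if i < n])
    for row in range(p):
        groups.append([row * p + y for y in range(p) if row * p + y < n])
    return [g for g in groups if len(g) >= 2]


def pairwise_distances(
    cohort: Cohort, model: EventModel, workers: int = 1
) -> DistanceMatrix:
    """Symmetric MED matrix over all cohort profiles plus the diploid.

    Work is split into the p^2 + p pair groups; every unordered pair is
    computed exactly once and the result is independent of worker count.
    """
    profiles = cohort.all_profiles()
    ids = [p.sample_id for p in profiles]
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 profiles")
    mat = np.zeros((n, n), dtype=np.int64)
    groups = pair_groups(n)
    layout = cohort.layout

    def run_group(group: list[int]) -> list[tuple[int, int, int]]:
        out = []
        for a_i in range(len(group)):
            for b_i in range(a_i + 1, len(group)):
                i, jx = group[a_i], group[b_i]
                d = med_symmetric(profiles[i], profiles[jx], model, layout)
                out.append((i, jx, int(d)))
        return out

    if workers <= 1:
        results = [run_group(g) for g in groups]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(run_group, groups))
    for chunk in results:
        for i, jx, d in chunk:
            mat[i, jx] = d
            mat[jx, i] = d
    return DistanceMatrix(ids, mat)
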