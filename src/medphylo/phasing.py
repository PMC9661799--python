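"""Evolutionary phasing of major/minor copy numbers onto haplotypes.

Allele-specific copy-number callers report an unordered (major, minor)
pair per segment.  Evolutionary phasing picks the assignment of those
values to the two parental haplotypes that minimizes the summed
minimum-event distance of both haplotypes from a normal (all-ones)
reference — the minimum-evolution criterion.  The search space of 2^n
assignments is encoded as a linear phasing FST with two mirrored
transitions per segment; composing it with the reference-side MED machine
on both sides reduces phasing to one shortest-path computation, evaluated
here with the same per-chromosome depth dynamic program as the distances.
"""

from __future__ import annotations

import math

import numpy as np

from . import _dpcore, fst_core
from .genome_model import GenomeLayout
from .med_model import EventModel, _feas_py

INF = math.inf


def phasing_fst(major: np.ndarray, minor: np.ndarray) -> fst_core.Transducer:
    """The unweighted linear phasing FST P.

    n segments give n+1 states; between neighboring states there are two
    transitions carrying (major -> minor) and (minor -> major), so each of
    the 2^n accepting paths decodes one haplotype assignment.
    """
    n = len(major)
    t = fst_core.Transducer(n_states=n + 1, initial=0, finals={n: 0})
    for i, (ma, mi) in enumerate(zip(major, minor)):
        t.add(i, int(ma), int(mi), 0, i + 1)
        if int(ma) != int(mi):
            t.add(i, int(mi), int(ma), 0, i + 1)
    return t


def _validate(major: np.ndarray, minor: np.ndarray, layout: GenomeLayout) -> None:
    if major.shape != minor.shape or major.shape[0] != layout.n_segments:
        raise ValueError("major/minor vectors do not match the layout")
    if (minor < 0).any():
        raise ValueError("negative copy numbers")
    if (minor > major).any():
        bad = np.flatnonzero(minor > major)[:5]
        raise ValueError(f"minor > major at segments {bad.tolist()}")


def _jmax(model: EventModel, target_max: int) -> int:
    if not model.config.wgd_enabled:
        return 0
    cap = model.config.cap
    if model._double:
        return min(model.config.max_wgd, int(math.log2(cap)))
    return min(model.config.max_wgd, cap - 1, max(0, target_max - 1))


def evolutionary_phase(
    major: np.ndarray,
    minor: np.ndarray,
    model: EventModel,
    layout: GenomeLayout,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Optimal haplotype assignment and its summed MED from the reference.

    Returns (hapA, hapB, score) with {hapA[i], hapB[i]} == {major[i],
    minor[i]} at every position and score equal to the minimum over all
    2^n assignments of MED(1s -> hapA) + MED(1s -> hapB); each haplotype
    is treated as its own genome (WGD per haplotype).  Ties are broken by
    assigning the major copy number to haplotype A, left to right.
    """
    major = np.asarray(major, dtype=np.int64)
    minor = np.asarray(minor, dtype=np.int64)
    _validate(major, minor, layout)
    cfg = model.config
    slices = list(layout.chrom_slices().values())
    jmax = _jmax(model, int(major.max(initial=0)))

    best = INF
    best_j = (0, 0)
    for jA in range(jmax + 1):
        for jB in range(jmax + 1):
            tot = jA + jB
            for sl in slices:
                tot += _phase_unit_cost(major[sl], minor[sl], jA, jB, model)
                if tot >= best:
                    break
            if tot < best:
                best = tot
                best_j = (jA, jB)
    if math.isinf(best):  # pragma: no cover - assignment always exists
        raise AssertionError("phasing found no finite assignment")

    hapA = np.empty_like(major)
    hapB = np.empty_like(major)
    jA, jB = best_j
    for sl in slices:
        a, b = _phase_unit_trace(major[sl], minor[sl], jA, jB, model)
        hapA[sl] = a
        hapB[sl] = b
    # canonical orientation: the mirror assignment has the same score, so
    # put the major copy number on haplotype A at the first unbalanced
    # position (deterministic tie-break)
    diff = np.flatnonzero(hapA != hapB)
    if diff.size and hapA[diff[0]] < hapB[diff[0]]:
        hapA, hapB = hapB, hapA
    return hapA, hapB, int(best)


def _phase_dims(maj, mnr, jA, jB, model):
    cfg = model.config
    return _dpcore.phase_dims(
        maj, mnr, jA, jB, cfg.cap, cfg.loh_steps, cfg.seg_steps, model._double
    )


def _phase_unit_cost(maj, mnr, jA, jB, model) -> float:
    dims = _phase_dims(maj, mnr, jA, jB, model)
    tables = _dpcore.phase_tables(
        maj, mnr, jA, jB, model.config.cap, *dims, model._double
    )
    best = int(tables[-1].min())
    return INF if best >= _dpcore.INF else best


def _phase_unit_trace(maj, mnr, jA, jB, model):
    """Backtrace the optimal assignment for one chromosome."""
    from .med_model import _trace

    cap = model.config.cap
    K, LA, HA, LB, HB = _phase_dims(maj, mnr, jA, jB, model)
    tables = _dpcore.phase_tables(maj, mnr, jA, jB, cap, K, LA, HA, LB, HB, model._double)
    states = _trace(tables, (K, LA, HA, K, LB, HB))
    hapA = np.empty(len(maj), dtype=np.int64)
    hapB = np.empty(len(maj), dtype=np.int64)
    for i, (kA, lA, hA, kB, lB, hB) in enumerate(states):
        ma, mi = int(maj[i]), int(mnr[i])
        major_on_A = _feas_py(1, kA, lA, hA, ma, jA, cap, model._double) and _feas_py(
            1, kB, lB, hB, mi, jB, cap, model._double
        )
        if major_on_A:
            hapA[i], hapB[i] = ma, mi
        else:
            hapA[i], hapB[i] = mi, ma
    return hapA, hapB
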