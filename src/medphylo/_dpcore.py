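"""Numba kernels for minimum-event distances on encoded chromosome units.

Each n-fold self-composed phase machine (LOH losses, segmental losses,
segmental gains) admits a canonical compact form whose state is the number
of currently open runs ("pending depth"): a run costs 1 when it opens,
extends for free, skips zero-copy positions, must change every non-zero
position it covers, and terminates at the chromosome separator.  The chain
``T_LOH o T_WGD o T_L o T_G`` restricted to one X-free unit is therefore a
shortest path over tuples of pending depths, computed here as a forward
dynamic program:

* per position the transition cost is separable across depth dimensions
  (``max(0, d_new - d_old)`` per dimension), so relaxation is a pair of
  linear scans per dimension;
* a state is then feasible at position i iff some intermediate symbol
  assignment (post-LOH value u, post-loss value m, and for the symmetric
  kernel an ancestor value z) is consistent with the observed symbols.

Paying for a depth increase on a zero-copy (skipped) position is allowed by
the relaxation; it is equivalent to paying at the next non-skipped position
and never changes the minimum (runs cannot open on zero-copy segments, but
deferring the opening costs the same).

The WGD count j (and j1/j2 for the symmetric kernel) is fixed per call;
callers minimize over j and add it, since WGD events span all units.
``wgd_double`` selects the WGD step semantics: +1 per WGD on every non-zero
segment (default model) or doubling per WGD.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = np.int64(1) << 60


@njit(cache=True, nogil=True, inline="always")
def _wgd_apply(u, j, wgd_double):
    if j == 0 or u == 0:
        return u
    if wgd_double:
        return u << j
    return u + j


@njit(cache=True, nogil=True, inline="always")
def _feas_branch(z, k, l, h, c, j, cap, wgd_double):
    """Can ancestor value z reach child value c through depths (k, l, h)?

    k: LOH-phase pending depth, l: loss-phase, h: gain-phase.  The
    post-LOH value is u = max(0, z - k); the post-loss value m must satisfy
    m = (u after WGD) - l = c - h with 1 <= m, unless the segment was
    zeroed (u = 0), in which case c must be 0 and l, h are unconstrained.
    """
    u = z - k
    if u < 0:
        u = 0
    if u > 0:
        v = _wgd_apply(u, j, wgd_double)
        if v > cap:
            return False
        m = v - l
        return m >= 1 and m == c - h
    return c == 0


@njit(cache=True, nogil=True)
def _relax_dim(a, D, stride):
    """In-place tropical relaxation along one depth dimension.

    Decreasing a pending depth is free (runs close); increasing it costs 1
    per unit (runs open).
    """
    S = a.shape[0]
    block = D * stride
    for b in range(0, S, block):
        for inner in range(stride):
            base = b + inner
            for k in range(1, D):
                v = a[base + (k - 1) * stride] + 1
                if v < a[base + k * stride]:
                    a[base + k * stride] = v
            for k in range(D - 2, -1, -1):
                v = a[base + (k + 1) * stride]
                if v < a[base + k * stride]:
                    a[base + k * stride] = v


# ---------------------------------------------------------------------------
# asymmetric MED on one unit, fixed WGD count
# ---------------------------------------------------------------------------


def asym_dims(x, y, j, cap, n_loh, n_seg, wgd_double):
    """Depth-dimension sizes (K, L, H) for the asymmetric kernel."""
    maxx = int(x.max(initial=0))
    maxy = int(y.max(initial=0))
    kmax = min(n_loh, maxx)
    if wgd_double:
        vmax = min(cap, maxx << j)
    else:
        vmax = min(cap, maxx + j)
    lmax = min(n_seg, max(0, vmax - 1))
    hmax = min(n_seg, max(0, maxy - 1))
    return kmax + 1, lmax + 1, hmax + 1


@njit(cache=True, nogil=True)
def asym_cost(x, y, j, cap, K, L, H, wgd_double):
    S = K * L * H
    cur = np.full(S, INF, dtype=np.int64)
    cur[0] = 0
    for i in range(x.shape[0]):
        new = cur.copy()
        _relax_dim(new, K, L * H)
        _relax_dim(new, L, H)
        _relax_dim(new, H, 1)
        xi = x[i]
        yi = y[i]
        idx = 0
        for k in range(K):
            for l in range(L):
                for h in range(H):
                    if not _feas_branch(xi, k, l, h, yi, j, cap, wgd_double):
                        new[idx] = INF
                    idx += 1
        cur = new
    best = INF
    for s in range(S):
        if cur[s] < best:
            best = cur[s]
    return best


@njit(cache=True, nogil=True)
def asym_tables(x, y, j, cap, K, L, H, wgd_double):
    """Like asym_cost but returns all DP layers, for path reconstruction."""
    n = x.shape[0]
    S = K * L * H
    out = np.full((n + 1, S), INF, dtype=np.int64)
    out[0, 0] = 0
    for i in range(n):
        new = out[i].copy()
        _relax_dim(new, K, L * H)
        _relax_dim(new, L, H)
        _relax_dim(new, H, 1)
        xi = x[i]
        yi = y[i]
        idx = 0
        for k in range(K):
            for l in range(L):
                for h in range(H):
                    if not _feas_branch(xi, k, l, h, yi, j, cap, wgd_double):
                        new[idx] = INF
                    idx += 1
        out[i + 1] = new
    return out


# ---------------------------------------------------------------------------
# symmetric (ancestor-kernel) MED on one unit, fixed WGD counts per branch
# ---------------------------------------------------------------------------


def sym_dims(x, y, j1, j2, cap, n_loh, n_seg, wgd_double):
    """Depth-dimension sizes (zmax, K, L1, H1, L2, H2) for the symmetric kernel."""
    maxx = int(x.max(initial=0))
    maxy = int(y.max(initial=0))
    zmax = min(cap, max(maxx, maxy))
    kmax = min(n_loh, zmax)

    def vmax(j):
        if wgd_double:
            return min(cap, zmax << j)
        return min(cap, zmax + j)

    l1 = min(n_seg, max(0, vmax(j1) - 1))
    h1 = min(n_seg, max(0, maxx - 1))
    l2 = min(n_seg, max(0, vmax(j2) - 1))
    h2 = min(n_seg, max(0, maxy - 1))
    return zmax, kmax + 1, l1 + 1, h1 + 1, l2 + 1, h2 + 1


@njit(cache=True, nogil=True)
def _sym_mask(new, xi, yi, j1, j2, cap, zmax, K, L1, H1, L2, H2, wgd_double):
    idx = 0
    for k1 in range(K):
        for l1 in range(L1):
            for h1 in range(H1):
                for k2 in range(K):
                    for l2 in range(L2):
                        for h2 in range(H2):
                            ok = False
                            for z in range(zmax + 1):
                                if _feas_branch(z, k1, l1, h1, xi, j1, cap, wgd_double) and _feas_branch(
                                    z, k2, l2, h2, yi, j2, cap, wgd_double
                                ):
                                    ok = True
                                    break
                            if not ok:
                                new[idx] = INF
                            idx += 1


@njit(cache=True, nogil=True)
def sym_cost(x, y, j1, j2, cap, zmax, K, L1, H1, L2, H2, wgd_double):
    S = K * L1 * H1 * K * L2 * H2
    cur = np.full(S, INF, dtype=np.int64)
    cur[0] = 0
    for i in range(x.shape[0]):
        new = cur.copy()
        _relax_dim(new, K, L1 * H1 * K * L2 * H2)
        _relax_dim(new, L1, H1 * K * L2 * H2)
        _relax_dim(new, H1, K * L2 * H2)
        _relax_dim(new, K, L2 * H2)
        _relax_dim(new, L2, H2)
        _relax_dim(new, H2, 1)
        _sym_mask(new, x[i], y[i], j1, j2, cap, zmax, K, L1, H1, L2, H2, wgd_double)
        cur = new
    best = INF
    for s in range(S):
        if cur[s] < best:
            best = cur[s]
    return best


@njit(cache=True, nogil=True)
def sym_tables(x, y, j1, j2, cap, zmax, K, L1, H1, L2, H2, wgd_double):
    n = x.shape[0]
    S = K * L1 * H1 * K * L2 * H2
    out = np.full((n + 1, S), INF, dtype=np.int64)
    out[0, 0] = 0
    for i in range(n):
        new = out[i].copy()
        _relax_dim(new, K, L1 * H1 * K * L2 * H2)
        _relax_dim(new, L1, H1 * K * L2 * H2)
        _relax_dim(new, H1, K * L2 * H2)
        _relax_dim(new, K, L2 * H2)
        _relax_dim(new, L2, H2)
        _relax_dim(new, H2, 1)
        _sym_mask(new, x[i], y[i], j1, j2, cap, zmax, K, L1, H1, L2, H2, wgd_double)
        out[i + 1] = new
    return out


# ---------------------------------------------------------------------------
# evolutionary phasing on one unit: two haploid branches from an all-ones
# source, with a per-position choice of which haplotype receives the major
# copy number
# ---------------------------------------------------------------------------


def phase_dims(major, minor, jA, jB, cap, n_loh, n_seg, wgd_double):
    maxc = int(major.max(initial=0))

    def vmax(j):
        if wgd_double:
            return min(cap, 1 << j)
        return min(cap, 1 + j)

    lA = min(n_seg, max(0, vmax(jA) - 1))
    lB = min(n_seg, max(0, vmax(jB) - 1))
    hh = min(n_seg, max(0, maxc - 1))
    return 2, lA + 1, hh + 1, lB + 1, hh + 1


@njit(cache=True, nogil=True)
def _phase_mask(new, maj, mnr, jA, jB, cap, K, LA, HA, LB, HB, wgd_double):
    idx = 0
    for kA in range(K):
        for lA in range(LA):
            for hA in range(HA):
                for kB in range(K):
                    for lB in range(LB):
                        for hB in range(HB):
                            ok = (
                                _feas_branch(1, kA, lA, hA, maj, jA, cap, wgd_double)
                                and _feas_branch(1, kB, lB, hB, mnr, jB, cap, wgd_double)
                            ) or (
                                _feas_branch(1, kA, lA, hA, mnr, jA, cap, wgd_double)
                                and _feas_branch(1, kB, lB, hB, maj, jB, cap, wgd_double)
                            )
                            if not ok:
                                new[idx] = INF
                            idx += 1


@njit(cache=True, nogil=True)
def phase_tables(major, minor, jA, jB, cap, K, LA, HA, LB, HB, wgd_double):
    n = major.shape[0]
    S = K * LA * HA * K * LB * HB
    out = np.full((n + 1, S), INF, dtype=np.int64)
    out[0, 0] = 0
    for i in range(n):
        new = out[i].copy()
        _relax_dim(new, K, LA * HA * K * LB * HB)
        _relax_dim(new, LA, HA * K * LB * HB)
        _relax_dim(new, HA, K * LB * HB)
        _relax_dim(new, K, LB * HB)
        _relax_dim(new, LB, HB)
        _relax_dim(new, HB, 1)
        _phase_mask(new, major[i], minor[i], jA, jB, cap, K, LA, HA, LB, HB, wgd_double)
        out[i + 1] = new
    return out
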