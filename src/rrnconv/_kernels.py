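"""Numba kernels for the hot simulation loops.

The Monte-Carlo rate machinery needs millions of simulated
mutation-accumulation lineages (replicates x lineages x candidate rates).
Only columns that are heterologous in the ancestor can ever change under
pure gene conversion — a conversion moves existing per-column alleles
between copies and can never create a new state — so lineages are
simulated on the compressed ancestral heterologous-column matrix.  This
is an exact change of representation, not an approximation.

The greedy minimal-event counter here mirrors
:func:`rrnconv.inference.greedy_event_partition`; the two are
cross-checked in the test-suite, together with an independent
dynamic-programming oracle.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["count_events_by_region", "simulate_batch"]


@njit(cache=True)
def _bisect_left(a, lo, hi, x):
    while lo < hi:
        mid = (lo + hi) // 2
        if a[mid] < x:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def _bisect_right(a, lo, hi, x):
    while lo < hi:
        mid = (lo + hi) // 2
        if a[mid] <= x:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def _match_mask(anc, col, state, recipient):
    mask = 0
    for d in range(anc.shape[0]):
        if d != recipient and anc[d, col] == state:
            mask |= 1 << d
    return mask


@njit(cache=True)
def count_events_by_region(anc, state, col_region, out):
    """Greedy minimal-event count per region, added into ``out``.

    Returns 0 on success, -1 if a changed column matches no other copy
    (impossible under pure conversion; guards corrupted input).
    """
    n_copies, m = anc.shape
    for r in range(n_copies):
        mask = 0
        last = -1
        lastreg = -1
        for c in range(m):
            if state[r, c] == anc[r, c]:
                continue
            mc = _match_mask(anc, c, state[r, c], r)
            if mc == 0:
                return -1
            start_new = True
            if mask != 0 and col_region[c] == lastreg:
                newmask = mask
                for x in range(last + 1, c):
                    newmask &= _match_mask(anc, x, state[r, x], r)
                    if newmask == 0:
                        break
                newmask &= mc
                if newmask != 0:
                    mask = newmask
                    start_new = False
            if start_new:
                out[col_region[c]] += 1
                mask = mc
            last = c
            lastreg = col_region[c]
    return 0


@njit(cache=True)
def simulate_batch(
    anc,
    col_region,
    het_pos,
    region_het_lo,
    region_het_hi,
    region_len,
    region_is_spacer,
    tmpl_region,
    tmpl_min,
    tmpl_max,
    n_events,
    seeds,
    n_lineages,
    size_floor,
):
    """Simulate lineages and count observable events per replicate/region.

    Per lineage ``i``: reseed the stream from ``seeds[i]`` (common random
    numbers across candidate rates), draw ``n_events[i]`` conversions
    (template event with replacement -> size uniform between its min/max
    extents floored at ``size_floor`` -> uniform start inside the region
    -> uniform recipient and distinct donor), apply them sequentially with
    donors contributing their *current* sequence, then add the greedy
    minimal observable event counts to the lineage's replicate row.

    Returns an ``(n_replicates, n_regions)`` int64 matrix, with -1 in
    column 0 of a row on a novel-allele inconsistency (cannot arise from
    pure conversion simulation).
    """
    n_total = n_events.shape[0]
    n_rep = n_total // n_lineages
    n_regions = region_len.shape[0]
    n_tmpl = tmpl_region.shape[0]
    n_copies = anc.shape[0]
    counts = np.zeros((n_rep, n_regions), dtype=np.int64)
    state = np.empty_like(anc)
    for i in range(n_total):
        rep = i // n_lineages
        n_ev = n_events[i]
        if n_ev <= 0:
            continue
        np.random.seed(seeds[i])
        state[:, :] = anc
        for _k in range(n_ev):
            t = np.random.randint(0, n_tmpl)
            rg = tmpl_region[t]
            if region_is_spacer[rg] == 1:
                size = region_len[rg]
                start = 1
            else:
                lo = tmpl_min[t]
                hi = tmpl_max[t]
                if lo < size_floor:
                    lo = size_floor
                if hi < lo:
                    hi = lo
                size = lo + np.random.randint(0, hi - lo + 1)
                if size > region_len[rg]:
                    size = region_len[rg]
                start = 1 + np.random.randint(0, region_len[rg] - size + 1)
            recip = np.random.randint(0, n_copies)
            donor = np.random.randint(0, n_copies - 1)
            if donor >= recip:
                donor += 1
            a = region_het_lo[rg]
            b = region_het_hi[rg]
            clo = _bisect_left(het_pos, a, b, start)
            chi = _bisect_right(het_pos, a, b, start + size - 1)
            for c in range(clo, chi):
                state[recip, c] = state[donor, c]
        status = count_events_by_region(anc, state, col_region, counts[rep])
        if status < 0:
            counts[rep, 0] = -1
    return counts
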