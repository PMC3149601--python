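"""Numba-jitted inner loops for the queue dynamics.

Both the network agent model and the single-user reduction share the same
per-agent mechanics:

* each queue entry carries a composite key ``priority + u`` with
  ``u ~ U[0,1)`` drawn at message creation, so ordering by key is ordering
  by integer priority with uniform random tie-breaking;
* replying selects ``S ~ U{0..q}`` entries without replacement with
  probability proportional to priority, realised as an exponential race
  (smallest ``Exp(1)/priority`` first), which is distributionally identical
  to iterative renormalised sampling;
* delivery merges the sorted queue with the sorted batch of arrivals,
  keeps at most one pending entry per sender (a queue slot is a
  conversation partner awaiting a reply — further messages from the same
  sender while one is pending occupy no extra slot) and then at most the
  ``capacity`` largest keys, counting everything dropped.

Queues are stored as per-agent rows of fixed-width arrays sorted by
descending key.  All randomness flows through numba's global RNG, seeded
once per call, so runs are bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_abm_kernel", "run_single_user_kernel"]


@njit(cache=True)
def _insertion_sort_desc(keys, senders, lo, hi):
    for a in range(lo + 1, hi):
        k = keys[a]
        s = senders[a]
        b = a - 1
        while b >= lo and keys[b] < k:
            keys[b + 1] = keys[b]
            senders[b + 1] = senders[b]
            b -= 1
        keys[b + 1] = k
        senders[b + 1] = s


@njit(cache=True)
def _sort_desc(keys, senders, lo, hi):
    n = hi - lo
    if n <= 64:
        _insertion_sort_desc(keys, senders, lo, hi)
    else:
        order = np.argsort(-keys[lo:hi])
        keys[lo:hi] = keys[lo:hi][order]
        senders[lo:hi] = senders[lo:hi][order]


@njit(cache=True)
def _merge_topk(qkey, qsnd, qlen, i, ink, isnd, ilo, ihi, cap,
                tmpk, tmps, mark, tag):
    """Merge agent i's sorted queue with sorted arrivals.

    Keeps the first (highest-key) entry per sender, then the top ``cap``
    keys.  ``mark``/``tag`` implement O(1) seen-sender checks.  Returns the
    number of dropped entries (duplicates plus overflow).
    """
    a = 0
    b = ilo
    out = 0
    q = qlen[i]
    total = q + (ihi - ilo)
    while out < cap and (a < q or b < ihi):
        take_queue = b >= ihi or (a < q and qkey[i, a] >= ink[b])
        if take_queue:
            key = qkey[i, a]
            snd = qsnd[i, a]
            a += 1
        else:
            key = ink[b]
            snd = isnd[b]
            b += 1
        if mark[snd] != tag:
            mark[snd] = tag
            tmpk[out] = key
            tmps[out] = snd
            out += 1
    for t in range(out):
        qkey[i, t] = tmpk[t]
        qsnd[i, t] = tmps[t]
    qlen[i] = out
    return total - out


@njit(cache=True)
def _reply_select(qkey, qsnd, qlen, i, race, sortbuf):
    """Draw S ~ U{0..q} and mark the S race winners.

    Marks selected entries by negating their race key in ``race``; returns S.
    Selection is priority-proportional without replacement via the
    exponential race on the integer part of the composite key.
    """
    q = qlen[i]
    if q == 0:
        return 0
    s = np.random.randint(0, q + 1)
    if s == 0:
        return 0
    if s == q:
        for idx in range(q):
            race[idx] = -1.0
        return s
    for idx in range(q):
        prio = np.floor(qkey[i, idx])
        race[idx] = np.random.exponential() / prio
        sortbuf[idx] = race[idx]
    sb = sortbuf[:q]
    sb.sort()
    thresh = sb[s - 1]
    marked = 0
    for idx in range(q):
        if race[idx] <= thresh and marked < s:
            race[idx] = -1.0
            marked += 1
    return s


@njit(cache=True)
def _edge_pos(indptr, neighbors, i, j):
    lo = indptr[i]
    hi = indptr[i + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        if neighbors[mid] < j:
            lo = mid + 1
        else:
            hi = mid
    return lo  # caller guarantees j is a neighbour of i


@njit(cache=True)
def run_abm_kernel(seed, indptr, neighbors, deg, cap, p, T):
    """Synchronous queue dynamics on a symmetric substrate.

    Per step: every agent replies to a priority-weighted random subset of its
    queue (incrementing reply weights) and broadcasts to all contacts with
    probability ``p`` (weightless); everything produced in the step is
    delivered at the end of the step, so nothing sent at t is answerable
    before t+1.

    Returns ``(w, st_log, n_broadcast_events, n_discarded)`` where ``w`` is
    the per-directed-edge reply count aligned with ``neighbors``.
    """
    np.random.seed(seed)
    n = len(deg)
    capmax = 1
    for i in range(n):
        if cap[i] > capmax:
            capmax = cap[i]
    qkey = np.zeros((n, capmax))
    qsnd = np.zeros((n, capmax), np.int32)
    qlen = np.zeros(n, np.int32)
    e2 = len(neighbors)
    w = np.zeros(e2, np.int64)
    maxev = 0
    for i in range(n):
        maxev += cap[i]
    maxev += e2 + 8
    ev_rec = np.empty(maxev, np.int32)
    ev_snd = np.empty(maxev, np.int32)
    ev_key = np.empty(maxev, np.float64)
    race = np.empty(capmax)
    sortbuf = np.empty(capmax)
    tmpk = np.empty(capmax)
    tmps = np.empty(capmax, np.int32)
    ink = np.empty(maxev)
    isnd = np.empty(maxev, np.int32)
    counts = np.zeros(n + 1, np.int64)
    pos = np.zeros(n, np.int64)
    order = np.empty(maxev, np.int64)
    st_log = np.zeros(T, np.int64)
    mark = np.full(n, -1, np.int64)
    tag = 0
    n_broadcast = 0
    n_discard = 0

    for t in range(T):
        m = 0
        for i in range(n):
            # reply phase
            s = _reply_select(qkey, qsnd, qlen, i, race, sortbuf)
            if s > 0:
                q = qlen[i]
                keep = 0
                for idx in range(q):
                    if race[idx] < 0.0:
                        j = qsnd[i, idx]
                        w[_edge_pos(indptr, neighbors, i, j)] += 1
                        ev_rec[m] = j
                        ev_snd[m] = i
                        ev_key[m] = deg[i] + np.random.random()
                        m += 1
                    else:
                        qkey[i, keep] = qkey[i, idx]
                        qsnd[i, keep] = qsnd[i, idx]
                        keep += 1
                qlen[i] = keep
                st_log[t] += s
            # broadcast phase (weightless seeding)
            if np.random.random() < p:
                n_broadcast += 1
                for a in range(indptr[i], indptr[i + 1]):
                    ev_rec[m] = neighbors[a]
                    ev_snd[m] = i
                    ev_key[m] = deg[i] + np.random.random()
                    m += 1
        # delivery: group this step's messages by recipient
        for i in range(n + 1):
            counts[i] = 0
        for e in range(m):
            counts[ev_rec[e] + 1] += 1
        for i in range(n):
            counts[i + 1] += counts[i]
            pos[i] = counts[i]
        for e in range(m):
            r = ev_rec[e]
            order[pos[r]] = e
            pos[r] += 1
        for r in range(n):
            lo = counts[r]
            hi = counts[r + 1]
            if lo == hi:
                continue
            for a in range(lo, hi):
                ink[a] = ev_key[order[a]]
                isnd[a] = ev_snd[order[a]]
            _sort_desc(ink, isnd, lo, hi)
            tag += 1
            n_discard += _merge_topk(
                qkey, qsnd, qlen, r, ink, isnd, lo, hi, cap[r],
                tmpk, tmps, mark, tag
            )
    return w, st_log, n_broadcast, n_discard


@njit(cache=True)
def run_single_user_kernel(seed, prios, send_prob, cap, T):
    """Mean-field focal user: partners are independent message sources.

    ``prios`` holds one static integer priority per partner; each partner
    sends one message per step with probability ``send_prob``.  The focal
    user runs the same reply/enqueue mechanics as the network model with
    queue capacity ``cap``.

    Returns ``(w, replies_total, arrivals_total)`` with ``w`` the
    per-partner reply counts.
    """
    np.random.seed(seed)
    m = len(prios)
    qkey = np.zeros((1, cap))
    qsnd = np.zeros((1, cap), np.int32)
    qlen = np.zeros(1, np.int32)
    w = np.zeros(m, np.int64)
    race = np.empty(cap)
    sortbuf = np.empty(cap)
    tmpk = np.empty(cap)
    tmps = np.empty(cap, np.int32)
    ink = np.empty(m + 1)
    isnd = np.empty(m + 1, np.int32)
    mark = np.full(m, -1, np.int64)
    tag = 0
    replies_total = 0
    arrivals_total = 0
    for t in range(T):
        s = _reply_select(qkey, qsnd, qlen, 0, race, sortbuf)
        if s > 0:
            q = qlen[0]
            keep = 0
            for idx in range(q):
                if race[idx] < 0.0:
                    w[qsnd[0, idx]] += 1
                else:
                    qkey[0, keep] = qkey[0, idx]
                    qsnd[0, keep] = qsnd[0, idx]
                    keep += 1
            qlen[0] = keep
            replies_total += s
        n_in = 0
        for j in range(m):
            if np.random.random() < send_prob:
                ink[n_in] = prios[j] + np.random.random()
                isnd[n_in] = j
                n_in += 1
        arrivals_total += n_in
        if n_in > 0:
            _sort_desc(ink, isnd, 0, n_in)
            tag += 1
            _merge_topk(qkey, qsnd, qlen, 0, ink, isnd, 0, n_in, cap,
                        tmpk, tmps, mark, tag)
    return w, replies_total, arrivals_total
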