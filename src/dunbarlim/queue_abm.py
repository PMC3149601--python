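"""Agent-based model of message exchange under bounded priority queues.

Each agent owns a queue holding at most ``q_max_i`` pending messages, a
minimal embodiment of finite attention.  Per time step, synchronously:

1. every agent replies to ``S_t ~ U{0..q_i}`` of its queued messages,
   selected without replacement proportionally to the sender's static total
   degree (popular senders get answered first); each reply increments the
   directed edge weight ``w[i][j]`` and travels back to the original sender;
   independently, with probability ``p`` the agent broadcasts a weightless
   message to all its contacts (the exogenous seeding of activity);
2. everything produced in the step is delivered at the end of the step:
   arrivals merge into the recipient's queue in priority order, with at
   most one pending entry per sender, and entries in excess of capacity
   are discarded (lowest priority first, ties uniform).

A queue slot is thus a *conversation partner awaiting a reply*, not a raw
message counter: while a reply to some contact is pending, further messages
from that contact occupy no extra slot.  This bounds queue occupancy by
``min(degree, capacity)`` and makes capacity bind exactly where the number
of active contacts reaches the number of attention slots: agents with
``k < q_max`` keep conversations with essentially all contacts alive
(weight per contact grows slowly with degree, helped by the priority
advantage of popular agents), while agents with ``k > q_max`` must drop
partners every step and their per-step reply budget ``~q_max/2`` is spread
over ``k`` contacts (weight per contact decays as 1/k).  The resulting
peaked curve of weight-per-contact against degree reproduces the empirical
saturation at a finite number of stable relationships, with the peak
position set — linearly — by the queue capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from . import _kernels
from .social_metrics import BinnedCurve, Binning, bin_curve, find_peak
from .substrate_gen import CapacityAssignment, Substrate, assign_capacities

__all__ = [
    "QueueEntry",
    "AgentState",
    "SimConfig",
    "SimResult",
    "RunTrace",
    "broadcast_phase",
    "reply_phase",
    "enqueue",
    "run_simulation",
    "replica_medians",
    "derive_seed",
]

_GOLDEN = 0x9E3779B1


def derive_seed(master: int, index: int) -> int:
    """Counter-based child seed, kept within 31 bits."""
    return int((master + _GOLDEN * (index + 1)) % (2**31))


@dataclass
class QueueEntry:
    """One pending message: who sent it, at what static priority."""

    sender: int
    priority: int
    arrival_step: int = 0
    key: float = 0.0          # priority + U[0,1) tie-break, set at creation
    msg_id: int = -1          # only tracked by the instrumented engine

    def __post_init__(self) -> None:
        if self.priority < 1:
            raise ValueError("priority must be >= 1")
        if not (self.priority <= self.key < self.priority + 1):
            # key not supplied: draw the tie-break lazily is the caller's job;
            # default to the bare priority (deterministic lowest tie rank).
            if self.key == 0.0:
                self.key = float(self.priority)


@dataclass
class AgentState:
    """Bounded priority queue plus capacity for one agent.

    The queue is kept in non-increasing composite-key order (priority with
    uniform tie-breaks), never longer than ``capacity``.
    """

    capacity: int
    queue: List[QueueEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise ValueError("capacity must be >= 1")

    @property
    def q(self) -> int:
        return len(self.queue)

    def check(self) -> None:
        assert self.q <= self.capacity
        keys = [e.key for e in self.queue]
        assert all(keys[i] >= keys[i + 1] for i in range(len(keys) - 1))


def broadcast_phase(
    substrate: Substrate,
    p: float,
    rng: np.random.Generator,
    step: int = 0,
) -> List[Tuple[int, QueueEntry]]:
    """Weightless seeding: each agent broadcasts to all contacts w.p. ``p``.

    Returns an outbox of ``(recipient, entry)`` pairs; entries carry the
    broadcaster's total degree as priority and contribute nothing to edge
    weights.
    """
    outbox: List[Tuple[int, QueueEntry]] = []
    if p == 0:
        return outbox
    draws = rng.random(substrate.n)
    for i in range(substrate.n):
        if draws[i] < p and substrate.degree[i] > 0:
            prio = int(substrate.degree[i])
            for j in substrate.neighbors_of(i):
                outbox.append(
                    (int(j),
                     QueueEntry(sender=i, priority=prio, arrival_step=step,
                                key=prio + rng.random()))
                )
    return outbox


def reply_phase(
    agent: AgentState, rng: np.random.Generator
) -> Tuple[List[QueueEntry], AgentState]:
    """Answer ``S_t ~ U{0..q}`` queue entries, priority-proportionally.

    Selection is iterative sampling without replacement: at each draw an
    entry is chosen with probability proportional to its priority among the
    remaining ones.  Chosen entries are removed from the queue and returned;
    the caller turns them into weighted replies.
    """
    q = agent.q
    if q == 0:
        return [], agent
    s = int(rng.integers(0, q + 1))
    if s == 0:
        return [], agent
    remaining = list(range(q))
    chosen: List[int] = []
    for _ in range(s):
        weights = np.array([agent.queue[i].priority for i in remaining],
                           dtype=np.float64)
        pick = int(rng.choice(len(remaining), p=weights / weights.sum()))
        chosen.append(remaining.pop(pick))
    chosen_set = set(chosen)
    replies = [agent.queue[i] for i in sorted(chosen_set)]
    agent.queue = [e for i, e in enumerate(agent.queue) if i not in chosen_set]
    return replies, agent


def enqueue(
    agent: AgentState,
    incoming: Sequence[QueueEntry],
    policy: str = "global-priority-drop-lowest",
) -> Tuple[AgentState, int]:
    """Deliver a batch of messages into an agent's bounded queue.

    One pending entry per sender: of all queued-plus-incoming entries from
    the same sender only the best-ranked survives.  The default policy then
    merges everything in key order and keeps the top ``capacity`` entries
    (arrivals can displace queued lower-priority entries).  The alternative
    ``append-until-full`` policy never evicts what is already queued.
    Returns the updated agent and the drop count (duplicates + overflow).
    """
    before = agent.q + len(incoming)

    def dedup(entries: Sequence[QueueEntry]) -> List[QueueEntry]:
        seen: set = set()
        kept = []
        for e in entries:
            if e.sender not in seen:
                seen.add(e.sender)
                kept.append(e)
        return kept

    if policy == "global-priority-drop-lowest":
        merged = sorted(agent.queue + list(incoming), key=lambda e: -e.key)
        agent.queue = dedup(merged)[: agent.capacity]
    elif policy == "append-until-full":
        inc = sorted(incoming, key=lambda e: -e.key)
        merged = dedup(agent.queue + inc)  # existing entries keep their slot
        agent.queue = sorted(merged[: agent.capacity], key=lambda e: -e.key)
    else:
        raise ValueError(f"unknown queue policy {policy!r}")
    return agent, before - agent.q


@dataclass
class SimConfig:
    """Full parameterisation of one model run."""

    substrate: Substrate
    p: float = 0.02
    T: int = 2000
    seed: int = 0
    q_max: int = 50
    sigma: float = 0.0
    reply_rule: str = "uniform-0-to-q"
    queue_policy: str = "global-priority-drop-lowest"
    capacities: Optional[CapacityAssignment] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("need 0 <= p <= 1")
        if self.T < 1:
            raise ValueError("need T >= 1")
        if self.reply_rule != "uniform-0-to-q":
            raise ValueError(f"unknown reply rule {self.reply_rule!r}")

    def resolve_capacities(self) -> CapacityAssignment:
        if self.capacities is not None:
            return self.capacities
        return assign_capacities(
            self.substrate.n, self.q_max, self.sigma,
            seed=derive_seed(self.seed, 7919),
        )


@dataclass
class TraceMessage:
    msg_id: int
    author: int
    parent_id: Optional[int]  # None for broadcast roots
    step: int


@dataclass
class RunTrace:
    """Per-event record of a run: every broadcast root and reply message."""

    messages: List[TraceMessage] = field(default_factory=list)
    n_broadcast_roots: int = 0
    n_replies: int = 0


@dataclass
class SimResult:
    """Outputs of one run: accumulated weights and derived curve."""

    weights: sp.csr_matrix            # (i, j) -> replies from i to j
    totals: np.ndarray                # per-agent total out-weight
    omega_curve: BinnedCurve
    st_log: np.ndarray                # replies sent per step
    n_broadcast_events: int
    n_discarded: int
    seed: int
    engine: str
    trace: Optional[RunTrace] = None
    rng_provenance: Dict[str, object] = field(default_factory=dict)

    @property
    def total_replies(self) -> int:
        return int(self.st_log.sum())


def _curve_from_totals(
    substrate: Substrate,
    totals: np.ndarray,
    binning: Optional[Binning] = None,
    center: str = "median",
) -> BinnedCurve:
    """Weight-per-contact against substrate degree, over all active agents.

    The denominator is the substrate out-degree (the number of contacts),
    matching the mean-field convention; agents with no contacts are
    excluded, agents who never replied contribute omega = 0.
    """
    deg = substrate.degree
    mask = deg > 0
    omega = totals[mask] / deg[mask]
    return bin_curve(deg[mask], omega, binning, center=center)


def _run_fast(config: SimConfig) -> SimResult:
    sub = config.substrate
    caps = config.resolve_capacities()
    w, st_log, n_bcast, n_disc = _kernels.run_abm_kernel(
        np.uint32(config.seed % (2**31)),
        sub.indptr,
        sub.neighbors,
        sub.degree.astype(np.int64),
        caps.q.astype(np.int64),
        float(config.p),
        int(config.T),
    )
    weights = sp.csr_matrix(
        (w, sub.neighbors, sub.indptr), shape=(sub.n, sub.n)
    )
    totals = np.asarray(weights.sum(axis=1)).ravel()
    return SimResult(
        weights=weights,
        totals=totals,
        omega_curve=_curve_from_totals(sub, totals),
        st_log=st_log,
        n_broadcast_events=int(n_bcast),
        n_discarded=int(n_disc),
        seed=config.seed,
        engine="fast",
        rng_provenance={"engine": "numba-global", "seed": config.seed},
    )


def _run_traced(config: SimConfig, check_invariants: bool = False) -> SimResult:
    """Reference engine: pure Python, retains the per-event message trace.

    Intended for desk-scale runs; implements exactly the same policies as
    the fast kernel (composite keys, uniform S_t, priority-proportional
    selection, merge-and-truncate delivery).
    """
    sub = config.substrate
    caps = config.resolve_capacities()
    rng = np.random.default_rng(config.seed)
    agents = [AgentState(capacity=int(c)) for c in caps.q]
    trace = RunTrace()
    weights: Dict[Tuple[int, int], int] = {}
    st_log = np.zeros(config.T, dtype=np.int64)
    n_bcast = 0
    n_disc = 0
    next_id = 0

    for t in range(config.T):
        outbox: List[Tuple[int, QueueEntry]] = []
        for i in range(sub.n):
            replies, _ = reply_phase(agents[i], rng)
            st_log[t] += len(replies)
            prio = max(int(sub.degree[i]), 1)
            for entry in replies:
                j = entry.sender
                weights[(i, j)] = weights.get((i, j), 0) + 1
                mid = next_id
                next_id += 1
                trace.messages.append(
                    TraceMessage(msg_id=mid, author=i,
                                 parent_id=entry.msg_id, step=t)
                )
                trace.n_replies += 1
                outbox.append(
                    (j, QueueEntry(sender=i, priority=prio, arrival_step=t + 1,
                                   key=prio + rng.random(), msg_id=mid))
                )
        # broadcasts: one root message per event, one queue copy per contact
        draws = rng.random(sub.n)
        for i in range(sub.n):
            if draws[i] < config.p and sub.degree[i] > 0:
                n_bcast += 1
                prio = int(sub.degree[i])
                mid = next_id
                next_id += 1
                trace.messages.append(
                    TraceMessage(msg_id=mid, author=i, parent_id=None, step=t)
                )
                trace.n_broadcast_roots += 1
                for j in sub.neighbors_of(i):
                    outbox.append(
                        (int(j),
                         QueueEntry(sender=i, priority=prio,
                                    arrival_step=t + 1,
                                    key=prio + rng.random(), msg_id=mid))
                    )
        by_recipient: Dict[int, List[QueueEntry]] = {}
        for j, entry in outbox:
            by_recipient.setdefault(j, []).append(entry)
        for j, incoming in by_recipient.items():
            _, d = enqueue(agents[j], incoming, policy=config.queue_policy)
            n_disc += d
        if check_invariants:
            for a in agents:
                a.check()

    if weights:
        rows, cols, vals = zip(*((i, j, v) for (i, j), v in weights.items()))
    else:
        rows, cols, vals = (), (), ()
    wmat = sp.csr_matrix(
        (np.array(vals, dtype=np.int64),
         (np.array(rows, dtype=np.int64), np.array(cols, dtype=np.int64))),
        shape=(sub.n, sub.n),
    )
    totals = np.asarray(wmat.sum(axis=1)).ravel()
    return SimResult(
        weights=wmat,
        totals=totals,
        omega_curve=_curve_from_totals(sub, totals),
        st_log=st_log,
        n_broadcast_events=n_bcast,
        n_discarded=n_disc,
        seed=config.seed,
        engine="traced",
        trace=trace,
        rng_provenance={"engine": "numpy-generator", "seed": config.seed},
    )


def run_simulation(
    config: SimConfig,
    engine: str = "auto",
    check_invariants: bool = False,
) -> SimResult:
    """Run the model for ``config.T`` steps.

    ``engine="fast"`` uses the compiled kernel (default queue policy only);
    ``"traced"`` uses the instrumented Python engine and retains the
    per-event message trace needed to emit a conversation log.  ``"auto"``
    picks the fast path whenever the configuration allows it.
    """
    if engine == "auto":
        engine = ("fast"
                  if config.queue_policy == "global-priority-drop-lowest"
                  and not check_invariants
                  else "traced")
    if engine == "fast":
        if config.queue_policy != "global-priority-drop-lowest":
            raise ValueError("fast engine supports only the default policy")
        return _run_fast(config)
    if engine == "traced":
        return _run_traced(config, check_invariants=check_invariants)
    raise ValueError(f"unknown engine {engine!r}")


@dataclass
class ReplicaSummary:
    q_max: int
    curve: BinnedCurve
    peak_degree: float
    peak_flag: str
    replica_seeds: List[int]


def replica_medians(
    configs: Sequence[SimConfig],
    replicas: int,
    binning: Optional[Binning] = None,
    smooth_window: int = 3,
    engine: str = "fast",
) -> List[ReplicaSummary]:
    """Median curves over independent replicas, one summary per config.

    Each config keeps its substrate fixed; replicas differ only in the
    dynamics seed, derived from the config seed by a counter scheme.  The
    per-bin center is the median across replicas of the per-replica medians,
    and the peak is located on that median curve.
    """
    if replicas < 2:
        raise ValueError("need at least 2 replicas")
    out: List[ReplicaSummary] = []
    for config in configs:
        seeds = [derive_seed(config.seed, r) for r in range(replicas)]
        curves = []
        for s in seeds:
            res = run_simulation(replace(config, seed=s), engine=engine)
            curves.append(_curve_from_totals(config.substrate, res.totals,
                                             binning=binning))
        base = curves[0]
        centers = np.median(np.stack([c.center for c in curves]), axis=0)
        lo = np.median(np.stack([c.band_lo for c in curves]), axis=0)
        hi = np.median(np.stack([c.band_hi for c in curves]), axis=0)
        med_curve = BinnedCurve(
            bin_edges=base.bin_edges, x=base.x, center=centers,
            band_lo=lo, band_hi=hi, n=base.n, center_stat="median",
        )
        peak, flag = find_peak(med_curve, smooth_window=smooth_window)
        out.append(
            ReplicaSummary(q_max=config.q_max, curve=med_curve,
                           peak_degree=peak, peak_flag=flag,
                           replica_seeds=seeds)
        )
    return out
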