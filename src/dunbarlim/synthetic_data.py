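"""Synthetic conversation logs with the structure the analysis assumes.

The real corpus behind the empirical curves (hundreds of millions of
messages) is not distributable, so this module makes the ingest/metrics
pipeline fully testable in two complementary ways:

* ``abm`` mode re-emits the message trace of an instrumented model run as a
  conversation log — broadcasts become root messages, every reply becomes a
  record pointing at the exact message it answered — so ingesting the log
  and projecting it must reproduce the run's weight matrix integer-exactly
  (a mechanism-consistency round trip);
* ``parametric`` mode synthesises a log directly from a known saturation
  law: users receive power-law contact counts, and each user's per-contact
  reply intensity rises linearly with contact count up to a capacity ``c``
  and falls as ``c^2 / m`` beyond it, so the projected weight-per-contact
  curve has its peak at ``c`` by construction — a known-answer input for
  the metrics stack that is independent of the agent model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .queue_abm import RunTrace, SimResult
from .reply_ingest import MessageRecord

__all__ = [
    "GeneratorSpec",
    "emit_conversation_log",
    "parametric_log",
]


@dataclass
class GeneratorSpec:
    """Parameters of the parametric log generator.

    ``capacity`` is the contact count at which per-edge reply intensity
    peaks; ``intensity`` scales how far above 1 the mean per-edge weight
    rises at the peak; ``gamma`` is the contact-count exponent; ``activity``
    scales overall reply volume (0 switches replying off entirely, giving
    an empty log).
    """

    n_users: int = 20_000
    gamma: float = -2.1
    capacity: int = 150
    intensity: float = 8.0
    activity: float = 1.0
    k_max: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 2 or self.capacity < 1:
            raise ValueError("need n_users >= 2 and capacity >= 1")


def emit_conversation_log(result: SimResult) -> Iterator[MessageRecord]:
    """Re-emit an instrumented model run as a conversation log.

    One root record per broadcast event (not per delivered copy); one child
    record per reply, attached to the exact message answered.  Timestamps
    are the simulation steps.  Requires a run with ``engine="traced"``.
    """
    trace: Optional[RunTrace] = result.trace
    if trace is None:
        raise ValueError(
            "run has no message trace; re-run with engine='traced'"
        )
    for msg in trace.messages:
        yield MessageRecord(
            message_id=f"m{msg.msg_id}",
            author_id=f"u{msg.author}",
            parent_id=None if msg.parent_id is None else f"m{msg.parent_id}",
            timestamp=msg.step,
        )


def _distinct_contacts(
    u: int, m: int, n_users: int, rng: np.random.Generator
) -> np.ndarray:
    """m distinct contacts of user u, uniform over the other users."""
    if m > n_users - 1:
        raise ValueError("more contacts requested than users available")
    if m * 3 > n_users:  # dense case: permutation is cheaper than rejection
        others = np.delete(np.arange(n_users), u)
        return rng.permutation(others)[:m]
    chosen: set = set()
    while len(chosen) < m:
        draw = rng.integers(0, n_users, size=m - len(chosen))
        for v in draw:
            v = int(v)
            if v != u:
                chosen.add(v)
    return np.fromiter(chosen, dtype=np.int64, count=m)


def _contact_counts(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    kmax = min(spec.k_max, spec.n_users - 1)
    support = np.arange(1, kmax + 1, dtype=np.float64)
    pmf = support**spec.gamma
    pmf /= pmf.sum()
    return rng.choice(np.arange(1, kmax + 1), size=spec.n_users, p=pmf)


def parametric_log(spec: GeneratorSpec) -> Iterator[MessageRecord]:
    """Synthesise a flat-forest conversation log with a known omega peak.

    For a user with ``m`` contacts the mean per-edge weight is
    ``1 + intensity * min(m, c^2/m) / c`` — linear growth to the capacity
    ``c``, then inverse decay — and per-edge weights are drawn as
    ``1 + Poisson(mean - 1)``.  Each contacted pair gets one root message
    authored by the contact and the user's replies attached flat below it.
    """
    if spec.activity == 0:
        return
    rng = np.random.default_rng(spec.seed)
    counts = _contact_counts(spec, rng)
    c = float(spec.capacity)
    next_id = 0
    for u in range(spec.n_users):
        m = int(counts[u])
        lam = spec.activity * spec.intensity * min(m, c * c / m) / c
        contacts = _distinct_contacts(u, m, spec.n_users, rng)
        weights = 1 + rng.poisson(lam, size=m)
        for v, w in zip(contacts, weights):
            root_id = f"r{next_id}"
            next_id += 1
            yield MessageRecord(
                message_id=root_id, author_id=f"u{v}", parent_id=None
            )
            for _ in range(int(w)):
                yield MessageRecord(
                    message_id=f"m{next_id}", author_id=f"u{u}",
                    parent_id=root_id,
                )
                next_id += 1
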