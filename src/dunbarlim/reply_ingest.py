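"""Conversation logs -> reply forests -> weighted directed user network.

A conversation log is a flat record-per-line file of messages; each message
optionally points at the message it answers.  Parent links turn the log into
a forest of reply trees, and projecting every reply event onto its author and
its parent's author yields a directed network whose integer edge weight
``w[i][j]`` counts how many times user *i* replied to user *j*.  That weight
is the interaction-strength measure everything downstream builds on.

Conventions:

* a record whose ``parent_id`` is absent, empty, or not present in the log is
  a root (truncated threads lose their head, not their replies);
* self-replies (author answers their own message) contribute no edge;
* users who only author roots still appear as isolated nodes by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import networkx as nx

__all__ = [
    "MessageRecord",
    "IngestReport",
    "ReplyForest",
    "UserNetwork",
    "IngestError",
    "CycleError",
    "read_messages",
    "build_forest",
    "project_to_network",
    "write_edge_list",
    "read_edge_list",
]


class IngestError(ValueError):
    """Fatal problem with a conversation log (unreadable, duplicate ids...)."""


class CycleError(IngestError):
    """Parent links form a cycle; carries the offending message ids."""

    def __init__(self, members: List[str]):
        super().__init__(f"parent links form a cycle: {members}")
        self.members = members


@dataclass(frozen=True)
class MessageRecord:
    """One authored message, possibly a reply to another message."""

    message_id: str
    author_id: str
    parent_id: Optional[str] = None
    timestamp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.parent_id == self.message_id:
            raise ValueError(f"message {self.message_id!r} is its own parent")


@dataclass
class IngestReport:
    """Per-line problems encountered while reading a log.

    Malformed lines are counted and described, never silently dropped.
    """

    n_read: int = 0
    errors: List[Tuple[int, str]] = field(default_factory=list)

    @property
    def n_errors(self) -> int:
        return len(self.errors)

    def add(self, lineno: int, message: str) -> None:
        self.errors.append((lineno, message))


_TSV_FIELDS = ("message_id", "author_id", "parent_id", "timestamp")


def _parse_timestamp(raw: str, lineno: int) -> Optional[int]:
    if raw == "" or raw is None:
        return None
    try:
        return int(raw)
    except (TypeError, ValueError):
        raise ValueError(f"line {lineno}: bad timestamp {raw!r}") from None


def read_messages(
    path,
    dialect: str = "tsv",
    report: Optional[IngestReport] = None,
) -> Iterator[MessageRecord]:
    """Stream :class:`MessageRecord` objects from a conversation log.

    Parameters
    ----------
    path:
        Log file.  ``tsv``: tab-delimited with a
        ``message_id  author_id  parent_id  timestamp`` header, empty
        ``parent_id`` meaning root.  ``jsonl``: one JSON object per line with
        the same keys (missing/null ``parent_id`` meaning root).
    dialect:
        ``"tsv"`` or ``"jsonl"``.
    report:
        Optional :class:`IngestReport`; malformed lines are recorded there
        (with line numbers) and skipped.  Without a report a malformed line
        raises :class:`IngestError`.

    Yields records in file order.  A duplicate ``message_id`` is always fatal.
    """
    if dialect not in ("tsv", "jsonl"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    seen: set = set()
    sink = report

    def problem(lineno: int, msg: str) -> None:
        if sink is None:
            raise IngestError(f"line {lineno}: {msg}")
        sink.add(lineno, msg)

    with path.open("r", encoding="utf-8") as fh:
        lines = iter(enumerate(fh, start=1))
        header: Optional[List[str]] = None
        if dialect == "tsv":
            try:
                _, first = next(lines)
            except StopIteration:
                return
            header = first.rstrip("\n").split("\t")
            if header[: len(_TSV_FIELDS)] != list(_TSV_FIELDS[: len(header)]):
                # headerless file: treat the first line as data
                lines = iter(
                    [(1, first)]
                    + [(i, l) for i, l in lines]  # pragma: no cover - rare path
                )
                header = None
        for lineno, line in lines:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            try:
                if dialect == "tsv":
                    parts = line.split("\t")
                    if len(parts) < 2:
                        raise ValueError(f"line {lineno}: expected >=2 fields")
                    parts += [""] * (4 - len(parts))
                    mid, author, parent, ts = parts[:4]
                    if not mid or not author:
                        raise ValueError(f"line {lineno}: missing required field")
                    rec = MessageRecord(
                        message_id=mid,
                        author_id=author,
                        parent_id=parent or None,
                        timestamp=_parse_timestamp(ts, lineno),
                    )
                else:
                    obj = json.loads(line)
                    mid = obj.get("message_id")
                    author = obj.get("author_id")
                    if not mid or not author:
                        raise ValueError(f"line {lineno}: missing required field")
                    ts = obj.get("timestamp")
                    rec = MessageRecord(
                        message_id=str(mid),
                        author_id=str(author),
                        parent_id=(str(obj["parent_id"])
                                   if obj.get("parent_id") not in (None, "")
                                   else None),
                        timestamp=int(ts) if ts is not None else None,
                    )
            except (ValueError, json.JSONDecodeError) as exc:
                problem(lineno, str(exc))
                continue
            if rec.message_id in seen:
                raise IngestError(
                    f"line {lineno}: duplicate message_id {rec.message_id!r}"
                )
            seen.add(rec.message_id)
            if sink is not None:
                sink.n_read += 1
            yield rec


@dataclass
class ReplyForest:
    """All messages of a log indexed by id, plus the root set.

    ``roots`` contains every message with no parent *and* every message whose
    parent is not present in the log (dangling replies become roots).
    """

    records: Dict[str, MessageRecord]
    roots: List[str]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_trees(self) -> int:
        return len(self.roots)

    def resolved_parent(self, message_id: str) -> Optional[str]:
        """Parent id if it exists in the log, else None."""
        pid = self.records[message_id].parent_id
        return pid if pid is not None and pid in self.records else None


def build_forest(records: Iterable[MessageRecord]) -> ReplyForest:
    """Assemble records into a reply forest.

    Records with an unresolvable ``parent_id`` are treated as roots.  Raises
    :class:`IngestError` on duplicate ids and :class:`CycleError` if parent
    links loop (possible only with corrupted ids).
    """
    index: Dict[str, MessageRecord] = {}
    for rec in records:
        if rec.message_id in index:
            raise IngestError(f"duplicate message_id {rec.message_id!r}")
        index[rec.message_id] = rec

    roots: List[str] = []
    for mid, rec in index.items():
        if rec.parent_id is None or rec.parent_id not in index:
            roots.append(mid)

    # Verify the forest property: follow parent chains with tri-colour marks.
    state: Dict[str, int] = {}  # 0 in-progress, 1 done
    for start in index:
        if state.get(start) == 1:
            continue
        chain: List[str] = []
        node: Optional[str] = start
        while node is not None and state.get(node) != 1:
            if state.get(node) == 0:
                cycle_at = chain.index(node)
                raise CycleError(chain[cycle_at:])
            state[node] = 0
            chain.append(node)
            pid = index[node].parent_id
            node = pid if pid is not None and pid in index else None
        for n in chain:
            state[n] = 1
    return ReplyForest(records=index, roots=roots)


class UserNetwork:
    """Directed weighted user network: ``w[i][j]`` replies from *i* to *j*.

    Thin wrapper over a :class:`networkx.DiGraph` whose edges carry an
    integer ``weight`` >= 1.  Out-degree ``k_out`` counts distinct users
    replied to; in-degree ``k_in`` counts distinct users replied from.
    """

    def __init__(self, graph: Optional[nx.DiGraph] = None):
        self.graph = graph if graph is not None else nx.DiGraph()

    # -- construction -----------------------------------------------------
    def add_user(self, user: str) -> None:
        self.graph.add_node(user)

    def add_reply(self, source: str, target: str, count: int = 1) -> None:
        if source == target:
            raise ValueError("self-loops are not allowed")
        if count < 1:
            raise ValueError("weight increments must be >= 1")
        w = self.graph.get_edge_data(source, target, default={}).get("weight", 0)
        self.graph.add_edge(source, target, weight=w + count)

    # -- queries -----------------------------------------------------------
    @property
    def users(self):
        return self.graph.nodes

    def __contains__(self, user: str) -> bool:
        return user in self.graph

    def n_users(self) -> int:
        return self.graph.number_of_nodes()

    def weight(self, source: str, target: str) -> int:
        data = self.graph.get_edge_data(source, target)
        return 0 if data is None else int(data["weight"])

    def k_out(self, user: str) -> int:
        return self.graph.out_degree(user)

    def k_in(self, user: str) -> int:
        return self.graph.in_degree(user)

    def out_weight(self, user: str) -> int:
        return int(sum(d["weight"] for _, _, d in
                       self.graph.out_edges(user, data=True)))

    def successors(self, user: str):
        return self.graph.successors(user)

    def predecessors(self, user: str):
        return self.graph.predecessors(user)

    def total_weight(self) -> int:
        return int(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def edges(self) -> Iterator[Tuple[str, str, int]]:
        for u, v, d in self.graph.edges(data=True):
            yield u, v, int(d["weight"])

    def __eq__(self, other) -> bool:  # weight-exact equality
        if not isinstance(other, UserNetwork):
            return NotImplemented
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        mine = {(u, v): w for u, v, w in self.edges()}
        theirs = {(u, v): w for u, v, w in other.edges()}
        return mine == theirs


def project_to_network(
    forest: ReplyForest, include_isolated: bool = True
) -> UserNetwork:
    """Project a reply forest onto its authors.

    Every reply whose author differs from its parent's author increments
    ``w[author(reply)][author(parent)]`` by one.  Self-replies and roots add
    no edges; with ``include_isolated`` users who only author roots still
    appear as isolated nodes.
    """
    net = UserNetwork()
    for mid, rec in forest.records.items():
        if include_isolated:
            net.add_user(rec.author_id)
        pid = forest.resolved_parent(mid)
        if pid is None:
            continue
        parent_author = forest.records[pid].author_id
        if rec.author_id != parent_author:
            net.add_reply(rec.author_id, parent_author)
        elif include_isolated:
            net.add_user(parent_author)
    return net


def filter_window(
    records: Iterable[MessageRecord],
    since: Optional[int] = None,
    until: Optional[int] = None,
) -> Iterator[MessageRecord]:
    """Keep records whose timestamp lies in [since, until].

    Records without a timestamp pass the filter unchanged (the aggregation
    window defaults to the whole log).
    """
    for rec in records:
        ts = rec.timestamp
        if ts is not None:
            if since is not None and ts < since:
                continue
            if until is not None and ts > until:
                continue
        yield rec


def write_edge_list(net: UserNetwork, path) -> None:
    """Write ``source\ttarget\tweight`` with a header."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, w in sorted(net.edges()):
            fh.write(f"{u}\t{v}\t{w}\n")


def read_edge_list(path) -> UserNetwork:
    net = UserNetwork()
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("source"):
            raise IngestError("edge list must start with a source/target header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise IngestError(f"line {lineno}: expected 3 fields")
            net.add_reply(parts[0], parts[1], int(parts[2]))
    return net


def write_graphml(net: UserNetwork, path) -> None:
    """Optional graph-exchange XML export."""
    nx.write_graphml(net.graph, path)
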