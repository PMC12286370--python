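"""Directed two-mode (bipartite) network representation.

In a swipe-based dating market every tie runs between the two gender
modes, never within one, and ties are directed: a swipe from a woman to
a man is a different event from a swipe from that man to the woman.  A
single incidence matrix cannot hold both directions, so the network is
stored as a *pair* of binary incidence matrices:

``M_F``
    shape ``(n_women, n_men)``; entry ``(i, j) = 1`` iff woman ``i``
    swiped man ``j``.
``M_M``
    shape ``(n_men, n_women)``; entry ``(i, j) = 1`` iff man ``i``
    swiped woman ``j``.

A *match* (mutual interest) is a pair with ties in both directions; the
reciprocal matrix collects exactly those pairs.  Matrices are binary by
construction: repeated identical swipes are collapsed (with the
collapsed count logged) because only the first swipe and the response
to it are meaningful events.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DirectedBipartiteNetwork",
    "from_edge_list",
    "reciprocal_matrix",
    "read_network",
    "write_network",
]


class NetworkError(ValueError):
    """Raised for structurally invalid networks or edge lists."""


@dataclass
class DirectedBipartiteNetwork:
    """A directed bipartite network held as two binary incidence matrices.

    Parameters
    ----------
    women, men
        Ordered node registries (lists of identifiers).  Order is an
        internal detail: every vector-valued measure reports by node id.
    M_F
        ``(n_women, n_men)`` binary matrix of woman->man swipes.
    M_M
        ``(n_men, n_women)`` binary matrix of man->woman swipes.
    node_attrs
        Optional per-node attribute mapping (e.g. ``age``, ``city``).
    """

    women: list
    men: list
    M_F: np.ndarray
    M_M: np.ndarray
    node_attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.women = list(self.women)
        self.men = list(self.men)
        self.M_F = np.asarray(self.M_F, dtype=np.int8)
        self.M_M = np.asarray(self.M_M, dtype=np.int8)
        self.validate()

    # -- basic properties -------------------------------------------------

    @property
    def n_women(self) -> int:
        return len(self.women)

    @property
    def n_men(self) -> int:
        return len(self.men)

    @property
    def n_nodes(self) -> int:
        return self.n_women + self.n_men

    @property
    def total_ties(self) -> int:
        """Total number of directed swipes, ``sum(M_F) + sum(M_M)``."""
        return int(self.M_F.sum()) + int(self.M_M.sum())

    @property
    def woman_index(self) -> dict:
        return {w: i for i, w in enumerate(self.women)}

    @property
    def man_index(self) -> dict:
        return {m: i for i, m in enumerate(self.men)}

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`NetworkError`."""
        if self.M_F.shape != (self.n_women, self.n_men):
            raise NetworkError(
                f"M_F has shape {self.M_F.shape}, expected "
                f"({self.n_women}, {self.n_men})"
            )
        if self.M_M.shape != (self.n_men, self.n_women):
            raise NetworkError(
                f"M_M has shape {self.M_M.shape}, expected "
                f"({self.n_men}, {self.n_women})"
            )
        for name, mat in (("M_F", self.M_F), ("M_M", self.M_M)):
            if mat.size and not np.isin(mat, (0, 1)).all():
                raise NetworkError(f"{name} has entries other than 0/1")
        if len(set(self.women)) != self.n_women:
            raise NetworkError("duplicate identifiers in the women registry")
        if len(set(self.men)) != self.n_men:
            raise NetworkError("duplicate identifiers in the men registry")
        overlap = set(self.women) & set(self.men)
        if overlap:
            raise NetworkError(f"identifiers in both registries: {sorted(overlap)}")

    def edges(self) -> list:
        """All directed ties as ``(sender_id, receiver_id)`` pairs."""
        out = []
        for i, j in zip(*np.nonzero(self.M_F)):
            out.append((self.women[i], self.men[j]))
        for i, j in zip(*np.nonzero(self.M_M)):
            out.append((self.men[i], self.women[j]))
        return out

    def subnetwork(self, women: Sequence, men: Sequence) -> "DirectedBipartiteNetwork":
        """Restrict to the given node subsets (ids), preserving order of
        the parent registries; ties incident to dropped nodes are removed."""
        wkeep = set(women)
        mkeep = set(men)
        wi = [i for i, w in enumerate(self.women) if w in wkeep]
        mi = [i for i, m in enumerate(self.men) if m in mkeep]
        sub_w = [self.women[i] for i in wi]
        sub_m = [self.men[i] for i in mi]
        attrs = {n: self.node_attrs[n] for n in (*sub_w, *sub_m) if n in self.node_attrs}
        return DirectedBipartiteNetwork(
            women=sub_w,
            men=sub_m,
            M_F=self.M_F[np.ix_(wi, mi)] if wi and mi else np.zeros((len(wi), len(mi)), np.int8),
            M_M=self.M_M[np.ix_(mi, wi)] if wi and mi else np.zeros((len(mi), len(wi)), np.int8),
            node_attrs=attrs,
        )


def from_edge_list(
    edges: Iterable[tuple],
    nodes: Iterable[tuple] | Mapping,
    node_attrs: Mapping | None = None,
) -> DirectedBipartiteNetwork:
    """Build a network from a swipe edge list and a gender table.

    Parameters
    ----------
    edges
        Iterable of ``(sender_id, receiver_id)`` pairs.  Duplicate
        identical pairs are collapsed to a single binary tie; the number
        collapsed is logged for audit.
    nodes
        Iterable of ``(id, gender)`` pairs (or an id->gender mapping)
        with gender coded ``"F"``/``"M"``.  Nodes with no incident edge
        are retained as isolates.
    node_attrs
        Optional id -> attribute-dict mapping (``age``, ``city``...).

    Raises
    ------
    NetworkError
        On a same-gender edge, an edge endpoint missing from the node
        table, an unrecognised gender code, or an empty node table.
    """
    if isinstance(nodes, Mapping):
        node_pairs = list(nodes.items())
    else:
        node_pairs = list(nodes)
    if not node_pairs:
        raise NetworkError("empty node table")

    women: list = []
    men: list = []
    gender: dict = {}
    for nid, g in node_pairs:
        g = str(g).strip().upper()
        if nid in gender:
            raise NetworkError(f"duplicate node id {nid!r} in node table")
        if g == "F":
            women.append(nid)
        elif g == "M":
            men.append(nid)
        else:
            raise NetworkError(f"gender of node {nid!r} must be 'F' or 'M', got {g!r}")
        gender[nid] = g

    widx = {w: i for i, w in enumerate(women)}
    midx = {m: i for i, m in enumerate(men)}
    M_F = np.zeros((len(women), len(men)), dtype=np.int8)
    M_M = np.zeros((len(men), len(women)), dtype=np.int8)

    n_duplicates = 0
    for s, r in edges:
        if s not in gender or r not in gender:
            missing = s if s not in gender else r
            raise NetworkError(f"edge ({s!r}, {r!r}) references unknown node {missing!r}")
        gs, gr = gender[s], gender[r]
        if gs == gr:
            raise NetworkError(f"same-gender edge ({s!r}, {r!r}): both coded {gs!r}")
        if gs == "F":
            i, j = widx[s], midx[r]
            if M_F[i, j]:
                n_duplicates += 1
            M_F[i, j] = 1
        else:
            i, j = midx[s], widx[r]
            if M_M[i, j]:
                n_duplicates += 1
            M_M[i, j] = 1

    if n_duplicates:
        logger.info("collapsed %d duplicate swipe(s) to binary ties", n_duplicates)

    attrs = dict(node_attrs) if node_attrs else {}
    return DirectedBipartiteNetwork(women, men, M_F, M_M, attrs)


def reciprocal_matrix(net: DirectedBipartiteNetwork) -> np.ndarray:
    """Binary matrix of matches in female-row orientation.

    Entry ``(i, j) = 1`` iff woman ``i`` swiped man ``j`` *and* man
    ``j`` swiped woman ``i`` — the elementwise AND of ``M_F`` and
    ``M_M.T``.  Its sum is the number of matches, bounded above by
    ``min(sum(M_F), sum(M_M))``.
    """
    return (net.M_F & net.M_M.T).astype(np.int8)


# -- serialization --------------------------------------------------------


def write_network(net: DirectedBipartiteNetwork, path) -> None:
    """Serialize a network to a JSON document (registries, attributes
    and both directed edge sets)."""
    doc = {
        "format": "swipenet-network",
        "version": 1,
        "women": list(net.women),
        "men": list(net.men),
        "node_attrs": net.node_attrs,
        "edges_f": [[net.women[i], net.men[j]] for i, j in zip(*np.nonzero(net.M_F))],
        "edges_m": [[net.men[i], net.women[j]] for i, j in zip(*np.nonzero(net.M_M))],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_network(path) -> DirectedBipartiteNetwork:
    """Read a network written by :func:`write_network`.

    ``read_network(write_network(net))`` reproduces registries and both
    matrices exactly, isolates included.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise NetworkError(
                f"malformed network file {path}: {exc.msg} at line {exc.lineno}"
            ) from exc
    try:
        women = doc["women"]
        men = doc["men"]
        attrs = doc.get("node_attrs", {})
        edges = [tuple(e) for e in doc["edges_f"]] + [tuple(e) for e in doc["edges_m"]]
    except (KeyError, TypeError) as exc:
        raise NetworkError(f"malformed network file {path}: missing field {exc}") from exc
    nodes = [(w, "F") for w in women] + [(m, "M") for m in men]
    return from_edge_list(edges, nodes, node_attrs=attrs)
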