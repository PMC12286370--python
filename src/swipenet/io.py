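"""CSV readers/writers for swipe edge lists and node tables.

Edge CSV: header ``sender_id,receiver_id``, one directed swipe per row.
Node CSV: header ``user_id,gender[,age,city]``, gender coded ``F``/``M``.
"""

from __future__ import annotations

import pandas as pd

from .network import DirectedBipartiteNetwork, from_edge_list

__all__ = ["read_edges_csv", "read_nodes_csv", "load_network_csv", "write_network_csv"]


def read_edges_csv(path) -> list:
    df = pd.read_csv(path, dtype=str)
    required = {"sender_id", "receiver_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge CSV {path} must have columns {sorted(required)}")
    return list(df[["sender_id", "receiver_id"]].itertuples(index=False, name=None))


def read_nodes_csv(path) -> tuple[list, dict]:
    """Returns (``[(id, gender), ...]``, id -> attribute dict)."""
    df = pd.read_csv(path, dtype={"user_id": str, "gender": str})
    required = {"user_id", "gender"}
    if not required.issubset(df.columns):
        raise ValueError(f"node CSV {path} must have columns {sorted(required)}")
    nodes = list(df[["user_id", "gender"]].itertuples(index=False, name=None))
    extra = [c for c in df.columns if c not in required]
    attrs: dict = {}
    if extra:
        for _, row in df.iterrows():
            attrs[row["user_id"]] = {
                c: row[c] for c in extra if pd.notna(row[c])
            }
    return nodes, attrs


def load_network_csv(edges_path, nodes_path) -> DirectedBipartiteNetwork:
    """Build a network from an edge CSV and a node CSV."""
    nodes, attrs = read_nodes_csv(nodes_path)
    return from_edge_list(read_edges_csv(edges_path), nodes, node_attrs=attrs)


def write_network_csv(net: DirectedBipartiteNetwork, edges_path, nodes_path) -> None:
    pd.DataFrame(net.edges(), columns=["sender_id", "receiver_id"]).to_csv(
        edges_path, index=False
    )
    rows = []
    for nid in (*net.women, *net.men):
        row = {"user_id": nid, "gender": "F" if nid in set(net.women) else "M"}
        row.update(net.node_attrs.get(nid, {}))
        rows.append(row)
    pd.DataFrame(rows).to_csv(nodes_path, index=False)
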