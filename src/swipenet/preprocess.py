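"""Cleaning rules for raw swipe networks.

Three filters, each returning the filtered network together with an
auditable :class:`FilterReport`:

* ``filter_active`` — keep users who sent or received at least one
  swipe in the collection window.
* ``filter_bots`` — remove suspected bots: profiles that reciprocated
  every swipe they received, provided they received at least 30.  Users
  who accepted everything but received only a few swipes are kept (too
  little evidence), as are heavily-swiped users who showed any
  selectivity (popular, not automated).
* ``split_markets`` — cut the network into per-city markets; each city
  is its own dating market, and the few cross-city ties are dropped.

All filters are idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .network import DirectedBipartiteNetwork

logger = logging.getLogger(__name__)

__all__ = ["FilterReport", "filter_active", "filter_bots", "split_markets"]


@dataclass(frozen=True)
class FilterReport:
    rule: str
    nodes_removed: tuple
    n_ties_removed: int
    params: dict = field(default_factory=dict)

    @property
    def n_nodes_removed(self) -> int:
        return len(self.nodes_removed)

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "n_nodes_removed": self.n_nodes_removed,
            "nodes_removed": list(self.nodes_removed),
            "n_ties_removed": self.n_ties_removed,
            "params": self.params,
        }


def filter_active(net: DirectedBipartiteNetwork):
    """Drop zero-degree isolates; all ties are preserved."""
    out_w = net.M_F.sum(axis=1)
    in_w = net.M_M.sum(axis=0)
    out_m = net.M_M.sum(axis=1)
    in_m = net.M_F.sum(axis=0)
    keep_w = [w for i, w in enumerate(net.women) if out_w[i] + in_w[i] > 0]
    keep_m = [m for i, m in enumerate(net.men) if out_m[i] + in_m[i] > 0]
    removed = tuple(
        n for n in (*net.women, *net.men) if n not in set(keep_w) | set(keep_m)
    )
    filtered = net.subnetwork(keep_w, keep_m)
    report = FilterReport(rule="active", nodes_removed=removed, n_ties_removed=0)
    if removed:
        logger.info("active filter removed %d isolate(s)", len(removed))
    return filtered, report


def filter_bots(
    net: DirectedBipartiteNetwork,
    min_received: float = 30,
    accept_rate: float = 1.0,
    target_mode: str = "women",
):
    """Remove suspected bot profiles and all their incident ties.

    A target-mode node is removed iff its indegree is at least
    ``min_received`` ("at least 30" includes the boundary) *and* the
    fraction of its in-neighbours it swiped back is at least
    ``accept_rate`` (1.0 = accepted everything).
    """
    if min_received < 0 or accept_rate < 0:
        raise ValueError("thresholds must be non-negative")
    if target_mode == "women":
        indeg = net.M_M.sum(axis=0).astype(float)  # swipes received by women
        # reverse ties to in-neighbours: woman i swiped man j who swiped her
        reciprocated = (net.M_F * net.M_M.T).sum(axis=1).astype(float)
        ids = net.women
    elif target_mode == "men":
        indeg = net.M_F.sum(axis=0).astype(float)
        reciprocated = (net.M_M * net.M_F.T).sum(axis=1).astype(float)
        ids = net.men
    else:
        raise ValueError(f"target_mode must be 'women' or 'men', got {target_mode!r}")

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(indeg > 0, reciprocated / np.maximum(indeg, 1), 0.0)
    is_bot = (indeg >= min_received) & (frac >= accept_rate)
    removed = tuple(ids[i] for i in np.nonzero(is_bot)[0])

    keep_w = [w for w in net.women if not (target_mode == "women" and w in set(removed))]
    keep_m = [m for m in net.men if not (target_mode == "men" and m in set(removed))]
    filtered = net.subnetwork(keep_w, keep_m)
    report = FilterReport(
        rule="bots",
        nodes_removed=removed,
        n_ties_removed=net.total_ties - filtered.total_ties,
        params={
            "min_received": min_received,
            "accept_rate": accept_rate,
            "target_mode": target_mode,
        },
    )
    if removed:
        logger.info(
            "bot filter removed %d node(s), %d tie(s)",
            len(removed),
            report.n_ties_removed,
        )
    return filtered, report


def split_markets(net: DirectedBipartiteNetwork, attribute: str = "city") -> dict:
    """Split into one sub-network per attribute value.

    Cross-market ties are dropped (logged count); every node must carry
    the attribute.
    """
    missing = [n for n in (*net.women, *net.men) if attribute not in net.node_attrs.get(n, {})]
    if missing:
        raise ValueError(
            f"attribute {attribute!r} missing for {len(missing)} node(s): "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    labels = sorted({net.node_attrs[n][attribute] for n in (*net.women, *net.men)})
    markets = {}
    total_kept = 0
    for lab in labels:
        w = [x for x in net.women if net.node_attrs[x][attribute] == lab]
        m = [x for x in net.men if net.node_attrs[x][attribute] == lab]
        sub = net.subnetwork(w, m)
        markets[lab] = sub
        total_kept += sub.total_ties
    dropped = net.total_ties - total_kept
    if dropped:
        logger.info("dropped %d cross-market tie(s) across %d markets", dropped, len(labels))
    return markets
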