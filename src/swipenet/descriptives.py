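"""Whole-network and per-mode measures for directed two-mode networks.

Implements the degree machinery (raw and standardized in/outdegrees,
moment summaries), the directed two-mode density, per-mode indegree
centralization, reciprocity, and the cross-mode desirability comparison
(Cohen's d with a two-sample randomization test).

Desirability is operationalized as indegree: the number of swipes a
user received.  Because the two modes have different sizes, degrees are
standardized by the opposite-mode size (the maximum possible number of
senders/receivers) wherever men and women are compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import DirectedBipartiteNetwork, reciprocal_matrix

__all__ = [
    "DegreeSummary",
    "GenderGapResult",
    "degrees",
    "standardize_degrees",
    "degree_summary",
    "density",
    "indegree_centralization",
    "reciprocity",
    "cohens_d_from_moments",
    "gender_gap",
]

MODES = ("women", "men", "all")
DIRECTIONS = ("in", "out")


class UndefinedMeasureError(ValueError):
    """A measure is undefined on this network (empty mode, zero ties...)."""


def _check_mode(mode: str, allow_all: bool = False) -> None:
    allowed = MODES if allow_all else MODES[:2]
    if mode not in allowed:
        raise ValueError(f"mode must be one of {allowed}, got {mode!r}")


def degrees(net: DirectedBipartiteNetwork, mode: str, direction: str) -> pd.Series:
    """Raw in/outdegrees of one mode (or ``"all"``), indexed by node id.

    Indegree of women = column sums of the male sender matrix ``M_M``;
    outdegree of women = row sums of ``M_F``; analogously for men.
    Isolates are included with degree 0.
    """
    _check_mode(mode, allow_all=True)
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be 'in' or 'out', got {direction!r}")
    if mode == "all":
        w = degrees(net, "women", direction)
        m = degrees(net, "men", direction)
        return pd.concat([w, m])
    if mode == "women":
        vec = net.M_M.sum(axis=0) if direction == "in" else net.M_F.sum(axis=1)
        index = net.women
    else:
        vec = net.M_F.sum(axis=0) if direction == "in" else net.M_M.sum(axis=1)
        index = net.men
    return pd.Series(np.asarray(vec, dtype=float), index=index, name=f"{mode}_{direction}degree")


def standardize_degrees(net: DirectedBipartiteNetwork, mode: str, direction: str) -> pd.Series:
    """Degrees divided by the opposite-mode size (maximum possible).

    A woman with standardized indegree 0.5 received swipes from exactly
    half of the male users.  Values lie in [0, 1].
    """
    _check_mode(mode, allow_all=True)
    if mode == "all":
        w = standardize_degrees(net, "women", direction)
        m = standardize_degrees(net, "men", direction)
        return pd.concat([w, m])
    opposite = net.n_men if mode == "women" else net.n_women
    if opposite == 0:
        raise UndefinedMeasureError(
            f"standardized degrees of {mode} undefined: opposite mode is empty"
        )
    return degrees(net, mode, direction) / opposite


def _skewness(x: np.ndarray) -> float:
    """Moment-based Fisher-Pearson g1 = m3 / m2^(3/2); 0 on zero variance."""
    x = np.asarray(x, dtype=float)
    if x.size == 0 or np.ptp(x) == 0:
        return 0.0
    return float(stats.skew(x, bias=True))


@dataclass(frozen=True)
class DegreeSummary:
    """Moment summary of a degree vector (one mode x one direction)."""

    mode: str
    direction: str
    standardized: bool
    n: int
    mean: float
    sd: float
    median: float
    skewness: float
    max: float
    total: float


def degree_summary(
    net: DirectedBipartiteNetwork,
    mode: str,
    direction: str,
    standardized: bool = False,
) -> DegreeSummary:
    """Mean/SD/median/skewness/max/total of a degree vector.

    Moments are computed over every node of the mode, isolates included
    as zeros; the SD uses the n-1 (sample) denominator.
    """
    vec = (
        standardize_degrees(net, mode, direction)
        if standardized
        else degrees(net, mode, direction)
    ).to_numpy()
    return DegreeSummary(
        mode=mode,
        direction=direction,
        standardized=standardized,
        n=int(vec.size),
        mean=float(vec.mean()) if vec.size else float("nan"),
        sd=float(vec.std(ddof=1)) if vec.size > 1 else 0.0,
        median=float(np.median(vec)) if vec.size else float("nan"),
        skewness=_skewness(vec),
        max=float(vec.max()) if vec.size else float("nan"),
        total=float(vec.sum()),
    )


def density(net: DirectedBipartiteNetwork) -> float:
    """Directed two-mode density.

    The ratio of observed to possible directed cross-mode ties:

        density = (sum M_F + sum M_M) / (n_women * n_men * 2)

    Each of the ``n_women * n_men`` pairs supports two directed ties,
    one per direction, hence the factor 2 in the denominator.
    """
    if net.n_women == 0 or net.n_men == 0:
        raise UndefinedMeasureError("density undefined: one mode is empty")
    return net.total_ties / (net.n_women * net.n_men * 2)


def indegree_centralization(
    net: DirectedBipartiteNetwork, mode: str, denominator: str = "star"
) -> float:
    """Freeman-style indegree centralization of one mode.

    Numerator: sum over the mode's nodes of (max observed indegree -
    node indegree) — the observed concentration of received swipes on
    the most popular node.

    Denominator (``denominator="star"``, the default): the same sum
    under the bipartite in-star in which one node of the mode receives
    a swipe from *every* opposite-mode user and the rest receive none,
    i.e. ``(mode size - 1) * opposite-mode size``.  This is the maximum
    concentration the bipartite constraint allows for these mode sizes.

    ``denominator="tie_preserving"`` instead evaluates the star sum on
    the most concentrated arrangement with the *observed* number of
    received ties T: the central node takes ``min(T, n_opposite)`` and
    any overflow is packed onto as few other nodes as possible.  The
    two variants agree when T <= n_opposite.
    """
    _check_mode(mode)
    n_mode = net.n_women if mode == "women" else net.n_men
    n_opp = net.n_men if mode == "women" else net.n_women
    if n_mode < 2:
        raise UndefinedMeasureError("centralization undefined for mode size < 2")
    if n_opp == 0:
        raise UndefinedMeasureError("centralization undefined: opposite mode empty")
    indeg = degrees(net, mode, "in").to_numpy()
    numer = float((indeg.max() - indeg).sum())
    if denominator == "star":
        denom = (n_mode - 1) * n_opp
    elif denominator == "tie_preserving":
        T = int(indeg.sum())
        star = np.zeros(n_mode)
        left = T
        for i in range(n_mode):
            star[i] = min(left, n_opp)
            left -= star[i]
            if left <= 0:
                break
        denom = float((star.max() - star).sum())
        if denom == 0:
            raise UndefinedMeasureError(
                "tie-preserving centralization undefined: star has no dispersion"
            )
    else:
        raise ValueError(f"unknown denominator variant {denominator!r}")
    return numer / denom


def reciprocity(net: DirectedBipartiteNetwork) -> float:
    """Fraction of swipes that are part of a match.

        reciprocity = 2 * sum(M_R) / (sum M_F + sum M_M)

    Each match contributes two of the network's directed ties, hence
    the factor 2; the value is 1 iff every tie has its reverse.
    """
    ties = net.total_ties
    if ties == 0:
        raise UndefinedMeasureError("reciprocity undefined on a tieless network")
    return 2 * int(reciprocal_matrix(net).sum()) / ties


def cohens_d_from_moments(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Cohen's d = (mean1 - mean2) / pooled SD, with (n-1)-weighted pooling.

    pooled SD = sqrt(((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2)).
    """
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if pooled == 0:
        raise UndefinedMeasureError("Cohen's d undefined: zero pooled SD")
    return float((mean1 - mean2) / pooled)


@dataclass(frozen=True)
class GenderGapResult:
    """Cross-mode desirability comparison on standardized indegrees."""

    mean_women: float
    mean_men: float
    cohens_d: float  # (women - men) / pooled SD
    p_value: float  # two-sided randomization p
    n_permutations: int
    seed: int


def gender_gap(
    net: DirectedBipartiteNetwork,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> GenderGapResult:
    """Compare women's and men's standardized indegrees.

    Cohen's d is (women - men) / pooled SD.  The attached two-sample
    randomization test permutes the gender labels over the pooled
    standardized-indegree vector (standardization is done once, with
    the true group sizes, before any relabelling) and reports the
    proportion of permutations whose absolute mean difference is at
    least the observed one (two-sided).
    """
    if seed is None:
        raise ValueError("gender_gap requires an explicit seed for reproducibility")
    if net.n_women == 0 or net.n_men == 0:
        raise UndefinedMeasureError("gender gap undefined: one mode is empty")
    w = standardize_degrees(net, "women", "in").to_numpy()
    m = standardize_degrees(net, "men", "in").to_numpy()
    d = cohens_d_from_moments(
        w.mean(), w.std(ddof=1), w.size, m.mean(), m.std(ddof=1), m.size
    )
    observed = abs(w.mean() - m.mean())
    pooled = np.concatenate([w, m])
    rng = np.random.default_rng(seed)
    count = 0
    nw = w.size
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        diff = abs(perm[:nw].mean() - perm[nw:].mean())
        if diff >= observed - 1e-12:
            count += 1
    return GenderGapResult(
        mean_women=float(w.mean()),
        mean_men=float(m.mean()),
        cohens_d=d,
        p_value=count / n_permutations,
        n_permutations=n_permutations,
        seed=seed,
    )
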