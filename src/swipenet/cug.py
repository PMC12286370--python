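"""Conditional uniform graph (CUG) tests for directed two-mode networks.

The null model conditions on network size and on every sender's
outdegree (hence on density): each replicate independently applies a
uniformly random permutation to the entries of every row of *both*
sender matrices.  Equivalently, each sender keeps the number of swipes
they sent but re-chooses the recipients uniformly without replacement.
Column sums (indegrees, i.e. desirability) are free to vary, so the
test asks whether an observed desirability-dependent pattern could
arise when senders ignore desirability entirely.

Statistics supported:

* tie-level desirability gaps (mean over ties of sender's standardized
  indegree minus receiver's), in either direction, optionally weighted
  so each sender contributes total weight one;
* the reciprocated-pair gap (male point of view);
* reciprocity; per-mode indegree centralization; total ties (a
  conserved sanity check).

Empirical p-values count simulated values on each side of the observed
one, with ties counted on both sides and no (+1) correction, so a
statistic outside the whole simulated range reports exactly 0.00/1.00.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import DirectedBipartiteNetwork
from .descriptives import UndefinedMeasureError

__all__ = [
    "CUGResult",
    "permute_rows",
    "tie_gap",
    "reciprocal_gap",
    "empirical_pvalues",
    "cug_test",
    "CUG_STATISTICS",
]


def permute_rows(matrix: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute the entries within each row, uniformly.

    Row sums (outdegrees) are preserved exactly; column sums generally
    change.  Implemented by sorting random keys per row, which draws a
    uniform permutation of each row's entries.
    """
    matrix = np.asarray(matrix)
    if matrix.size == 0:
        return matrix.copy()
    keys = rng.random(matrix.shape)
    order = np.argsort(keys, axis=1)
    return np.take_along_axis(matrix, order, axis=1)


# -- tie-level statistics (matrix closed forms, no edge loops) ------------


def _std_indegrees(M_F: np.ndarray, M_M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(women's, men's) standardized indegree vectors from raw matrices."""
    n_w, n_m = M_F.shape
    std_w = M_M.sum(axis=0) / n_m  # women's indegree / n_men
    std_m = M_F.sum(axis=0) / n_w  # men's indegree / n_women
    return std_w, std_m


def _gap_from_matrices(
    M_F: np.ndarray, M_M: np.ndarray, direction: str, weighted: bool
) -> float:
    std_w, std_m = _std_indegrees(M_F, M_M)
    if direction == "men_to_women":
        S, s_send, s_recv = M_M, std_m, std_w
    elif direction == "women_to_men":
        S, s_send, s_recv = M_F, std_w, std_m
    else:
        raise ValueError(f"direction must be 'men_to_women' or 'women_to_men', got {direction!r}")
    out = S.sum(axis=1).astype(float)
    total = out.sum()
    if total == 0:
        raise UndefinedMeasureError(f"no ties in direction {direction}")
    if weighted:
        # each sender's ties carry weight 1/outdegree, so every active
        # sender contributes total weight exactly 1
        active = out > 0
        recv_mean = (S[active] @ s_recv) / out[active]
        return float(np.mean(s_send[active] - recv_mean))
    num = float((out * s_send).sum() - (S.sum(axis=0) * s_recv).sum())
    return num / total


def tie_gap(
    net: DirectedBipartiteNetwork, direction: str, weighted: bool = False
) -> float:
    """Mean desirability gap over the ties of one sending mode.

    For each swipe, the gap is the sender's standardized indegree minus
    the receiver's; negative values mean senders pursue receivers more
    desirable than themselves (aspirational pursuit).  With
    ``weighted=True`` each tie carries weight ``1/outdegree(sender)``,
    so prolific swipers do not dominate the mean.
    """
    return _gap_from_matrices(net.M_F, net.M_M, direction, weighted)


def _reciprocal_gap_from_matrices(M_F: np.ndarray, M_M: np.ndarray) -> float:
    R = M_F * M_M.T  # female-row orientation match matrix
    n_pairs = int(R.sum())
    if n_pairs == 0:
        raise UndefinedMeasureError("no reciprocated pairs")
    std_w, std_m = _std_indegrees(M_F, M_M)
    # male point of view: man's standardized indegree - woman's
    num = float((R.sum(axis=0) * std_m).sum() - (R.sum(axis=1) * std_w).sum())
    return num / n_pairs


def reciprocal_gap(net: DirectedBipartiteNetwork) -> float:
    """Mean desirability gap over matched pairs, male point of view.

    Mean over reciprocated pairs of (man's standardized indegree -
    woman's standardized indegree).  Matched pairs are mutual, so only
    the magnitude is interpretable; the male orientation fixes the sign
    convention.
    """
    return _reciprocal_gap_from_matrices(net.M_F, net.M_M)


def empirical_pvalues(observed: float, simulated: np.ndarray) -> tuple[float, float]:
    """(Pr(sim <= obs), Pr(sim >= obs)) over the simulated distribution.

    Ties with the observed value count on both sides, so the two
    proportions sum to at least 1.  No small-sample correction is
    applied: values outside the simulated range give exactly 0 and 1.
    """
    simulated = np.asarray(simulated, dtype=float)
    simulated = simulated[~np.isnan(simulated)]
    if simulated.size == 0:
        raise ValueError("empirical_pvalues requires a non-empty simulated vector")
    return (
        float(np.mean(simulated <= observed)),
        float(np.mean(simulated >= observed)),
    )


@dataclass(frozen=True)
class CUGResult:
    """Outcome of one conditional uniform graph test."""

    statistic: str
    weighted: bool
    observed: float
    simulated: np.ndarray = field(repr=False)
    n_sims: int
    n_missing: int  # replicates where the statistic was undefined
    p_le: float  # Pr(sim <= observed)
    p_ge: float  # Pr(sim >= observed)
    sim_mean: float
    sim_sd: float
    seed: int

    def summary(self) -> dict:
        """Flat dict of the headline numbers (one report-table row)."""
        return {
            "statistic": self.statistic,
            "weighted": self.weighted,
            "obs_mean": self.observed,
            "p_le_obs": self.p_le,
            "p_ge_obs": self.p_ge,
            "sim_mean": self.sim_mean,
            "sim_sd": self.sim_sd,
            "n_sims": self.n_sims,
            "n_missing": self.n_missing,
            "seed": self.seed,
        }


def _stat_centralization(M_F, M_M, mode):
    indeg = (M_M if mode == "women" else M_F).sum(axis=0).astype(float)
    n_mode = indeg.size
    n_opp = M_M.shape[0] if mode == "women" else M_F.shape[0]
    if n_mode < 2 or n_opp == 0:
        raise UndefinedMeasureError("centralization undefined at this size")
    return float((indeg.max() - indeg).sum()) / ((n_mode - 1) * n_opp)


def _stat_reciprocity(M_F, M_M):
    ties = int(M_F.sum()) + int(M_M.sum())
    if ties == 0:
        raise UndefinedMeasureError("reciprocity undefined on a tieless network")
    return 2 * int((M_F * M_M.T).sum()) / ties


CUG_STATISTICS = {
    "gap_men_to_women": lambda F, M, w: _gap_from_matrices(F, M, "men_to_women", w),
    "gap_women_to_men": lambda F, M, w: _gap_from_matrices(F, M, "women_to_men", w),
    "reciprocal_gap": lambda F, M, w: _reciprocal_gap_from_matrices(F, M),
    "reciprocity": lambda F, M, w: _stat_reciprocity(F, M),
    "centralization_women": lambda F, M, w: _stat_centralization(F, M, "women"),
    "centralization_men": lambda F, M, w: _stat_centralization(F, M, "men"),
    "total_ties": lambda F, M, w: float(F.sum() + M.sum()),
}


def cug_test(
    net: DirectedBipartiteNetwork,
    statistic: str,
    n_sims: int = 1000,
    seed: int | None = None,
    weighted: bool = False,
) -> CUGResult:
    """Run a CUG test of one statistic against the row-permutation null.

    Each of the ``n_sims`` replicates permutes the rows of both sender
    matrices independently (outdegrees and total ties are preserved,
    and this is asserted per replicate) and recomputes the statistic,
    including the standardized indegrees it depends on, from the
    permuted matrices.  Replicates on which the statistic is undefined
    (e.g. a permutation with no reciprocated pair) are recorded as
    missing and excluded from the p-value denominator.

    A seed is required: the simulated distribution is Monte Carlo and
    must be reproducible.
    """
    if seed is None:
        raise ValueError("cug_test requires an explicit seed for reproducibility")
    if statistic not in CUG_STATISTICS:
        raise ValueError(
            f"unknown statistic {statistic!r}; choose from {sorted(CUG_STATISTICS)}"
        )
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    fn = CUG_STATISTICS[statistic]
    observed = fn(net.M_F, net.M_M, weighted)

    rng = np.random.default_rng(seed)
    out_f = net.M_F.sum(axis=1)
    out_m = net.M_M.sum(axis=1)
    sims = np.full(n_sims, np.nan)
    for k in range(n_sims):
        PF = permute_rows(net.M_F, rng)
        PM = permute_rows(net.M_M, rng)
        assert (PF.sum(axis=1) == out_f).all() and (PM.sum(axis=1) == out_m).all()
        try:
            sims[k] = fn(PF, PM, weighted)
        except UndefinedMeasureError:
            pass  # left as NaN -> missing replicate

    valid = sims[~np.isnan(sims)]
    n_missing = n_sims - valid.size
    if valid.size == 0:
        raise UndefinedMeasureError(
            f"statistic {statistic!r} undefined on every replicate"
        )
    p_le, p_ge = empirical_pvalues(observed, valid)
    return CUGResult(
        statistic=statistic,
        weighted=weighted,
        observed=float(observed),
        simulated=sims,
        n_sims=n_sims,
        n_missing=n_missing,
        p_le=p_le,
        p_ge=p_ge,
        sim_mean=float(valid.mean()),
        sim_sd=float(valid.std(ddof=1)) if valid.size > 1 else 0.0,
        seed=seed,
    )
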