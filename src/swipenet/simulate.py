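"""Synthetic two-sided swipe-market generator.

Emulates the statistical structure of a heterosexual dating-app
market so that every measure and test in the package can run without
proprietary data: a skewed gender ratio, right-skewed activity
(outdegree) with tunable dispersion, heavy-tailed latent desirability,
*aspirational pursuit* (senders biased toward high-desirability
receivers) controlled by a single coefficient per mode, and
desirability-gap-dependent reciprocation.

Generative model, per market:

1. every node gets a latent desirability score ``z`` (normal or, for
   heavy-tailed modes, lognormal; centred within mode);
2. every sender draws an intended outdegree from a negative-binomial
   count law (mean, dispersion ``k``; ``k = 0`` means a fixed count),
   truncated to the opposite-mode size;
3. the sender picks that many distinct receivers with probability
   proportional to ``exp(aspiration * z_receiver)`` (softmax sampling
   without replacement via the Gumbel-top-k trick) — ``aspiration = 0``
   is uniform choice, i.e. exactly the row-permutation null;
4. the receiver of each first swipe independently swipes back with
   probability ``sigmoid(intercept + slope * (z_initiator -
   z_receiver))``; a positive slope makes receivers choosier toward
   less desirable initiators, the non-reciprocity mechanism.

All randomness flows from one seeded generator; the same seed yields
an identical market.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import yaml
from scipy.special import expit

from .network import DirectedBipartiteNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ModeConfig",
    "MarketConfig",
    "SyntheticMarket",
    "generate_market",
    "recover_mechanism",
    "random_fixed_tie_network",
    "network_from_female_indegrees",
    "load_preset",
    "PRESETS",
]

PRESETS = ("brno_like", "prague_like", "null")


@dataclass(frozen=True)
class ModeConfig:
    """Generative parameters for one mode (gender) of the market.

    Parameters
    ----------
    n
        Number of users in the mode.
    activity_mean
        Mean intended outdegree (swipes sent).
    activity_dispersion
        Negative-binomial dispersion ``k`` (variance = mean +
        mean^2/k); smaller k = more right-skew.  ``k = 0`` makes every
        sender send exactly ``round(activity_mean)`` swipes.
    desirability
        ``"normal"`` or ``"lognormal"`` (heavy tail) latent score law.
    desirability_scale
        Scale (sigma) of the latent score distribution.
    aspiration
        Softmax coefficient on the receiver's latent score; 0 = choose
        uniformly, > 0 = aspirational pursuit.
    """

    n: int
    activity_mean: float
    activity_dispersion: float = 1.0
    desirability: str = "normal"
    desirability_scale: float = 1.0
    aspiration: float = 0.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("mode size must be >= 1")
        if self.activity_mean < 0 or self.activity_dispersion < 0:
            raise ValueError("activity parameters must be non-negative")
        if self.desirability not in ("normal", "lognormal"):
            raise ValueError(f"unknown desirability law {self.desirability!r}")


@dataclass(frozen=True)
class MarketConfig:
    """Full generative description of a synthetic swipe market."""

    women: ModeConfig
    men: ModeConfig
    recip_intercept: float = -1.0
    recip_slope: float = 0.0
    seed: int | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MarketConfig":
        d = dict(d)
        d["women"] = ModeConfig(**d["women"])
        d["men"] = ModeConfig(**d["men"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "MarketConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class SyntheticMarket:
    """A generated market: the network, its latent scores, its recipe."""

    network: DirectedBipartiteNetwork
    scores: dict  # node id -> latent desirability
    config: MarketConfig


def load_preset(name: str) -> MarketConfig:
    """Load one of the shipped preset configurations by name."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {PRESETS}")
    ref = resources.files("swipenet").joinpath(f"presets/{name}.yaml")
    with ref.open() as fh:
        return MarketConfig.from_dict(yaml.safe_load(fh))


def _draw_scores(mode: ModeConfig, rng: np.random.Generator) -> np.ndarray:
    if mode.desirability == "lognormal":
        z = rng.lognormal(mean=0.0, sigma=mode.desirability_scale, size=mode.n)
    else:
        z = rng.normal(loc=0.0, scale=mode.desirability_scale, size=mode.n)
    return z - z.mean()  # scores are relative standing within the mode


def _draw_counts(mode: ModeConfig, n_opp: int, rng: np.random.Generator) -> np.ndarray:
    if mode.activity_dispersion == 0:
        counts = np.full(mode.n, int(round(mode.activity_mean)))
    else:
        k = mode.activity_dispersion
        p = k / (k + mode.activity_mean) if mode.activity_mean > 0 else 1.0
        counts = rng.negative_binomial(k, p, size=mode.n)
    if (counts > n_opp).any():
        logger.warning(
            "%d intended outdegree(s) exceed opposite-mode size %d; truncated",
            int((counts > n_opp).sum()),
            n_opp,
        )
        counts = np.minimum(counts, n_opp)
    return counts.astype(int)


def _choose_receivers(
    counts: np.ndarray,
    receiver_scores: np.ndarray,
    aspiration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Softmax sampling without replacement for every sender at once.

    Adding i.i.d. Gumbel noise to the log-weights and taking the top-k
    keys draws k receivers without replacement from the softmax
    (Plackett-Luce) distribution with weights exp(aspiration * z).
    """
    n_s, n_r = counts.size, receiver_scores.size
    M = np.zeros((n_s, n_r), dtype=np.int8)
    if n_s == 0 or n_r == 0:
        return M
    keys = aspiration * receiver_scores[None, :] + rng.gumbel(size=(n_s, n_r))
    order = np.argsort(-keys, axis=1)
    for i, c in enumerate(counts):
        if c:
            M[i, order[i, :c]] = 1
    return M


def generate_market(config: MarketConfig, seed: int | None = None) -> SyntheticMarket:
    """Generate one synthetic market from a configuration.

    ``seed`` overrides ``config.seed``; one of the two must be set.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("generate_market requires a seed (argument or config.seed)")
    rng = np.random.default_rng(seed)

    z_w = _draw_scores(config.women, rng)
    z_m = _draw_scores(config.men, rng)

    counts_w = _draw_counts(config.women, config.men.n, rng)
    counts_m = _draw_counts(config.men, config.women.n, rng)

    # first swipes
    F = _choose_receivers(counts_w, z_m, config.women.aspiration, rng)  # women -> men
    M = _choose_receivers(counts_m, z_w, config.men.aspiration, rng)  # men -> women

    # responses: receiver of a first swipe may add the reverse tie
    p_resp_to_men = expit(config.recip_intercept + config.recip_slope * (z_m[:, None] - z_w[None, :]))
    accept_w = (rng.random(M.shape) < p_resp_to_men).astype(np.int8)  # women answering men
    p_resp_to_women = expit(config.recip_intercept + config.recip_slope * (z_w[:, None] - z_m[None, :]))
    accept_m = (rng.random(F.shape) < p_resp_to_women).astype(np.int8)  # men answering women

    # both response layers are driven by the *first* swipes only
    F0, M0 = F, M
    F = F0 | (M0 * accept_w).T  # women answering men who first-swiped them
    M = M0 | (F0 * accept_m).T  # men answering women who first-swiped them

    women = [f"w{i+1}" for i in range(config.women.n)]
    men = [f"m{i+1}" for i in range(config.men.n)]
    net = DirectedBipartiteNetwork(women, men, F, M)
    scores = {**dict(zip(women, z_w)), **dict(zip(men, z_m))}
    return SyntheticMarket(network=net, scores=scores, config=config)


def random_fixed_tie_network(
    n_women: int, n_men: int, n_ties: int, seed: int
) -> DirectedBipartiteNetwork:
    """Uniformly random network with an *exact* total tie count.

    Places ``n_ties`` distinct directed ties uniformly over the
    ``2 * n_women * n_men`` possible cells of the two matrices.  Useful
    for reconstructing a market from published aggregate counts: any
    measure that depends only on node and tie totals (mean degree,
    density) is then exact regardless of the placement.
    """
    cells = 2 * n_women * n_men
    if n_ties > cells:
        raise ValueError(f"{n_ties} ties do not fit in {cells} cells")
    rng = np.random.default_rng(seed)
    flat = rng.choice(cells, size=n_ties, replace=False)
    M_F = np.zeros(n_women * n_men, dtype=np.int8)
    M_M = np.zeros(n_men * n_women, dtype=np.int8)
    first = flat[flat < n_women * n_men]
    second = flat[flat >= n_women * n_men] - n_women * n_men
    M_F[first] = 1
    M_M[second] = 1
    return DirectedBipartiteNetwork(
        women=[f"w{i+1}" for i in range(n_women)],
        men=[f"m{i+1}" for i in range(n_men)],
        M_F=M_F.reshape(n_women, n_men),
        M_M=M_M.reshape(n_men, n_women),
    )


def network_from_female_indegrees(indegrees, n_men: int) -> DirectedBipartiteNetwork:
    """Network realizing a prescribed female indegree sequence.

    Column ``j`` of the male sender matrix gets ``indegrees[j]`` ones
    (men 1..d_j swipe woman j); the female sender matrix is empty.
    Useful for reconstructing indegree-driven measures (centralization)
    from published maxima and totals.
    """
    indegrees = np.asarray(indegrees, dtype=int)
    if (indegrees < 0).any() or (indegrees > n_men).any():
        raise ValueError("each indegree must lie in [0, n_men]")
    n_w = indegrees.size
    M_M = np.zeros((n_men, n_w), dtype=np.int8)
    for j, d in enumerate(indegrees):
        M_M[:d, j] = 1
    return DirectedBipartiteNetwork(
        women=[f"w{i+1}" for i in range(n_w)],
        men=[f"m{i+1}" for i in range(n_men)],
        M_F=np.zeros((n_w, n_men), dtype=np.int8),
        M_M=M_M,
    )


def recover_mechanism(
    alphas,
    base_config: MarketConfig,
    n_reps: int = 10,
    n_sims: int = 200,
    seed: int = 0,
    alpha_level: float = 0.05,
):
    """Power/calibration sweep over the male aspiration coefficient.

    For each value in ``alphas``, generates ``n_reps`` markets with the
    male aspiration set to that value, computes the men->women tie gap
    and its CUG test, and reports the mean observed gap and the
    fraction of replicates with ``Pr(<= obs) <= alpha_level``.

    Returns a pandas DataFrame with columns ``alpha``, ``mean_tie_gap``
    and ``rejection_rate``.
    """
    import pandas as pd
    from dataclasses import replace

    from .cug import cug_test, tie_gap

    rows = []
    rng = np.random.default_rng(seed)
    for a in alphas:
        cfg = replace(base_config, men=replace(base_config.men, aspiration=float(a)))
        gaps, rejects = [], []
        for _ in range(n_reps):
            s = int(rng.integers(2**31 - 1))
            market = generate_market(cfg, seed=s)
            gaps.append(tie_gap(market.network, "men_to_women"))
            res = cug_test(
                market.network, "gap_men_to_women", n_sims=n_sims, seed=s + 1
            )
            rejects.append(res.p_le <= alpha_level)
        rows.append(
            {
                "alpha": float(a),
                "mean_tie_gap": float(np.mean(gaps)),
                "rejection_rate": float(np.mean(rejects)),
            }
        )
    return pd.DataFrame(rows)
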