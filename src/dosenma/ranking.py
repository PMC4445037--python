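"""Treatment rankings from posterior draws: rank probabilities and SUCRA.

Each posterior draw induces an ordering of the treatments by their basic
parameters (the reference sits at 0).  Tallying ranks across draws gives the
rank-probability matrix; its cumulative sums give the cumulative ranking
curves whose average over the first T-1 ranks is the SUCRA (surface under
the cumulative ranking curve): 100% for a treatment certain to be best, 0%
for one certain to be worst.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nma import NMAPosterior


@dataclass(frozen=True)
class RankResult:
    treatments: tuple[str, ...]
    direction: str  # "lower_is_better" | "higher_is_better"
    rank_matrix: np.ndarray  # (T, T): P(treatment t has rank j+1)
    cumulative: np.ndarray  # row-wise cumulative sums
    sucra: np.ndarray  # percent, (T,)
    p_best: np.ndarray  # (T,)

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            t: {"sucra": float(self.sucra[i]), "p_best": float(self.p_best[i])}
            for i, t in enumerate(self.treatments)
        }


def sucra(rank_matrix: np.ndarray) -> np.ndarray:
    """SUCRA (percent) per treatment from a rank-probability matrix.

    SUCRA_t = 100 * sum_{j=1}^{T-1} cum_{t,j} / (T - 1), where cum is the
    cumulative rank probability.
    """
    rank_matrix = np.asarray(rank_matrix, dtype=float)
    T = rank_matrix.shape[1]
    if T < 2:
        raise ValueError("need at least two treatments")
    cum = np.cumsum(rank_matrix, axis=1)
    return 100.0 * cum[:, : T - 1].sum(axis=1) / (T - 1)


def rank_probabilities(
    post: NMAPosterior,
    direction: str = "lower_is_better",
    tie_seed: int = 0,
) -> RankResult:
    """Rank treatments in every draw and tally rank probabilities.

    For effectiveness outcomes lower SMD is better; for harms lower (log-)OR
    is better; ``direction="higher_is_better"`` reverses the ordering.  Ties
    within a draw are broken uniformly at random from a dedicated seeded
    stream so results are reproducible.
    """
    if direction not in ("lower_is_better", "higher_is_better"):
        raise ValueError(f"unknown direction {direction!r}")
    effects = post.basic_draws()  # (N, T), reference included at 0
    if direction == "higher_is_better":
        effects = -effects
    n, T = effects.shape
    rng = np.random.default_rng(tie_seed)
    tie_break = rng.random(effects.shape)
    order = np.lexsort((tie_break, effects))  # sorts each row, best first
    ranks = np.empty_like(order)
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(T)[None, :]

    counts = np.zeros((T, T))
    for t in range(T):
        counts[t] = np.bincount(ranks[:, t], minlength=T)
    rank_matrix = counts / n
    cum = np.cumsum(rank_matrix, axis=1)
    return RankResult(
        treatments=post.treatments,
        direction=direction,
        rank_matrix=rank_matrix,
        cumulative=cum,
        sucra=sucra(rank_matrix),
        p_best=rank_matrix[:, 0].copy(),
    )
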