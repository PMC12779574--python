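"""Functional vulnerability and resistance under simulated species loss.

Vulnerability is the negated Spearman rank correlation between each member's
sensitivity score and its redundancy contribution: positive values mean the
most extinction-prone species provide the most unique function.  Resistance
is measured from extinction curves — relative functional richness (FD of the
survivors over FD of the intact assemblage, on the shared grid) as species
are removed either *actively* (in strict order of sensitivity, high to low,
ties broken at random across replicates) or *passively* (0-2 probabilistic
removals per time step, removal probability increasing with sensitivity
rank).  Curves are standardised to start at (0, 1) and end at (1, 0); the
area under the curve and the half-life t_1/2 (proportion removed at which
half the FD is gone) summarise resistance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .tpd import AssemblageTPD


def functional_vulnerability(
    species_redundancy: Mapping[str, float],
    sensitivity: Mapping[str, float],
) -> float:
    """Negated Spearman correlation of sensitivity vs redundancy contribution.

    Requires at least 3 species present in both maps; ties receive average
    ranks.  Returns NaN (with no exception) when either vector is constant,
    since the correlation is undefined there.
    """
    common = [s for s in species_redundancy if s in sensitivity]
    if len(common) < 3:
        raise ValueError("need at least 3 species with both values")
    red = np.array([species_redundancy[s] for s in common])
    sens = np.array([sensitivity[s] for s in common])
    if np.ptp(red) == 0 or np.ptp(sens) == 0:
        import warnings

        warnings.warn("constant input vector: vulnerability undefined", stacklevel=2)
        return float("nan")
    rho = stats.spearmanr(sens, red).statistic
    return float(-rho)


@dataclass
class ExtinctionCurve:
    """Standardised FD-loss trajectory; ``points`` columns are (prop_removed, rel_fd)."""

    assemblage_id: str
    scheme: str
    mode: str  # "active" | "passive"
    points: np.ndarray  # (k, 2), first row (0, 1), last (1, 0)
    replicates: int
    rng_seed: int | None = None
    replicate_points: list[np.ndarray] | None = None


class _RichnessTracker:
    """Incrementally tracks union-support richness as members are removed."""

    def __init__(self, atpd: AssemblageTPD):
        self.cell_idx = atpd.cell_idx
        self.positions = {sid: atpd.member_positions(sid) for sid in atpd.member_ids}
        self.reset()

    def reset(self):
        self.counts = np.zeros(len(self.cell_idx), dtype=np.int64)
        for pos in self.positions.values():
            self.counts[pos] += 1
        self.richness = int(np.count_nonzero(self.counts))

    def remove(self, sid: str):
        pos = self.positions[sid]
        self.counts[pos] -= 1
        self.richness -= int(np.count_nonzero(self.counts[pos] == 0))


def _removal_order(scores: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Descending-score order; ties permuted uniformly at random."""
    jitter = rng.random(len(scores))
    return np.lexsort((jitter, -scores))


def active_extinction_curve(
    atpd: AssemblageTPD,
    scores: Mapping[str, float],
    scheme: str = "general_traits",
    n_tiebreak_reps: int = 100,
    rng_seed: int | None = 0,
) -> ExtinctionCurve:
    """Sequential removal in descending sensitivity order.

    ``rel_fd`` after j removals is the richness of the union support of
    survivors over the intact richness; curves from tie-break replicates are
    averaged pointwise.  With no tied scores a single pass is exact and only
    one replicate is run.
    """
    n = len(atpd.member_ids)
    if n < 2:
        raise ValueError("need at least 2 members")
    s = np.array([scores[sid] for sid in atpd.member_ids], dtype=float)
    reps = 1 if len(np.unique(s)) == n else n_tiebreak_reps
    rng = np.random.default_rng(rng_seed)
    tracker = _RichnessTracker(atpd)
    fd0 = tracker.richness
    acc = np.zeros(n + 1)
    for _ in range(reps):
        tracker.reset()
        order = _removal_order(s, rng)
        rel = [1.0]
        for j in order:
            tracker.remove(atpd.member_ids[j])
            rel.append(tracker.richness / fd0)
        acc += np.array(rel)
    rel_mean = acc / reps
    rel_mean[-1] = 0.0  # all species removed: no support left
    points = np.column_stack([np.arange(n + 1) / n, rel_mean])
    return ExtinctionCurve(
        assemblage_id=atpd.assemblage_id, scheme=scheme, mode="active",
        points=points, replicates=reps, rng_seed=rng_seed,
    )


def _rank_removal_probs(scores: np.ndarray) -> np.ndarray:
    """Map scores to per-step removal probabilities rank/(n+1), ties averaged."""
    ranks = stats.rankdata(scores, method="average")
    return ranks / (len(scores) + 1)


def passive_extinction_curve(
    atpd: AssemblageTPD,
    scores: Mapping[str, float],
    scheme: str = "general_traits",
    n_reps: int = 100,
    rng_seed: int | None = 0,
    max_removals_per_step: int = 2,
    lattice: int = 100,
    keep_replicates: bool = False,
    prob_fn=None,
) -> ExtinctionCurve:
    """Probability-weighted species loss, 0-2 removals per time step.

    Per replicate, each surviving species is examined every step and removed
    with probability rank(score)/(n_surviving + 1) (override the map with
    ``prob_fn``, a callable scores -> probabilities over survivors); when
    more than ``max_removals_per_step`` removals are drawn, that many are
    sampled without replacement from the drawn set.  Steps with no removal
    extend the time axis, so tolerant assemblages hold FD longer; each
    replicate's step curve is rescaled to [0, 1] in time and replicates are
    averaged on a common lattice.  With ``keep_replicates`` the raw
    (time step, rel_fd) trajectories are retained per replicate.
    """
    n = len(atpd.member_ids)
    if n < 2:
        raise ValueError("need at least 2 members")
    s_all = np.array([scores[sid] for sid in atpd.member_ids], dtype=float)
    rng = np.random.default_rng(rng_seed)
    tracker = _RichnessTracker(atpd)
    fd0 = tracker.richness
    grid_x = np.linspace(0.0, 1.0, lattice + 1)
    acc = np.zeros(lattice + 1)
    reps_pts = [] if keep_replicates else None
    prob_map = prob_fn or _rank_removal_probs
    for _ in range(n_reps):
        tracker.reset()
        alive = list(range(n))
        times, rels = [0.0], [1.0]
        t = 0
        while alive:
            t += 1
            p = prob_map(s_all[alive])
            drawn = np.nonzero(rng.random(len(alive)) < p)[0]
            if len(drawn) > max_removals_per_step:
                drawn = rng.choice(drawn, size=max_removals_per_step, replace=False)
            for d in sorted(drawn, reverse=True):
                tracker.remove(atpd.member_ids[alive[d]])
                del alive[d]
            times.append(float(t))
            rels.append(tracker.richness / fd0)
        raw_times = np.array(times)
        scaled = raw_times / raw_times[-1]
        rels = np.array(rels)
        rels[-1] = 0.0
        # step-function interpolation (previous value holds until the next step)
        idx = np.clip(np.searchsorted(scaled, grid_x, side="right") - 1, 0, len(rels) - 1)
        acc += rels[idx]
        if keep_replicates:
            reps_pts.append(np.column_stack([raw_times, rels]))
    mean = acc / n_reps
    mean[0], mean[-1] = 1.0, 0.0
    points = np.column_stack([grid_x, mean])
    return ExtinctionCurve(
        assemblage_id=atpd.assemblage_id, scheme=scheme, mode="passive",
        points=points, replicates=n_reps, rng_seed=rng_seed,
        replicate_points=reps_pts,
    )


def curve_auc(curve: ExtinctionCurve) -> float:
    """Trapezoidal area under the standardised extinction curve."""
    x, y = curve.points[:, 0], curve.points[:, 1]
    return float(np.trapezoid(y, x))


def curve_half_life(curve: ExtinctionCurve) -> float:
    """Smallest proportion removed at which rel_fd reaches 0.5 (interpolated).

    Returns 1.0 when the curve stays above 0.5 until the terminal point.
    """
    x, y = curve.points[:, 0], curve.points[:, 1]
    below = np.nonzero(y <= 0.5)[0]
    if len(below) == 0:
        return 1.0
    i = below[0]
    if i == 0 or y[i] == 0.5:
        return float(x[i])
    x0, y0, x1, y1 = x[i - 1], y[i - 1], x[i], y[i]
    if y0 == y1:
        return float(x1)
    return float(x0 + (y0 - 0.5) / (y0 - y1) * (x1 - x0))


__all__ = [
    "ExtinctionCurve",
    "functional_vulnerability", "active_extinction_curve",
    "passive_extinction_curve", "curve_auc", "curve_half_life",
]
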