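"""Functional richness and redundancy from assemblage TPDs.

Functional richness (FD) is the number of grid cells an assemblage's TPD
occupies with probability > 0 after trimming — a cell count, convertible to a
volume via the grid's cell volume, and independent of abundance.  Functional
redundancy is the abundance-weighted mean number of *surplus* species per
occupied cell: R = sum_c p_c * (M_c - 1), where p_c is the assemblage
probability in cell c and M_c counts member species whose trimmed TPD covers
c.  Relative redundancy divides by N - 1 so complete overlap of N species
scores 1.  A species' redundancy contribution is the drop in R when it is
removed (with mixture weights renormalised over the remainder).
"""

from __future__ import annotations

import numpy as np

from .tpd import AssemblageTPD, SpeciesTPD, assemblage_tpd


def functional_richness(atpd: AssemblageTPD) -> int:
    """Number of grid cells with occupancy probability > 0."""
    return int(np.count_nonzero(atpd.probs > 0))


def _occupancy_counts(atpd: AssemblageTPD) -> np.ndarray:
    """M_c: number of member species covering each cell of the assemblage support."""
    counts = np.zeros(len(atpd.cell_idx), dtype=np.int64)
    for sid in atpd.member_ids:
        counts[atpd.member_positions(sid)] += 1
    return counts


def functional_redundancy(atpd: AssemblageTPD) -> tuple[float, float]:
    """(redundancy, relative_redundancy) for an assemblage TPD.

    Redundancy is ``sum_c p_c * M_c - 1`` (0 for a single-species assemblage);
    relative redundancy is redundancy over N - 1, reported as 0.0 for N = 1.
    """
    n = len(atpd.member_ids)
    m = _occupancy_counts(atpd)
    r = float(atpd.probs @ m) - 1.0
    rel = r / (n - 1) if n > 1 else 0.0
    return r, rel


def species_redundancy_contribution(atpd: AssemblageTPD, species_id: str) -> float:
    """Change in assemblage redundancy when the focal species is removed.

    The reduced assemblage renormalises abundance weights over the remaining
    members, keeping its TPD a proper probability function.
    """
    if species_id not in atpd.member_ids:
        raise ValueError(f"{species_id} is not a member of {atpd.assemblage_id}")
    if len(atpd.member_ids) < 2:
        raise ValueError("cannot remove the only member of an assemblage")
    r_full, _ = functional_redundancy(atpd)
    members = [
        (atpd.member_tpds[sid], w)
        for sid, w in zip(atpd.member_ids, atpd.weights)
        if sid != species_id
    ]
    reduced = assemblage_tpd(atpd.assemblage_id, members)
    r_reduced, _ = functional_redundancy(reduced)
    return r_full - r_reduced


def all_species_redundancy_contributions(atpd: AssemblageTPD) -> dict[str, float]:
    """Redundancy contribution of every member, computed without rebuilding mixtures.

    Uses the closed form R_without_i = sum_c p'_c (M'_c - 1) with
    p'_c = (p_c - w_i t_ic) / (1 - w_i) and M'_c = M_c - [t_ic > 0]; equals
    :func:`species_redundancy_contribution` per species but runs in
    O(N * support) total.
    """
    n = len(atpd.member_ids)
    if n < 2:
        raise ValueError("need at least 2 members")
    m = _occupancy_counts(atpd)
    r_full = float(atpd.probs @ m) - 1.0
    out: dict[str, float] = {}
    for sid, w_i in zip(atpd.member_ids, atpd.weights):
        t = atpd.member_tpds[sid]
        pos = atpd.member_positions(sid)
        if w_i >= 1.0 - 1e-15:
            raise ValueError(f"{sid} carries all abundance; removal leaves nothing")
        # sum over cells of p'_c * (M'_c - 1), exploiting sparsity of the focal TPD:
        # off the focal support p' = p / (1 - w_i) and M' = M; on it
        # p' = (p - w_i t) / (1 - w_i) and M' = M - 1.
        base = float(atpd.probs @ (m - 1))
        p_prime_focal = (atpd.probs[pos] - w_i * t.probs) / (1.0 - w_i)
        sum_off = (base - float(atpd.probs[pos] @ (m[pos] - 1))) / (1.0 - w_i)
        sum_on = float(p_prime_focal @ (m[pos] - 2))
        out[sid] = r_full - (sum_off + sum_on)
    return out


__all__ = [
    "functional_richness", "functional_redundancy",
    "species_redundancy_contribution", "all_species_redundancy_contributions",
]
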