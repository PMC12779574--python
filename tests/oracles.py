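"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here works on dense full-grid arrays by direct summation or
definition-level recomputation, deliberately sharing no code with the
package's sparse implementations.
"""

from __future__ import annotations

import numpy as np

from avistability.tpd import AssemblageTPD, GridSpec, SpeciesTPD


def dense(tpd, n_cells: int) -> np.ndarray:
    """Full-grid probability vector for a sparse species/assemblage TPD."""
    v = np.zeros(n_cells)
    v[tpd.cell_idx] = tpd.probs
    return v


def oracle_richness(atpd: AssemblageTPD, n_cells: int) -> int:
    """Cell-by-cell count of cells occupied by the assemblage mixture."""
    mix = np.zeros(n_cells)
    for sid, w in zip(atpd.member_ids, atpd.weights):
        mix += w * dense(atpd.member_tpds[sid], n_cells)
    return int((mix > 0).sum())


def oracle_redundancy(atpd: AssemblageTPD, n_cells: int) -> tuple[float, float]:
    """Exhaustive sum of p_c * M_c - 1 over every grid cell."""
    mix = np.zeros(n_cells)
    m = np.zeros(n_cells)
    for sid, w in zip(atpd.member_ids, atpd.weights):
        d = dense(atpd.member_tpds[sid], n_cells)
        mix += w * d
        m += (d > 0).astype(float)
    r = float((mix * m).sum()) - 1.0
    n = len(atpd.member_ids)
    return r, (r / (n - 1) if n > 1 else 0.0)


def oracle_contribution(atpd: AssemblageTPD, species_id: str, n_cells: int) -> float:
    """Recompute-by-definition: R(full) - R(without focal, weights renormalised)."""
    r_full, _ = oracle_redundancy(atpd, n_cells)
    keep = [
        (sid, w) for sid, w in zip(atpd.member_ids, atpd.weights) if sid != species_id
    ]
    wsum = sum(w for _, w in keep)
    mix = np.zeros(n_cells)
    m = np.zeros(n_cells)
    for sid, w in keep:
        d = dense(atpd.member_tpds[sid], n_cells)
        mix += (w / wsum) * d
        m += (d > 0).astype(float)
    r_red = float((mix * m).sum()) - 1.0
    return r_full - r_red


def oracle_active_curve(atpd: AssemblageTPD, order: list[str], n_cells: int) -> np.ndarray:
    """rel_fd after each prefix removal, by recomputing union supports."""
    supports = {
        sid: set(atpd.member_tpds[sid].cell_idx.tolist()) for sid in atpd.member_ids
    }
    full = set().union(*supports.values())
    fd0 = len(full)
    rel = [1.0]
    remaining = list(atpd.member_ids)
    for sid in order:
        remaining.remove(sid)
        union = set().union(*(supports[s] for s in remaining)) if remaining else set()
        rel.append(len(union) / fd0)
    return np.array(rel)


def oracle_spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Average-rank Spearman correlation computed from first principles."""

    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0  # 1-based average rank
            i = j
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def make_toy_tpd(species_id: str, cells: dict[int, float]) -> SpeciesTPD:
    """Sparse species TPD from an explicit cell -> probability map."""
    idx = np.array(sorted(cells), dtype=np.int64)
    p = np.array([cells[i] for i in idx], dtype=float)
    return SpeciesTPD(species_id=species_id, cell_idx=idx, probs=p / p.sum())


def random_toy_assemblage(
    rng: np.random.Generator,
    n_species: int,
    n_cells: int,
    max_support: int = 12,
) -> AssemblageTPD:
    """Random sparse assemblage on a small abstract grid, for oracle tests."""
    from avistability.tpd import assemblage_tpd

    members = []
    for i in range(n_species):
        k = int(rng.integers(1, max_support + 1))
        cells = rng.choice(n_cells, size=k, replace=False)
        probs = rng.random(k) + 0.05
        members.append(
            (make_toy_tpd(f"s{i}", dict(zip(cells.tolist(), probs))), float(rng.random() + 0.1))
        )
    return assemblage_tpd("toy", members)
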