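"""Morphological niche axes, mixed-trait dissimilarity and 3-D embedding.

Avian linear morphometrics are dominated by a shared body-size factor.  A
two-step principal component analysis strips it out: separate PCAs on the
four beak traits and the three locomotory traits each yield a size-laden
first component and a shape-like second component; a third PCA on the two
first components recovers a single body-size axis.  The resulting trophic,
locomotory and size axes, plus log hand-wing index (dispersal), are combined
with the nine-part diet composition into a Gower-type dissimilarity in which
the four continuous axes and the diet block carry balanced weight.  Principal
coordinates analysis then embeds each study landscape's species into three
dimensions for density estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import DIET_NAMES, MORPHOMETRIC_NAMES

_BEAK = MORPHOMETRIC_NAMES[:4]
_LOCOMOTORY = MORPHOMETRIC_NAMES[4:]


@dataclass
class NicheAxes:
    """Per-species scores on the four derived morphological niche axes."""

    species_ids: list[str]
    trophic: np.ndarray
    locomotory: np.ndarray
    size: np.ndarray
    dispersal: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trophic": self.trophic,
                "locomotory": self.locomotory,
                "size": self.size,
                "dispersal": self.dispersal,
            },
            index=pd.Index(self.species_ids, name="species"),
        )

    def subset(self, species_ids) -> "NicheAxes":
        pos = {s: i for i, s in enumerate(self.species_ids)}
        ix = np.array([pos[s] for s in species_ids])
        return NicheAxes(
            species_ids=list(species_ids),
            trophic=self.trophic[ix],
            locomotory=self.locomotory[ix],
            size=self.size[ix],
            dispersal=self.dispersal[ix],
        )


def _pca_scores(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Covariance-PCA scores and loadings, components in decreasing-variance order."""
    xc = x - x.mean(axis=0)
    cov = np.cov(xc, rowvar=False)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    return xc @ evecs, evecs


def _orient(scores: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Flip sign so scores correlate positively with the anchor variable."""
    if scores.std() == 0 or anchor.std() == 0:
        return scores
    r = np.corrcoef(scores, anchor)[0, 1]
    return -scores if r < 0 else scores


def two_step_pca(
    morphometrics: pd.DataFrame,
    hwi: pd.Series,
    log_transform: bool = True,
) -> NicheAxes:
    """Derive trophic, locomotory, size and dispersal axes from 7 morphometrics + HWI.

    ``morphometrics`` is species x 7 (columns named as in
    :data:`~avistability.datamodel.MORPHOMETRIC_NAMES`); traits are
    log-transformed (all values must be positive) and z-scored before each
    decomposition when ``log_transform`` is set.  Signs are fixed so the size
    axis correlates positively with wing length and each second component
    correlates positively with its largest-loading raw trait, making scores
    reproducible across linear-algebra backends.  All axes are mean-centred
    over the full input species set.
    """
    morph = morphometrics[list(MORPHOMETRIC_NAMES)]
    if len(morph) < 3:
        raise ValueError("need at least 3 species")
    x = morph.to_numpy(dtype=float)
    if log_transform:
        if (x <= 0).any():
            raise ValueError("log transform requires strictly positive morphometrics")
        x = np.log(x)
    sd = x.std(axis=0, ddof=0)
    if np.all(sd == 0):
        raise ValueError("degenerate trait table: all species identical")
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - x.mean(axis=0)) / sd

    beak = z[:, :4]
    loco = z[:, 4:]
    s_beak, l_beak = _pca_scores(beak)
    s_loco, l_loco = _pca_scores(loco)

    # orient PC2s to their largest-loading raw trait
    troph = s_beak[:, 1] if s_beak.shape[1] > 1 else np.zeros(len(z))
    loc2 = s_loco[:, 1] if s_loco.shape[1] > 1 else np.zeros(len(z))
    if s_beak.shape[1] > 1:
        troph = _orient(troph, beak[:, int(np.argmax(np.abs(l_beak[:, 1])))])
    if s_loco.shape[1] > 1:
        loc2 = _orient(loc2, loco[:, int(np.argmax(np.abs(l_loco[:, 1])))])

    firsts = np.column_stack([s_beak[:, 0], s_loco[:, 0]])
    s_size, _ = _pca_scores(firsts)
    wing = z[:, list(MORPHOMETRIC_NAMES).index("wing_length")]
    size = _orient(s_size[:, 0], wing)

    h = np.log(np.asarray(hwi.loc[morph.index], dtype=float))
    dispersal = h - h.mean()

    return NicheAxes(
        species_ids=list(morph.index),
        trophic=troph,
        locomotory=loc2,
        size=size,
        dispersal=dispersal,
    )


def _gower_groups(
    axes_mat: np.ndarray,
    diets: np.ndarray,
) -> tuple[list[np.ndarray], list[str]]:
    """Pairwise per-group dissimilarities: 4 range-normalised axes + 1 diet block."""
    n = axes_mat.shape[0]
    groups, dropped = [], []
    for k in range(axes_mat.shape[1]):
        col = axes_mat[:, k]
        rng = col.max() - col.min()
        if rng == 0:
            dropped.append(f"axis_{k}")
            continue
        groups.append(np.abs(col[:, None] - col[None, :]) / rng)
    # compositional block: total-variation distance, already in [0, 1]
    diet_d = 0.5 * np.abs(diets[:, None, :] - diets[None, :, :]).sum(axis=2)
    if diet_d.max() > 0:
        groups.append(diet_d)
    else:
        dropped.append("diet")
    return groups, dropped


def mixed_trait_dissimilarity(
    axes: NicheAxes,
    diets: pd.DataFrame,
    zscore_axes: bool = True,
    weighting: str = "equal",
) -> pd.DataFrame:
    """Gower-type species dissimilarity over 4 niche axes + one diet block.

    Each continuous axis contributes its range-normalised absolute difference;
    the nine diet proportions enter as a single compositional group via
    total-variation distance.  ``weighting='equal'`` averages the five group
    matrices with equal weight; ``'balanced'`` iteratively reweights groups so
    each correlates equally with the combined dissimilarity (the balanced-
    Gower approach for mixed trait types).  Zero-range axes are dropped with a
    warning.  Output is symmetric, zero-diagonal, scaled to [0, 1].
    """
    ids = axes.species_ids
    if len(ids) < 4:
        raise ValueError("need at least 4 species")
    mat = np.column_stack([axes.trophic, axes.locomotory, axes.size, axes.dispersal])
    if zscore_axes:
        sd = mat.std(axis=0, ddof=0)
        mat = (mat - mat.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    d = diets.loc[ids, list(DIET_NAMES)].to_numpy(dtype=float)

    groups, dropped = _gower_groups(mat, d)
    if dropped:
        warnings.warn(f"zero-range trait group(s) dropped: {dropped}", stacklevel=2)
    if not groups:
        raise ValueError("all trait groups degenerate")

    if weighting == "equal":
        w = np.ones(len(groups)) / len(groups)
    elif weighting == "balanced":
        w = _balance_weights(groups)
    else:
        raise ValueError(f"unknown weighting: {weighting!r}")

    total = sum(wi * g for wi, g in zip(w, groups))
    np.fill_diagonal(total, 0.0)
    total = 0.5 * (total + total.T)
    return pd.DataFrame(total, index=ids, columns=ids)


def _balance_weights(groups: list[np.ndarray], n_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Weights equalising each group's correlation with the combined matrix."""
    k = len(groups)
    iu = np.triu_indices_from(groups[0], k=1)
    vecs = np.stack([g[iu] for g in groups])
    w = np.ones(k) / k
    for _ in range(n_iter):
        total = w @ vecs
        if total.std() == 0:
            break
        cors = np.array(
            [np.corrcoef(v, total)[0, 1] if v.std() > 0 else 1.0 for v in vecs]
        )
        cors = np.clip(cors, 1e-6, None)
        new = w * (cors.mean() / cors)
        new = new / new.sum()
        if np.abs(new - w).max() < tol:
            w = new
            break
        w = new
    return w


@dataclass
class Embedding:
    """3-D principal-coordinate positions for one landscape's species."""

    species_ids: list[str]
    coords: np.ndarray  # (n, 3)
    embedding_quality: float
    cailliez_constant: float = 0.0

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coords, columns=["pc1", "pc2", "pc3"],
            index=pd.Index(self.species_ids, name="species"),
        )


def _pcoa_eig(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(0.5 * (b + b.T))
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest additive constant making the dissimilarity Euclidean."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    w1 = -0.5 * j @ (d ** 2) @ j
    w2 = -0.5 * j @ d @ j
    zero = np.zeros((n, n))
    block = np.block([[zero, 2 * w1], [-np.eye(n), -4 * w2]])
    ev = np.linalg.eigvals(block)
    return float(max(ev.real.max(), 0.0))


def embed_3d(
    dissimilarity: pd.DataFrame,
    eig_tol: float = 1e-10,
) -> Embedding:
    """Principal-coordinates embedding of a dissimilarity matrix into 3-D.

    Double-centres the squared dissimilarities and keeps the first three
    positive-eigenvalue axes, scaled by the square roots of their eigenvalues.
    When fewer than three eigenvalues are clearly positive (third not
    separated from zero beyond ``eig_tol`` relative to the largest), the
    Cailliez additive-constant correction is applied and the decomposition
    redone.  ``embedding_quality`` is the fraction of positive-eigenvalue
    variance captured by the three retained axes.
    """
    ids = list(dissimilarity.index)
    d = dissimilarity.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity must be square and symmetric")
    evals, evecs = _pcoa_eig(d)
    scale = max(evals.max(), 1.0)
    c = 0.0
    if len(evals) < 3 or evals[2] <= eig_tol * scale:
        c = _cailliez_constant(d)
        if c > 0:
            d = d + c * (1 - np.eye(d.shape[0]))
            evals, evecs = _pcoa_eig(d)
            scale = max(evals.max(), 1.0)
    pos = evals > eig_tol * scale
    if pos.sum() < 3:
        raise ValueError(
            "fewer than 3 positive eigenvalues; reduce dimensionality or check input"
        )
    pos_evals = evals[pos]
    coords = evecs[:, :3] * np.sqrt(evals[:3])
    quality = float(pos_evals[:3].sum() / pos_evals.sum())
    return Embedding(
        species_ids=ids, coords=coords, embedding_quality=quality, cailliez_constant=c
    )


__all__ = [
    "NicheAxes", "Embedding",
    "two_step_pca", "mixed_trait_dissimilarity", "embed_3d",
]
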