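"""Species sensitivity scores: the likelihood of local extinction.

Three schemes, all centred to mean 0 and scaled to unit standard deviation
within each assemblage (higher = more likely to be lost):

* ``general_traits`` — mean of four oriented z-scored response traits:
  small geographical range (-z log range size), large body size (+z size
  axis), diet specialism (+z max diet proportion) and dispersal limitation
  (-z log hand-wing index).
* ``climate_traits`` — high elevation (+z), narrow temperature niche (-z),
  long generation (+z) and dispersal limitation (-z log HWI).
* ``rarity`` — negative within-assemblage abundance.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .datamodel import SpeciesProfile

SCHEMES = ("general_traits", "climate_traits", "rarity")


def _zscore(x: np.ndarray) -> np.ndarray:
    """Population z-score; all-zero when the vector is constant."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _require(profiles: Sequence[SpeciesProfile], attr: str) -> np.ndarray:
    vals = []
    for p in profiles:
        v = getattr(p, attr)
        if v is None:
            raise ValueError(f"species {p.species_id} is missing {attr}")
        vals.append(v)
    return np.asarray(vals, dtype=float)


def general_trait_sensitivity(
    profiles: Sequence[SpeciesProfile],
    size_axis: Mapping[str, float],
    component_weights: Sequence[float] = (1.0, 1.0, 1.0, 1.0),
) -> np.ndarray:
    """General response-trait sensitivity for one assemblage's members.

    Composite = weighted mean of (-z log range_size, +z size_axis,
    +z diet_specialism, -z log hwi), re-standardised within the assemblage.
    """
    rng = _require(profiles, "range_size")
    size = np.asarray([size_axis[p.species_id] for p in profiles], dtype=float)
    spec = np.asarray([p.diet_specialism for p in profiles])
    hwi = np.asarray([p.hwi for p in profiles])
    comps = np.column_stack(
        [-_zscore(np.log(rng)), _zscore(size), _zscore(spec), -_zscore(np.log(hwi))]
    )
    w = np.asarray(component_weights, dtype=float)
    return _zscore(comps @ (w / w.sum()))


def climate_trait_sensitivity(
    profiles: Sequence[SpeciesProfile],
    component_weights: Sequence[float] = (1.0, 1.0, 1.0, 1.0),
) -> np.ndarray:
    """Climate-change response-trait sensitivity for one assemblage's members."""
    elev = _require(profiles, "elevation_mid")
    niche = _require(profiles, "temp_niche_breadth")
    gen = _require(profiles, "generation_length")
    hwi = np.asarray([p.hwi for p in profiles])
    comps = np.column_stack(
        [_zscore(elev), -_zscore(niche), _zscore(gen), -_zscore(np.log(hwi))]
    )
    w = np.asarray(component_weights, dtype=float)
    return _zscore(comps @ (w / w.sum()))


def rarity_sensitivity(abundances: Sequence[float]) -> np.ndarray:
    """Rarity-based sensitivity: standardised negative abundance."""
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    return _zscore(-a)


__all__ = [
    "SCHEMES",
    "general_trait_sensitivity", "climate_trait_sensitivity", "rarity_sensitivity",
]
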