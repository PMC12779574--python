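"""Core data containers and survey ingestion.

Survey data arrive as long-format site records (site nested in study block
nested in study landscape), each site carrying a vegetation class, a use
intensity and — for secondary vegetation — a successional age.  Sites are
classified into ten fine land-use types, pooled into assemblages per
(landscape, block, land use), and species-level trait/diet profiles are
attached.  Taxa identified only to genus are represented by pseudo-species
whose traits average the supplied congeners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MORPHOMETRIC_NAMES = (
    "beak_length_culmen",
    "beak_length_nares",
    "beak_depth",
    "beak_width",
    "tail_length",
    "tarsus_length",
    "wing_length",
)

DIET_NAMES = (
    "herbivore_aquatic",
    "herbivore_terrestrial",
    "nectarivore",
    "granivore",
    "frugivore",
    "invertivore",
    "vertivore_aquatic",
    "vertivore_terrestrial",
    "scavenger",
)

#: diet column backing each trophic guild
GUILD_RESOURCE = {
    "granivore": "granivore",
    "frugivore": "frugivore",
    "invertivore": "invertivore",
}

SPECIALIST_THRESHOLD = 0.60
BROAD_THRESHOLD = 0.25


class LandUse(str, Enum):
    """Fine (10-level) land-use classification along the disturbance gradient."""

    PRISTINE_PRIMARY = "pristine_primary"
    DISTURBED_PRIMARY = "disturbed_primary"
    MATURE_SECONDARY = "mature_secondary"
    INTERMEDIATE_SECONDARY = "intermediate_secondary"
    YOUNG_SECONDARY = "young_secondary"
    PLANTATION = "plantation"
    PASTURE = "pasture"
    CROPLAND = "cropland"
    URBAN_MINIMAL = "urban_minimal"
    URBAN_INTENSE = "urban_intense"

    @property
    def coarse(self) -> str:
        """Collapse to the 4-level factor: primary / secondary / agriculture / urban."""
        return _COARSE[self]


_COARSE = {
    LandUse.PRISTINE_PRIMARY: "primary",
    LandUse.DISTURBED_PRIMARY: "primary",
    LandUse.MATURE_SECONDARY: "secondary",
    LandUse.INTERMEDIATE_SECONDARY: "secondary",
    LandUse.YOUNG_SECONDARY: "secondary",
    LandUse.PLANTATION: "agriculture",
    LandUse.PASTURE: "agriculture",
    LandUse.CROPLAND: "agriculture",
    LandUse.URBAN_MINIMAL: "urban",
    LandUse.URBAN_INTENSE: "urban",
}


class Rejected:
    """Sentinel for site records excluded by the classification rules."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "REJECT"


REJECT = Rejected()

_VEGETATION_CLASSES = {"primary", "secondary", "plantation", "pasture", "cropland", "urban"}
_INTENSITIES = {"minimal", "light", "intense"}
_SECONDARY_AGES = {"mature", "intermediate", "young", "indeterminate", "na"}


def classify_land_use(
    vegetation_class: str,
    use_intensity: str,
    secondary_age: str = "na",
) -> LandUse | Rejected:
    """Map a site's vegetation class, use intensity and successional age to a land use.

    Primary vegetation splits into pristine (minimal use) vs disturbed; urban
    splits into minimal vs intense use; secondary vegetation is partitioned by
    age class, and indeterminate-age secondary sites are rejected outright.

    Returns the :data:`REJECT` sentinel for excluded sites; raises
    ``ValueError`` on unrecognised inputs.
    """
    if vegetation_class not in _VEGETATION_CLASSES:
        raise ValueError(f"unknown vegetation class: {vegetation_class!r}")
    if use_intensity not in _INTENSITIES:
        raise ValueError(f"unknown use intensity: {use_intensity!r}")
    if secondary_age not in _SECONDARY_AGES:
        raise ValueError(f"unknown secondary age: {secondary_age!r}")

    if vegetation_class == "primary":
        return LandUse.PRISTINE_PRIMARY if use_intensity == "minimal" else LandUse.DISTURBED_PRIMARY
    if vegetation_class == "urban":
        return LandUse.URBAN_MINIMAL if use_intensity == "minimal" else LandUse.URBAN_INTENSE
    if vegetation_class == "secondary":
        if secondary_age == "mature":
            return LandUse.MATURE_SECONDARY
        if secondary_age == "intermediate":
            return LandUse.INTERMEDIATE_SECONDARY
        if secondary_age == "young":
            return LandUse.YOUNG_SECONDARY
        return REJECT  # indeterminate (or unstated) age secondary vegetation
    return {
        "plantation": LandUse.PLANTATION,
        "pasture": LandUse.PASTURE,
        "cropland": LandUse.CROPLAND,
    }[vegetation_class]


@dataclass(frozen=True)
class SpeciesProfile:
    """One species' morphometrics, diet composition and response-trait attributes.

    Morphometrics are species means in mm; ``hwi`` is the hand-wing index
    (wing elongation, a dispersal proxy).  ``diet`` holds proportions over the
    nine resource types in :data:`DIET_NAMES` and must sum to 1.  Response
    attributes (range size in km^2, generation length in years, mid-point
    elevation in m, temperature niche breadth in degrees C) are optional and
    only needed for sensitivity scoring.
    """

    species_id: str
    morphometrics: tuple[float, ...]
    hwi: float
    diet: tuple[float, ...]
    range_size: float | None = None
    generation_length: float | None = None
    elevation_mid: float | None = None
    temp_niche_breadth: float | None = None
    pseudo: bool = False

    def __post_init__(self):
        if len(self.morphometrics) != len(MORPHOMETRIC_NAMES):
            raise ValueError("expected 7 morphometric values")
        if len(self.diet) != len(DIET_NAMES):
            raise ValueError("expected 9 diet proportions")
        if any(m <= 0 for m in self.morphometrics):
            raise ValueError(f"{self.species_id}: morphometrics must be positive")
        if self.hwi <= 0:
            raise ValueError(f"{self.species_id}: hwi must be positive")
        d = np.asarray(self.diet, dtype=float)
        if (d < -1e-12).any() or (d > 1 + 1e-12).any() or abs(d.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.species_id}: diet proportions must lie in [0,1] and sum to 1")

    @property
    def diet_specialism(self) -> float:
        """Maximum diet proportion; 1 for a perfect specialist."""
        return float(max(self.diet))

    def primary_guild(self, threshold: float = SPECIALIST_THRESHOLD) -> str:
        """Trophic guild at the given threshold; 'generalist' if no resource exceeds it."""
        d = np.asarray(self.diet)
        if d.max() > threshold:
            return DIET_NAMES[int(d.argmax())]
        return "generalist"


@dataclass
class Assemblage:
    """Species abundances observed in one (landscape, block, land-use) unit."""

    assemblage_id: str
    landscape_id: str
    block_id: str
    land_use: LandUse
    members: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self):
        if any(a < 0 for _, a in self.members):
            raise ValueError("abundances must be non-negative")
        if self.members and not any(a > 0 for _, a in self.members):
            raise ValueError("at least one member must have positive abundance")

    @property
    def species_ids(self) -> list[str]:
        return [s for s, _ in self.members]

    @property
    def abundances(self) -> dict[str, float]:
        return dict(self.members)

    @property
    def richness(self) -> int:
        return len(self.members)


def aggregate_sites(
    site_records: pd.DataFrame,
    min_richness: int = 4,
) -> list[Assemblage]:
    """Pool survey sites into assemblages per (landscape, block, fine land use).

    ``site_records`` needs columns ``landscape_id, block_id, site_id, land_use,
    species, abundance`` where ``land_use`` is a :class:`LandUse` (records for
    rejected sites must be dropped by the caller; see :func:`ingest_surveys`).
    Member abundance is the sum over constituent sites.  Assemblages with
    fewer than ``min_richness`` species are retained with a warning, because
    whole-assemblage and guild-level analyses apply different minima.

    Raises ``ValueError`` if one site carries conflicting land-use labels.
    """
    if len(site_records) == 0:
        raise ValueError("no site records supplied")
    df = site_records.copy()
    lu_per_site = df.groupby(["landscape_id", "block_id", "site_id"])["land_use"].nunique()
    conflicted = lu_per_site[lu_per_site > 1]
    if len(conflicted):
        raise ValueError(
            "conflicting land-use labels within site(s): "
            + ", ".join(str(ix) for ix in conflicted.index.tolist())
        )

    grouped = (
        df.groupby(["landscape_id", "block_id", "land_use", "species"], sort=True)["abundance"]
        .sum()
        .reset_index()
    )
    assemblages: list[Assemblage] = []
    for (lsc, blk, lu), sub in grouped.groupby(["landscape_id", "block_id", "land_use"], sort=True):
        members = list(zip(sub["species"], sub["abundance"].astype(float)))
        asm = Assemblage(
            assemblage_id=f"{lsc}|{blk}|{lu.value if isinstance(lu, LandUse) else lu}",
            landscape_id=str(lsc),
            block_id=str(blk),
            land_use=lu,
            members=members,
        )
        if asm.richness < min_richness:
            warnings.warn(
                f"assemblage {asm.assemblage_id} has only {asm.richness} species "
                f"(< {min_richness}); retained but unusable for TPDs",
                stacklevel=2,
            )
        assemblages.append(asm)
    return assemblages


def impute_pseudo_species(
    genus: str,
    congener_profiles: Sequence[SpeciesProfile],
) -> SpeciesProfile:
    """Build a genus-level pseudo-species by averaging congener trait values.

    Every morphometric, the hand-wing index, the diet proportions (renormalised
    to the simplex after averaging) and any response attributes present in all
    congeners are arithmetic means.  The caller supplies the congener list;
    range-map filtering is out of scope here.
    """
    if not congener_profiles:
        raise ValueError(f"no congeners supplied for genus {genus!r}")
    morph = np.mean([p.morphometrics for p in congener_profiles], axis=0)
    hwi = float(np.mean([p.hwi for p in congener_profiles]))
    diet = np.mean([p.diet for p in congener_profiles], axis=0)
    diet = diet / diet.sum()

    def _opt(attr: str) -> float | None:
        vals = [getattr(p, attr) for p in congener_profiles]
        if any(v is None for v in vals):
            return None
        return float(np.mean(vals))

    return SpeciesProfile(
        species_id=f"{genus}_sp",
        morphometrics=tuple(float(v) for v in morph),
        hwi=hwi,
        diet=tuple(float(v) for v in diet),
        range_size=_opt("range_size"),
        generation_length=_opt("generation_length"),
        elevation_mid=_opt("elevation_mid"),
        temp_niche_breadth=_opt("temp_niche_breadth"),
        pseudo=True,
    )


GUILDS = ("granivore", "frugivore", "invertivore", "generalist")


def guild_members(
    species_ids: Iterable[str],
    profiles: Mapping[str, SpeciesProfile],
    guild: str,
    threshold: float = SPECIALIST_THRESHOLD,
) -> list[str]:
    """Species in ``species_ids`` belonging to ``guild`` at ``threshold``.

    A species is in a resource guild when the matching diet proportion is
    strictly greater than ``threshold``; a generalist exceeds the 60%
    specialist threshold for no single resource (regardless of ``threshold``).
    """
    if guild not in GUILDS:
        raise ValueError(f"unknown guild: {guild!r}")
    out = []
    for sid in species_ids:
        diet = np.asarray(profiles[sid].diet)
        if guild == "generalist":
            if diet.max() <= SPECIALIST_THRESHOLD:
                out.append(sid)
        else:
            ix = DIET_NAMES.index(GUILD_RESOURCE[guild])
            if diet[ix] > threshold:
                out.append(sid)
    return out


def guild_subset(
    assemblage: Assemblage,
    profiles: Mapping[str, SpeciesProfile],
    guild: str,
    threshold: float = SPECIALIST_THRESHOLD,
    landscape_species: Iterable[str] | None = None,
) -> Assemblage | None:
    """Restrict an assemblage to one trophic guild.

    Returns ``None`` when the guild has three or fewer members across the
    whole study landscape (``landscape_species``; defaults to the assemblage
    itself), since a trait probability density cannot be built there.
    """
    pool = list(landscape_species) if landscape_species is not None else assemblage.species_ids
    if len(guild_members(pool, profiles, guild, threshold)) <= 3:
        return None
    keep = set(guild_members(assemblage.species_ids, profiles, guild, threshold))
    members = [(s, a) for s, a in assemblage.members if s in keep]
    if not members:
        return None
    return Assemblage(
        assemblage_id=f"{assemblage.assemblage_id}|{guild}",
        landscape_id=assemblage.landscape_id,
        block_id=assemblage.block_id,
        land_use=assemblage.land_use,
        members=members,
    )


# ---------------------------------------------------------------------------
# file ingestion

AVONET_COLUMN_MAP = {
    "Beak.Length_Culmen": "beak_length_culmen",
    "Beak.Length_Nares": "beak_length_nares",
    "Beak.Depth": "beak_depth",
    "Beak.Width": "beak_width",
    "Tail.Length": "tail_length",
    "Tarsus.Length": "tarsus_length",
    "Wing.Length": "wing_length",
    "Hand-Wing.Index": "hwi",
}


def read_trait_table(
    path_or_df,
    column_map: Mapping[str, str] | None = None,
    species_col: str = "species",
) -> pd.DataFrame:
    """Read a species x traits CSV (AVONET-style names accepted via ``column_map``)."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    df = df.rename(columns=dict(AVONET_COLUMN_MAP, **(column_map or {})))
    if species_col != "species":
        df = df.rename(columns={species_col: "species"})
    missing = [c for c in MORPHOMETRIC_NAMES + ("hwi",) if c not in df.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    return df.set_index("species")


def read_diet_table(path_or_df, species_col: str = "species") -> pd.DataFrame:
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    if species_col != "species":
        df = df.rename(columns={species_col: "species"})
    missing = [c for c in DIET_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"diet table missing columns: {missing}")
    return df.set_index("species")


def build_profiles(
    traits: pd.DataFrame,
    diets: pd.DataFrame,
    attributes: pd.DataFrame | None = None,
) -> dict[str, SpeciesProfile]:
    """Join trait, diet and optional attribute tables into SpeciesProfile objects."""
    profiles = {}
    for sid in traits.index:
        if sid not in diets.index:
            raise ValueError(f"species {sid!r} missing from diet table")
        t, d = traits.loc[sid], diets.loc[sid]
        attrs = {}
        if attributes is not None and sid in attributes.index:
            row = attributes.loc[sid]
            for col in ("range_size", "generation_length", "elevation_mid", "temp_niche_breadth"):
                if col in row.index and pd.notna(row[col]):
                    attrs[col] = float(row[col])
        diet = np.asarray([d[c] for c in DIET_NAMES], dtype=float)
        diet = diet / diet.sum()  # guard against rounding in on-disk tables
        profiles[sid] = SpeciesProfile(
            species_id=str(sid),
            morphometrics=tuple(float(t[c]) for c in MORPHOMETRIC_NAMES),
            hwi=float(t["hwi"]),
            diet=tuple(diet),
            **attrs,
        )
    return profiles


def ingest_surveys(
    surveys: pd.DataFrame,
    min_richness: int = 4,
) -> tuple[list[Assemblage], pd.DataFrame]:
    """Classify land use for raw survey records and aggregate into assemblages.

    ``surveys`` is long-format with columns ``landscape_id, block_id, site_id,
    vegetation_class, use_intensity, secondary_age, species, abundance``.
    Returns the assemblages plus a frame of records rejected by the land-use
    rules (for audit).
    """
    needed = {
        "landscape_id", "block_id", "site_id", "vegetation_class",
        "use_intensity", "secondary_age", "species", "abundance",
    }
    missing = needed - set(surveys.columns)
    if missing:
        raise ValueError(f"survey table missing columns: {sorted(missing)}")
    df = surveys.copy()
    df["secondary_age"] = df["secondary_age"].fillna("na")
    labels = [
        classify_land_use(v, i, a)
        for v, i, a in zip(df["vegetation_class"], df["use_intensity"], df["secondary_age"])
    ]
    df["land_use"] = labels
    rejected = df[[lu is REJECT for lu in labels]].drop(columns="land_use")
    kept = df[[isinstance(lu, LandUse) for lu in labels]]
    assemblages = aggregate_sites(kept, min_richness=min_richness)
    return assemblages, rejected


__all__ = [
    "MORPHOMETRIC_NAMES", "DIET_NAMES", "GUILDS", "GUILD_RESOURCE",
    "SPECIALIST_THRESHOLD", "BROAD_THRESHOLD",
    "LandUse", "REJECT", "Rejected", "SpeciesProfile", "Assemblage",
    "classify_land_use", "aggregate_sites", "impute_pseudo_species",
    "guild_members", "guild_subset", "read_trait_table", "read_diet_table",
    "build_profiles", "ingest_surveys", "AVONET_COLUMN_MAP",
]
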