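"""Controlled vocabularies, character profiles and collection tallies.

Thirteen laccate taxa of the Ganodermataceae are recognized for the United
States (twelve *Ganoderma* species plus *Tomophagus colossus*, with
*G. curtisii* f.sp. *meredithiae* as a physiological variant carried at the
rank of forma specialis).  This module holds that species vocabulary, the
morphological/ecological character model used by the identification key
(context-tissue color class, melanoid deposits, concentric growth zones,
chlamydospores, stipe habit, hymenium pore density, host group, geography,
in-vitro growth rate, basidiospore means), the reference character profile of
each taxon, and the survey-style frequency tallies.

Missing data is an explicit :data:`MISSING` sentinel throughout, never an
empty string: the key engine must distinguish "character observed absent"
from "character not observed".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

__all__ = [
    "SPECIES",
    "MISSING",
    "CONTEXT_COLORS",
    "TRISTATE",
    "STIPE_CLASSES",
    "HOST_GROUPS",
    "REGIONS",
    "GROWTH_RATE_CLASSES",
    "CharacterProfile",
    "CollectionRecord",
    "UnknownColorTerm",
    "classify_context_color",
    "load_reference_profiles",
    "tally_species",
    "tally_host_groups",
    "read_collections_tsv",
    "write_collections_tsv",
    "round_half_away",
]

#: The thirteen admissible taxon names, in the order they are tabulated.
SPECIES: tuple[str, ...] = (
    "G. curtisii",
    "G. curtisii f.sp. meredithiae",
    "G. lucidum",
    "G. martinicense",
    "G. oregonense",
    "G. polychromum",
    "G. ravenelii",
    "G. sessile",
    "G. tsugae",
    "G. tuberculosum",
    "G. cf. weberianum",
    "G. zonatum",
    "T. colossus",
)

#: Sentinel for an unobserved character state.
MISSING = "missing"

CONTEXT_COLORS = ("white", "buff", "dark_brown")
TRISTATE = ("present", "absent", MISSING)
STIPE_CLASSES = ("stipitate", "pseudostipitate", "sessile")
HOST_GROUPS = ("hardwood", "conifer", "monocot", "cycad", "cactus")
REGIONS = ("eastern_US", "western_US", "pacific_northwest", "subtropical", "restricted_UT_CA")
GROWTH_RATE_CLASSES = ("fast", "slow")  # fast ~6 mm/day, slow <3 mm/day on MEA

_US_STATES = set(
    "AL AK AZ AR CA CO CT DE FL GA HI ID IL IN IA KS KY LA ME MD MA MI MN MS "
    "MO MT NE NV NH NJ NM NY NC ND OH OK OR PA RI SC SD TN TX UT VT VA WA WV "
    "WI WY DC".split()
)


class UnknownColorTerm(ValueError):
    """A context-tissue color description with no entry in the synonym table."""


def _data_text(name: str) -> str:
    return resources.files("ganokit.data").joinpath(name).read_text(encoding="utf-8")


def _load_color_synonyms() -> dict[str, str]:
    table = yaml.safe_load(_data_text("color_synonyms.yaml"))
    out: dict[str, str] = {}
    for color_class, terms in table.items():
        if color_class not in CONTEXT_COLORS:
            raise ValueError(f"synonym table maps to unknown class {color_class!r}")
        for term in terms:
            out[_normalize_color_term(term)] = color_class
    return out


def _normalize_color_term(term: str) -> str:
    return " ".join(term.lower().replace("-", " ").replace("_", " ").split())


_COLOR_SYNONYMS: Optional[dict[str, str]] = None


def classify_context_color(description: str) -> str:
    """Map a free-text context-tissue color term to one of three classes.

    Fresh context tissue falls into three broad categories: white,
    pinkish-buff to cinnamon-buff (light brown), or cinnamon brown (dark
    brown).  The mapping is a shipped synonym table of Ridgway-style color
    names; an unmapped term raises :class:`UnknownColorTerm` rather than
    guessing.
    """
    global _COLOR_SYNONYMS
    if not description or not description.strip():
        raise ValueError("color description must be non-empty")
    if _COLOR_SYNONYMS is None:
        _COLOR_SYNONYMS = _load_color_synonyms()
    key = _normalize_color_term(description)
    try:
        return _COLOR_SYNONYMS[key]
    except KeyError:
        raise UnknownColorTerm(
            f"no context-color class for {description!r}; add it to color_synonyms.yaml"
        ) from None


@dataclass(frozen=True)
class CharacterProfile:
    """One specimen's observable character states.

    Every categorical field defaults to :data:`MISSING`; numeric fields use
    ``None`` for missing.  ``pores_per_mm`` is an interval ``(lo, hi)`` of
    pore counts per mm of hymenium.
    """

    specimen_id: str = ""
    context_color: str = MISSING
    melanoid_deposits: str = MISSING
    concentric_zones: str = MISSING
    contextual_chlamydospores: str = MISSING
    culture_chlamydospores: str = MISSING
    stipe_class: str = MISSING
    pores_per_mm: Optional[tuple[float, float]] = None
    host_group: str = MISSING
    region: str = MISSING
    growth_rate_class: str = MISSING
    spore_length_mean: Optional[float] = None  # µm
    spore_width_mean: Optional[float] = None  # µm
    pileus_notes: str = ""

    def __post_init__(self) -> None:
        _check_enum("context_color", self.context_color, CONTEXT_COLORS)
        for name in ("melanoid_deposits", "concentric_zones",
                     "contextual_chlamydospores", "culture_chlamydospores"):
            _check_enum(name, getattr(self, name), ("present", "absent"))
        _check_enum("stipe_class", self.stipe_class, STIPE_CLASSES)
        _check_enum("host_group", self.host_group, HOST_GROUPS)
        _check_enum("region", self.region, REGIONS)
        _check_enum("growth_rate_class", self.growth_rate_class, GROWTH_RATE_CLASSES)
        if self.pores_per_mm is not None:
            lo, hi = self.pores_per_mm
            if not (0 < lo <= hi):
                raise ValueError(f"pores_per_mm interval must be positive and ordered: {self.pores_per_mm}")
        for name in ("spore_length_mean", "spore_width_mean"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")

    def without(self, *characters: str) -> "CharacterProfile":
        """Return a copy with the named characters reset to missing."""
        numeric = {"spore_length_mean", "spore_width_mean", "pores_per_mm"}
        updates = {c: (None if c in numeric else MISSING) for c in characters}
        return replace(self, **updates)

    def known_characters(self) -> list[str]:
        out = []
        for f in fields(self):
            if f.name in ("specimen_id", "pileus_notes"):
                continue
            v = getattr(self, f.name)
            if v is not None and v != MISSING:
                out.append(f.name)
        return out


def _check_enum(name: str, value: str, allowed: Sequence[str]) -> None:
    if value != MISSING and value not in allowed:
        raise ValueError(f"{name}={value!r} not in {tuple(allowed)} or {MISSING!r}")


@dataclass(frozen=True)
class CollectionRecord:
    """One surveyed collection (fresh or herbarium)."""

    collection_id: str
    species: str
    state: str = MISSING
    host_genus: str = MISSING
    host_group: str = MISSING
    herbarium: str = "field"

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.state != MISSING and self.state not in _US_STATES:
            raise ValueError(f"invalid US state code {self.state!r}")
        _check_enum("host_group", self.host_group, HOST_GROUPS)
        if self.herbarium not in ("field", "FLAS", "NCSCLG"):
            raise ValueError(f"unknown herbarium {self.herbarium!r}")


def load_reference_profiles() -> dict[str, CharacterProfile]:
    """Load the shipped reference profile of each of the 13 taxa.

    Each reference profile records the modal character states of the taxon;
    passed through the identification key, every reference profile must
    identify exactly its own taxon.
    """
    raw = yaml.safe_load(_data_text("reference_profiles.yaml"))
    profiles: dict[str, CharacterProfile] = {}
    for species, states in raw.items():
        if species not in SPECIES:
            raise ValueError(f"reference profile for unknown species {species!r}")
        if "pores_per_mm" in states and states["pores_per_mm"] is not None:
            states["pores_per_mm"] = tuple(states["pores_per_mm"])
        profiles[species] = CharacterProfile(specimen_id=f"ref:{species}", **states)
    missing = set(SPECIES) - set(profiles)
    if missing:
        raise ValueError(f"reference profiles missing for {sorted(missing)}")
    return profiles


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (5 rounds up), unlike banker's rounding."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def tally_species(records: Iterable[CollectionRecord], total: Optional[int] = None,
                  decimals: int = 0) -> pd.DataFrame:
    """Tabulate (species, count, percent) over a set of collections.

    ``percent`` is ``100·count/total`` rounded half-away-from-zero to
    ``decimals`` places; ``total`` defaults to the number of records but can
    be supplied to express per-species frequencies against a larger survey
    total.
    """
    records = list(records)
    counts: dict[str, int] = {}
    for r in records:
        counts[r.species] = counts.get(r.species, 0) + 1
    if total is None:
        total = len(records)
    if total == 0:
        raise ValueError("total must be positive")
    if total < sum(counts.values()):
        raise ValueError("total smaller than the summed counts")
    rows = [
        {"species": sp, "count": n, "percent": round_half_away(100.0 * n / total, decimals)}
        for sp, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["species", "count", "percent"])


def tally_host_groups(records: Iterable[CollectionRecord], decimals: int = 0) -> pd.DataFrame:
    """Tabulate host-substrate affinities over the known-host subset.

    Every input record must carry a host group; percentages are over this
    known-host subtotal with the same rounding contract as
    :func:`tally_species`.
    """
    records = list(records)
    if not records:
        raise ValueError("no records with known host group")
    for r in records:
        if r.host_group == MISSING:
            raise ValueError(f"record {r.collection_id!r} has no host group")
    n = len(records)
    counts: dict[str, int] = {}
    for r in records:
        counts[r.host_group] = counts.get(r.host_group, 0) + 1
    rows = [
        {"host_group": g, "count": c, "percent": round_half_away(100.0 * c / n, decimals)}
        for g, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["host_group", "count", "percent"])


_COLLECTION_COLUMNS = ["collection_id", "species", "state", "host_genus", "host_group", "herbarium"]


def write_collections_tsv(records: Iterable[CollectionRecord], path) -> None:
    df = pd.DataFrame(
        [{c: getattr(r, c) for c in _COLLECTION_COLUMNS} for r in records],
        columns=_COLLECTION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_collections_tsv(path) -> list[CollectionRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(_COLLECTION_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"collections TSV missing columns {sorted(missing_cols)}")
    return [CollectionRecord(**{c: row[c] for c in _COLLECTION_COLUMNS}) for _, row in df.iterrows()]
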