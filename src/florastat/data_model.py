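"""Observation tables, taxonomy harmonization and identification classes.

The unit of analysis is one identification attempt ("observation"): a
verified species name, the application's first suggested name, the study
setting (curated-database images vs. field use) and three image annotations.
Each observation is scored into one of four ordered identification classes
by comparing the harmonized suggestion against the harmonized verified name:

* ``SPECIES`` — first suggestion is the correct species,
* ``GENUS``   — wrong species but correct genus,
* ``FAMILY``  — wrong genus but correct family,
* ``NONE``    — not even the family is correct (or no suggestion at all).

Name harmonization merges synonyms through a pluggable mapping table and
collapses infraspecific taxa (subspecies, varieties) to species level, so
that scoring never penalizes purely nomenclatural disagreement.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger("florastat")

# ---------------------------------------------------------------------------
# Vocabularies
# ---------------------------------------------------------------------------

SETTINGS = ("database", "field")
ORGANS = ("both", "reproductive", "vegetative")
FOCUS = ("multiple", "single")
BACKGROUND = ("no_vegetation", "non_natural", "vegetation")

OBSERVATION_COLUMNS = (
    "obs_id",
    "setting",
    "verified_name",
    "suggested_name",
    "organs",
    "focus",
    "background",
)

SPECIES_COLUMNS = (
    "accepted_name",
    "genus",
    "family",
    "growth_form",
    "life_form",
    "habitat",
    "frequency",
    "n_training_images",
)

#: number of atlas grid cells in the study region; frequencies live in [1, 540]
MAX_FREQUENCY = 540


class IdentificationClass(enum.IntEnum):
    """Ordered outcome of one identification attempt (SPECIES is best)."""

    NONE = 0
    FAMILY = 1
    GENUS = 2
    SPECIES = 3

    @property
    def label(self) -> str:
        return self.name.lower()


#: classes ordered best-first, the order used in every report
CLASS_ORDER = (
    IdentificationClass.SPECIES,
    IdentificationClass.GENUS,
    IdentificationClass.FAMILY,
    IdentificationClass.NONE,
)
CLASS_LABELS = tuple(c.label for c in CLASS_ORDER)

# rank markers that introduce infraspecific epithets; all tokens from the
# marker onward are dropped when collapsing to species level
_RANK_MARKERS = {"subsp.", "subsp", "ssp.", "ssp", "var.", "var", "f.",
                 "subvar.", "subvar", "forma", "cv."}
_HYBRID_TOKENS = {"×", "x"}
_WS_RE = re.compile(r"\s+")


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


@dataclass
class TaxonomyMap:
    """Synonym merging plus accepted-name → (genus, family) lookup.

    ``synonyms`` maps casefolded raw binomials to canonical accepted names;
    accepted names implicitly map to themselves (idempotence).  ``species``
    maps casefolded accepted names to ``(genus, family)``; a genus → family
    map is derived from it so that suggestions outside the accepted list can
    still be scored at genus/family level.
    """

    synonyms: dict[str, str] = field(default_factory=dict)
    species: dict[str, tuple[str, str]] = field(default_factory=dict)
    _canonical: dict[str, str] = field(default_factory=dict, repr=False)
    _genus_family: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._canonical = {}
        self._genus_family = {}
        for name, (genus, fam) in self.species.items():
            self._canonical[name] = name
            self._genus_family.setdefault(genus.casefold(), fam)
        # accepted names must map to themselves even if listed as synonyms
        for raw, acc in list(self.synonyms.items()):
            if raw.casefold() in self.species:
                del self.synonyms[raw]

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_species_table(cls, species: pd.DataFrame,
                           synonyms: dict[str, str] | None = None,
                           ) -> "TaxonomyMap":
        sp = {
            str(r.accepted_name).casefold(): (str(r.genus), str(r.family))
            for r in species.itertuples()
        }
        syn = {k.casefold(): v for k, v in (synonyms or {}).items()}
        return cls(synonyms=syn, species=sp)

    @classmethod
    def from_csv(cls, species_path, synonyms_path=None) -> "TaxonomyMap":
        """Load from a three-column (accepted,genus,family) CSV plus an
        optional two-column (synonym,accepted) CSV."""
        spdf = pd.read_csv(species_path, dtype=str)
        need = {"accepted_name", "genus", "family"}
        if not need.issubset(spdf.columns):
            raise SchemaError(
                f"taxonomy species file lacks columns {sorted(need - set(spdf.columns))}")
        sp = {
            str(r.accepted_name).casefold(): (str(r.genus), str(r.family))
            for r in spdf.itertuples()
        }
        syn: dict[str, str] = {}
        if synonyms_path is not None:
            syndf = pd.read_csv(synonyms_path, dtype=str)
            if not {"synonym", "accepted"}.issubset(syndf.columns):
                raise SchemaError("taxonomy synonym file needs columns synonym,accepted")
            syn = {str(r.synonym).casefold(): str(r.accepted)
                   for r in syndf.itertuples()}
        return cls(synonyms=syn, species=sp)

    # -- lookups ----------------------------------------------------------

    def accepted_or_none(self, name: str) -> str | None:
        key = name.casefold()
        if key in self.species:
            return self._display(key)
        return self.synonyms.get(key)

    def _display(self, key: str) -> str:
        # accepted names are stored casefolded; re-capitalize genus token
        genus, _ = self.species[key]
        toks = key.split()
        return " ".join([genus] + toks[1:]) if toks else key

    def family_of(self, name: str) -> str | None:
        key = name.casefold()
        if key in self.species:
            return self.species[key][1]
        return self._genus_family.get(key.split()[0] if key else "")

    def genus_of(self, name: str) -> str:
        key = name.casefold()
        if key in self.species:
            return self.species[key][0]
        return name.split()[0] if name else ""

    def __contains__(self, name: str) -> bool:
        return name.casefold() in self.species


# ---------------------------------------------------------------------------
# Harmonization and classification
# ---------------------------------------------------------------------------


def harmonize_name(raw_name: str, taxonomy: TaxonomyMap) -> str:
    """Collapse a raw taxon string to its accepted species binomial.

    Infraspecific parts (tokens after the second, including rank markers such
    as ``subsp.`` and ``var.``) are stripped, hybrid signs removed, then the
    synonym table applied.  Unknown names are returned unchanged (after
    normalization) and logged, so scoring can still use their genus token.
    """
    if raw_name is None or not str(raw_name).strip():
        raise ValidationError("empty taxon name cannot be harmonized")
    tokens = []
    for tok in _WS_RE.split(str(raw_name).strip()):
        tok = tok.lstrip("×")  # hybrid epithets like "×rubens"
        if not tok or tok.casefold() in _RANK_MARKERS | _HYBRID_TOKENS:
            continue
        tokens.append(tok)
    name = " ".join(tokens[:2])
    accepted = taxonomy.accepted_or_none(name)
    if accepted is not None:
        return accepted
    logger.debug("name %r not in taxonomy; kept as-is", name)
    return name


def classify_pair(verified_name: str, suggested_name: str | None,
                  taxonomy: TaxonomyMap) -> IdentificationClass:
    """Score one (verified, suggested) name pair.

    The verified name must resolve to an accepted species; the suggestion may
    be empty (→ ``NONE``) or unknown (scored on its genus token and the
    genus → family map).
    """
    verified = harmonize_name(verified_name, taxonomy)
    if verified not in taxonomy:
        raise ValidationError(
            f"verified name {verified!r} is not an accepted species in the taxonomy")
    if suggested_name is None or not str(suggested_name).strip():
        return IdentificationClass.NONE
    suggested = harmonize_name(suggested_name, taxonomy)
    if suggested.casefold() == verified.casefold():
        return IdentificationClass.SPECIES
    if taxonomy.genus_of(suggested).casefold() == taxonomy.genus_of(verified).casefold():
        return IdentificationClass.GENUS
    fam_s = taxonomy.family_of(suggested)
    if fam_s is not None and fam_s == taxonomy.family_of(verified):
        return IdentificationClass.FAMILY
    return IdentificationClass.NONE


def classify_observation(obs, taxonomy: TaxonomyMap) -> IdentificationClass:
    """Classify a single observation (mapping or row with the two names)."""
    return classify_pair(obs["verified_name"], obs["suggested_name"], taxonomy)


def classify_table(observations: pd.DataFrame,
                   taxonomy: TaxonomyMap) -> pd.DataFrame:
    """Return a copy of ``observations`` with ``id_class`` label and
    ``class_code`` (IdentificationClass value) columns appended."""
    cache: dict[tuple[str, str], IdentificationClass] = {}
    codes = []
    for v, s in zip(observations["verified_name"], observations["suggested_name"]):
        s = "" if s is None or (isinstance(s, float) and pd.isna(s)) else str(s)
        key = (str(v), s)
        if key not in cache:
            cache[key] = classify_pair(key[0], key[1], taxonomy)
        codes.append(cache[key])
    out = observations.copy()
    out["class_code"] = pd.array([int(c) for c in codes], dtype="int64")
    out["id_class"] = [c.label for c in codes]
    return out


# ---------------------------------------------------------------------------
# I/O and validation
# ---------------------------------------------------------------------------

_VOCABS = {"setting": SETTINGS, "organs": ORGANS, "focus": FOCUS,
           "background": BACKGROUND}


def _check_vocab(df: pd.DataFrame, column: str, allowed: tuple[str, ...]) -> None:
    bad = ~df[column].isin(allowed)
    if bad.any():
        row = int(df.index[bad][0]) + 2  # 1-based with header line
        raise ValidationError(
            f"column {column!r}, file row {row}: value {df.loc[df.index[bad][0], column]!r} "
            f"not in vocabulary {list(allowed)}")


def validate_species_table(species: pd.DataFrame) -> pd.DataFrame:
    missing = set(SPECIES_COLUMNS) - set(species.columns)
    if missing:
        raise SchemaError(f"species table lacks required columns {sorted(missing)}")
    sp = species.copy()
    sp["frequency"] = pd.to_numeric(sp["frequency"], errors="raise").astype(int)
    sp["n_training_images"] = pd.to_numeric(sp["n_training_images"],
                                            errors="raise").astype(int)
    if ((sp["frequency"] < 1) | (sp["frequency"] > MAX_FREQUENCY)).any():
        raise ValidationError(f"species frequency outside [1, {MAX_FREQUENCY}]")
    if (sp["n_training_images"] < 1).any():
        raise ValidationError("n_training_images must be a positive integer")
    if sp["accepted_name"].duplicated().any():
        dup = sp.loc[sp["accepted_name"].duplicated(), "accepted_name"].iloc[0]
        raise ValidationError(f"duplicate accepted_name {dup!r} in species table")
    return sp


def load_observations(obs_path, species_path,
                      taxonomy: TaxonomyMap | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate an observation CSV plus its species-trait CSV.

    Returns the two validated tables; category columns are checked against
    the closed vocabularies (errors name the row), duplicate observation ids
    are rejected, and every verified name must be resolvable in the taxonomy
    (built from the species table when not supplied).
    """
    obs = pd.read_csv(obs_path, dtype=str, keep_default_na=False)
    missing = set(OBSERVATION_COLUMNS) - set(obs.columns)
    if missing:
        raise SchemaError(f"observation table lacks required columns {sorted(missing)}")
    species = validate_species_table(pd.read_csv(species_path, dtype=str,
                                                 keep_default_na=False))
    for col, vocab in _VOCABS.items():
        _check_vocab(obs, col, vocab)
    if obs["obs_id"].duplicated().any():
        dup = obs.loc[obs["obs_id"].duplicated(), "obs_id"].iloc[0]
        raise ValidationError(f"duplicate obs_id {dup!r}")
    if (obs["verified_name"].str.strip() == "").any():
        raise ValidationError("verified_name must be nonempty for every observation")
    if taxonomy is None:
        taxonomy = TaxonomyMap.from_species_table(species)
    unknown = sorted({
        n for n in obs["verified_name"].unique()
        if harmonize_name(n, taxonomy) not in taxonomy
    })
    if unknown:
        raise ValidationError(f"verified names not in taxonomy: {unknown[:5]}")
    logger.info("loaded %d observations (%s) and %d species",
                len(obs),
                ", ".join(f"{s}: {n}" for s, n in
                          obs["setting"].value_counts().items()),
                len(species))
    return obs, species


def write_observations(obs: pd.DataFrame, path) -> None:
    obs.to_csv(path, index=False)


def write_species(species: pd.DataFrame, path) -> None:
    species.to_csv(path, index=False)
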