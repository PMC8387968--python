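"""Synthetic observation tables with known ground truth.

The generator emulates the structure of a two-setting identification study:
a species list with taxonomic and ecological traits, and a hierarchical
observation table (several photographs per species, far more replicates in
the curated-database setting than in the field).  Identification outcomes
follow a sequential (continuation-ratio) model on the four ordered classes:

1. species-level success is Bernoulli on the logit scale,
   ``logit p = baseline + beta_ln_train · ln(train) + organ + focus + background + u_species``
   with a Normal(0, sd_species²) species random intercept;
2. conditional on failure, the genus is still correct with probability
   ``p_genus_given_fail``;
3. conditional on genus failure, the family is correct with probability
   ``p_family_given_genus_fail``; otherwise not even the family matches.

Per-species frequency (atlas grid cells occupied, capped at 540) and
training-image counts are coupled through a latent Gaussian copula so that
``ln(training images)`` and frequency carry a configurable correlation.

The first-suggestion name of every observation is synthesized so that
re-classifying the table through :mod:`florastat.data_model` reproduces the
drawn class exactly — the generator and the classifier are mutually
consistent by construction, which downstream tests exploit.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._random import substream
from .data_model import (
    MAX_FREQUENCY,
    SPECIES_COLUMNS,
    IdentificationClass,
    TaxonomyMap,
    classify_table,
)
from .errors import ConfigurationError

__all__ = ["SimulationConfig", "SimulationTruth",
           "generate_species_table", "generate_observations", "simulate_dataset"]

# trait distributions of the species pool (herb-dominated temperate flora)
_GROWTH_FORMS = (("herb", 0.62), ("graminoid", 0.14), ("shrub", 0.10),
                 ("tree", 0.09), ("fern", 0.05))
_LIFE_FORMS = (("hemicryptophyte", 0.46), ("therophyte", 0.16),
               ("phanerophyte", 0.14), ("geophyte", 0.09),
               ("chamaephyte", 0.08), ("hydrophyte", 0.07))
_HABITATS = (("grassland", 0.34), ("forest", 0.30), ("wetland", 0.16),
             ("ruderal", 0.12), ("aquatic", 0.08))


def _default_covariates() -> dict[str, dict[str, float]]:
    # marginal annotation frequencies of a combined database+field study
    return {
        "organs": {"reproductive": 0.33, "both": 0.47, "vegetative": 0.20},
        "focus": {"single": 0.78, "multiple": 0.22},
        "background": {"no_vegetation": 0.56, "non_natural": 0.03,
                       "vegetation": 0.41},
    }


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults give a realistic study.

    Effects are on the logit scale.  ``replicate_range`` bounds (inclusive)
    the uniform per-species replicate counts per setting; the defaults mirror
    the 1–16 database images and 1–5 field observations per species of the
    emulated study design.
    """

    n_species: int = 300
    n_families: int = 20
    replicate_range: dict = field(
        default_factory=lambda: {"database": (1, 16), "field": (1, 5)})
    baseline_logit: float = 0.6
    beta_ln_train: float = 0.25
    organ_effects: dict = field(
        default_factory=lambda: {"reproductive": 0.3, "both": 0.3,
                                 "vegetative": -0.4})
    focus_effect: float = -0.6
    background_effects: dict = field(
        default_factory=lambda: {"no_vegetation": 0.0, "non_natural": 0.0,
                                 "vegetation": 0.0})
    sd_species: float = 1.0
    p_genus_given_fail: float = 0.5
    p_family_given_genus_fail: float = 0.55
    covariate_probabilities: dict = field(default_factory=_default_covariates)
    freq_train_correlation: float = 0.5
    p_field: float = 0.5
    ln_train_mean: float = 5.5
    ln_train_sd: float = 1.2
    freq_mean: float = 250.0
    freq_sd: float = 130.0
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_species < 0:
            raise ConfigurationError("n_species must be nonnegative")
        if self.n_families < 1:
            raise ConfigurationError("n_families must be positive")
        for setting, rng_pair in self.replicate_range.items():
            lo, hi = rng_pair
            if lo < 1 or lo > hi:
                raise ConfigurationError(
                    f"replicate_range[{setting!r}] must satisfy 1 <= min <= max")
        for name in ("p_genus_given_fail", "p_family_given_genus_fail",
                     "p_field"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.sd_species < 0:
            raise ConfigurationError("sd_species must be nonnegative")
        if not -1.0 <= self.freq_train_correlation <= 1.0:
            raise ConfigurationError("freq_train_correlation must be in [-1, 1]")
        if set(self.organ_effects) != {"reproductive", "both", "vegetative"}:
            raise ConfigurationError(
                "organ_effects must cover exactly reproductive/both/vegetative")
        if set(self.background_effects) != {"no_vegetation", "non_natural",
                                            "vegetation"}:
            raise ConfigurationError(
                "background_effects must cover exactly "
                "no_vegetation/non_natural/vegetation")
        for cov, dist in self.covariate_probabilities.items():
            ps = np.asarray(list(dist.values()), dtype=float)
            if (ps < 0).any() or (ps > 1).any() or abs(ps.sum() - 1.0) > 1e-8:
                raise ConfigurationError(
                    f"covariate_probabilities[{cov!r}] must be a probability "
                    "distribution summing to 1")
        return self


@dataclass
class SimulationTruth:
    """Generating parameters and realized outcomes of one synthetic dataset."""

    config: dict
    intercepts: dict[str, float]
    class_counts: dict[str, int]
    classes: dict[str, str]  # obs_id -> realized identification class label

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _draw_categorical(rng: np.random.Generator, dist: dict[str, float],
                      size: int) -> np.ndarray:
    labels = np.asarray(sorted(dist), dtype=object)
    probs = np.asarray([dist[str(l)] for l in labels], dtype=float)
    probs = probs / probs.sum()
    return labels[rng.choice(len(labels), size=size, p=probs)]


def generate_species_table(config: SimulationConfig) -> pd.DataFrame:
    """Synthesize the species pool with traits, frequency and training counts.

    Genera are spread over families so that (whenever the sizes allow) every
    family holds at least two genera and most genera at least two species —
    the structure the classifier's genus/family matching needs to be
    exercised.  Frequency and ln(training images) share a latent bivariate
    Gaussian with correlation ``freq_train_correlation``; frequency uses a
    clipped-normal marginal on [1, 540] and training counts a lognormal one.
    """
    config.validate()
    n = config.n_species
    cols = list(SPECIES_COLUMNS)
    if n == 0:
        return pd.DataFrame(columns=cols)
    rng = substream(config.seed, "species_table")

    n_genera = min(n, max(2 * config.n_families, math.ceil(n / 3)))
    genus_family = np.arange(n_genera) % config.n_families
    species_genus = np.arange(n) % n_genera

    genus_names = np.array([f"Genus{g:03d}" for g in range(n_genera)], dtype=object)
    family_names = np.array([f"Family{f:02d}" for f in range(config.n_families)],
                            dtype=object)
    counters: dict[int, int] = {}
    accepted = []
    for g in species_genus:
        counters[g] = counters.get(g, 0) + 1
        accepted.append(f"{genus_names[g]} species{counters[g]}")

    cov = np.array([[1.0, config.freq_train_correlation],
                    [config.freq_train_correlation, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")
    train = np.maximum(
        1, np.rint(np.exp(config.ln_train_mean + config.ln_train_sd * z[:, 0]))
    ).astype(int)
    freq = np.clip(np.rint(config.freq_mean + config.freq_sd * z[:, 1]),
                   1, MAX_FREQUENCY).astype(int)

    table = pd.DataFrame({
        "accepted_name": accepted,
        "genus": genus_names[species_genus],
        "family": family_names[genus_family[species_genus]],
        "growth_form": _draw_categorical(rng, dict(_GROWTH_FORMS), n),
        "life_form": _draw_categorical(rng, dict(_LIFE_FORMS), n),
        "habitat": _draw_categorical(rng, dict(_HABITATS), n),
        "frequency": freq,
        "n_training_images": train,
    })
    return table[cols]


class _SpeciesIndex:
    """Precomputed lookups used when synthesizing first-suggestion names."""

    def __init__(self, species: pd.DataFrame) -> None:
        self.genus_species: dict[str, list[str]] = {}
        self.family_genera: dict[str, list[str]] = {}
        self.genus_family: dict[str, str] = {}
        for r in species.itertuples():
            self.genus_species.setdefault(r.genus, []).append(r.accepted_name)
            self.genus_family[r.genus] = r.family
        for g, fam in self.genus_family.items():
            self.family_genera.setdefault(fam, []).append(g)
        self.families = sorted(self.family_genera)


def _suggestion_for_class(cls: IdentificationClass, name: str, genus: str,
                          family: str, index: _SpeciesIndex,
                          rng: np.random.Generator,
                          ) -> tuple[IdentificationClass, str]:
    """Build a first-suggestion name realizing ``cls``; may demote FAMILY to
    NONE when the species' family holds no second genus."""
    if cls == IdentificationClass.SPECIES:
        return cls, name
    if cls == IdentificationClass.GENUS:
        others = [s for s in index.genus_species[genus] if s != name]
        if others:
            return cls, others[rng.integers(len(others))]
        return cls, f"{genus} zzspuria"
    if cls == IdentificationClass.FAMILY:
        other_genera = [g for g in index.family_genera[family] if g != genus]
        if other_genera:
            g = other_genera[rng.integers(len(other_genera))]
            return cls, f"{g} zzspuria"
        cls = IdentificationClass.NONE  # family level unreachable, demote
    # NONE: half the failures return nothing, half a wrong-family taxon
    if rng.random() < 0.5:
        return IdentificationClass.NONE, ""
    other_fams = [f for f in index.families if f != family]
    if other_fams:
        fam = other_fams[rng.integers(len(other_fams))]
        g = index.family_genera[fam][rng.integers(len(index.family_genera[fam]))]
        return IdentificationClass.NONE, f"{g} zzspuria"
    return IdentificationClass.NONE, ""


def generate_observations(species: pd.DataFrame, config: SimulationConfig,
                          ) -> tuple[pd.DataFrame, SimulationTruth]:
    """Draw the hierarchical observation table and its ground truth.

    Every species appears in the database setting; a ``p_field`` fraction
    also appears in the field setting.  Replicate counts are uniform over
    ``replicate_range`` per setting, annotations i.i.d. from
    ``covariate_probabilities``, and outcomes follow the sequential logit
    model described in the module docstring.
    """
    config.validate()
    if species.empty:
        raise ConfigurationError("species table is empty; nothing to observe")
    u = substream(config.seed, "intercepts").normal(
        0.0, config.sd_species, size=len(species))
    in_field = substream(config.seed, "field_membership").random(
        len(species)) < config.p_field

    index = _SpeciesIndex(species)
    names_arr = species["accepted_name"].to_numpy(object)
    genus_arr = species["genus"].to_numpy(object)
    family_arr = species["family"].to_numpy(object)
    frames = []
    truth_classes: dict[str, str] = {}
    counter = 0
    for setting in ("database", "field"):
        mask = np.ones(len(species), dtype=bool) if setting == "database" else in_field
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        lo, hi = config.replicate_range.get(setting, (1, 1))
        reps = substream(config.seed, setting, "replicates").integers(
            lo, hi + 1, size=idx.size)
        sp_rows = np.repeat(idx, reps)
        n_obs = sp_rows.size
        rng_cov = substream(config.seed, setting, "covariates")
        organs = _draw_categorical(
            rng_cov, config.covariate_probabilities["organs"], n_obs)
        focus = _draw_categorical(
            rng_cov, config.covariate_probabilities["focus"], n_obs)
        background = _draw_categorical(
            rng_cov, config.covariate_probabilities["background"], n_obs)

        ln_train = np.log(species["n_training_images"].to_numpy(float)[sp_rows])
        eta = (config.baseline_logit
               + config.beta_ln_train * ln_train
               + np.array([config.organ_effects[o] for o in organs])
               + config.focus_effect * (focus == "multiple")
               + np.array([config.background_effects[b] for b in background])
               + u[sp_rows])
        rng_out = substream(config.seed, setting, "outcomes")
        success = rng_out.random(n_obs) < expit(eta)
        genus_ok = rng_out.random(n_obs) < config.p_genus_given_fail
        family_ok = rng_out.random(n_obs) < config.p_family_given_genus_fail
        drawn = np.where(success, IdentificationClass.SPECIES,
                         np.where(genus_ok, IdentificationClass.GENUS,
                                  np.where(family_ok, IdentificationClass.FAMILY,
                                           IdentificationClass.NONE)))

        rng_sug = substream(config.seed, setting, "suggestions")
        obs_ids, suggested, realized = [], [], []
        prefix = setting[0].upper()
        for k in range(n_obs):
            j = sp_rows[k]
            cls, name = _suggestion_for_class(
                IdentificationClass(int(drawn[k])), names_arr[j], genus_arr[j],
                family_arr[j], index, rng_sug)
            obs_id = f"{prefix}{counter:06d}"
            counter += 1
            obs_ids.append(obs_id)
            suggested.append(name)
            realized.append(cls)
            truth_classes[obs_id] = cls.label
        frames.append(pd.DataFrame({
            "obs_id": obs_ids,
            "setting": setting,
            "verified_name": names_arr[sp_rows],
            "suggested_name": suggested,
            "organs": organs,
            "focus": focus,
            "background": background,
        }))

    obs = pd.concat(frames, ignore_index=True)
    counts = {c.label: 0 for c in
              (IdentificationClass.SPECIES, IdentificationClass.GENUS,
               IdentificationClass.FAMILY, IdentificationClass.NONE)}
    for lab in truth_classes.values():
        counts[lab] += 1
    truth = SimulationTruth(
        config=dataclasses.asdict(config),
        intercepts={str(n): float(v)
                    for n, v in zip(species["accepted_name"], u)},
        class_counts=counts,
        classes=truth_classes,
    )
    return obs, truth


def simulate_dataset(config: SimulationConfig,
                     ) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Convenience wrapper: species table, classified observations, truth."""
    species = generate_species_table(config)
    obs, truth = generate_observations(species, config)
    taxonomy = TaxonomyMap.from_species_table(species)
    obs = classify_table(obs, taxonomy)
    return obs, species, truth
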