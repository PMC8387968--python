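"""Iterated one-observation-per-species subsampling and its two null tests.

Species contribute very unequal numbers of photographs, so raw per-observation
percentages would be dominated by heavily photographed species.  The engine
here controls that pseudoreplication: in each of ``n_iter`` iterations one
observation per species is drawn uniformly at random, class percentages are
computed over species, and results are averaged across iterations.

The per-iteration species → class assignment matrix (the "iteration stream")
is materialized once and shared by every downstream analysis of a run, so
the paired setting comparison, the grouped cross-table tests and the
frequency null model all see the same resamples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._random import substream_seed
from .data_model import CLASS_LABELS, CLASS_ORDER
from .errors import ValidationError

__all__ = ["IterationStream", "IterationSummary", "PairedComparison",
           "FrequencyNullResult", "iterate_subsample", "compare_settings",
           "frequency_null_test"]

_N_CLASSES = len(CLASS_ORDER)


@dataclass
class IterationStream:
    """Per-iteration one-per-species class assignments.

    ``classes`` has shape (n_species, n_iter); entry (s, t) is the
    IdentificationClass value of the observation drawn for species ``s`` in
    iteration ``t``.
    """

    species: np.ndarray          # unique species names, shape (n_species,)
    classes: np.ndarray          # int8, shape (n_species, n_iter)

    @property
    def n_iterations(self) -> int:
        return self.classes.shape[1]

    def percentages(self) -> np.ndarray:
        """Per-iteration class percentages over species, shape (n_iter, 4),
        columns ordered best-first (species, genus, family, none)."""
        out = np.empty((self.classes.shape[1], _N_CLASSES))
        for k, cls in enumerate(CLASS_ORDER):
            out[:, k] = (self.classes == int(cls)).mean(axis=0) * 100.0
        return out


@dataclass
class IterationSummary:
    """Averaged class percentages from the iterated subsampling."""

    n_iterations: int
    per_iteration: np.ndarray             # (n_iter, 4) percentages
    averaged: dict[str, float]            # class label -> mean %
    cumulative: dict[str, float]          # ">=species" / ">=genus" / ">=family"
    mc_standard_error: dict[str, float]   # label -> SE of the mean %

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id_class": list(CLASS_LABELS),
            "mean_percent": [self.averaged[c] for c in CLASS_LABELS],
            "mc_se": [self.mc_standard_error[c] for c in CLASS_LABELS],
        })


@dataclass
class PairedComparison:
    """Share of iterations in which the field percentage exceeded the
    database percentage, per class, with tie mass reported separately."""

    n_iterations: int
    n_common_species: int
    exceedance: dict[str, float]
    tie_mass: dict[str, float]
    significant: dict[str, bool]
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id_class": list(CLASS_LABELS),
            "prop_field_higher": [self.exceedance[c] for c in CLASS_LABELS],
            "tie_mass": [self.tie_mass[c] for c in CLASS_LABELS],
            "significant": [self.significant[c] for c in CLASS_LABELS],
        })


@dataclass
class FrequencyNullResult:
    """Median regional frequency per identification class against a
    same-class-sizes randomization null."""

    median_frequency: dict[str, float]    # across-iteration median of medians
    p_value: dict[str, float]             # share of iterations null > empirical

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id_class": list(CLASS_LABELS),
            "median_frequency": [self.median_frequency[c] for c in CLASS_LABELS],
            "p_null_greater": [self.p_value[c] for c in CLASS_LABELS],
        })


# ---------------------------------------------------------------------------


def _build_stream(observations: pd.DataFrame, n_iter: int,
                  rng: np.random.Generator) -> IterationStream:
    codes = observations["class_code"].to_numpy()
    species = observations["verified_name"].to_numpy(object)
    uniq, inv = np.unique(species, return_inverse=True)
    order = np.argsort(inv, kind="stable")
    counts = np.bincount(inv, minlength=len(uniq))
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    classes = np.empty((len(uniq), n_iter), dtype=np.int8)
    for s in range(len(uniq)):
        obs_idx = order[starts[s]:starts[s] + counts[s]]
        if counts[s] == 1:
            classes[s, :] = codes[obs_idx[0]]
        else:
            picks = rng.integers(0, counts[s], size=n_iter)
            classes[s, :] = codes[obs_idx[picks]]
    return IterationStream(species=uniq, classes=classes)


def iterate_subsample(observations: pd.DataFrame, n_iter: int = 1000,
                      seed: int = 0, stream_name: str = "subsample",
                      ) -> tuple[IterationSummary, IterationStream]:
    """Run the one-per-species subsampling ``n_iter`` times.

    ``observations`` must carry ``class_code`` (see
    :func:`florastat.data_model.classify_table`).  Returns the averaged
    summary plus the raw iteration stream for downstream stages.
    """
    if len(observations) == 0:
        raise ValidationError("cannot subsample an empty observation table")
    if n_iter < 1:
        raise ValidationError("n_iter must be a positive integer")
    rng = np.random.default_rng(substream_seed(seed, stream_name))
    stream = _build_stream(observations, n_iter, rng)
    per_iter = stream.percentages()
    averaged = {lab: float(per_iter[:, k].mean())
                for k, lab in enumerate(CLASS_LABELS)}
    se = {lab: float(per_iter[:, k].std(ddof=1) / np.sqrt(n_iter)) if n_iter > 1
          else 0.0
          for k, lab in enumerate(CLASS_LABELS)}
    cumulative = {
        ">=species": averaged["species"],
        ">=genus": averaged["species"] + averaged["genus"],
        ">=family": averaged["species"] + averaged["genus"] + averaged["family"],
    }
    summary = IterationSummary(n_iterations=n_iter, per_iteration=per_iter,
                               averaged=averaged, cumulative=cumulative,
                               mc_standard_error=se)
    return summary, stream


def compare_settings(obs_db: pd.DataFrame, obs_field: pd.DataFrame,
                     n_iter: int = 1000, seed: int = 0, alpha: float = 0.05,
                     ) -> PairedComparison:
    """Paired database/field comparison over the species common to both.

    In each iteration one observation per common species is drawn
    independently in each setting; the exceedance proportion is the share of
    iterations where the field class percentage strictly exceeds the
    database one.  Proportions below ``alpha`` or above ``1 - alpha`` are
    flagged significant (two-tailed reading of the one-sided exceedance).
    """
    if len(obs_db) == 0 or len(obs_field) == 0:
        raise ValidationError("both observation tables must be nonempty")
    common = np.intersect1d(obs_db["verified_name"].unique(),
                            obs_field["verified_name"].unique())
    if common.size == 0:
        raise ValidationError("no species present in both settings")
    db = obs_db[obs_db["verified_name"].isin(common)]
    fd = obs_field[obs_field["verified_name"].isin(common)]
    _, s_db = iterate_subsample(db, n_iter, seed, stream_name="paired_database")
    _, s_fd = iterate_subsample(fd, n_iter, seed, stream_name="paired_field")
    p_db, p_fd = s_db.percentages(), s_fd.percentages()
    exceed, ties, sig = {}, {}, {}
    for k, lab in enumerate(CLASS_LABELS):
        exceed[lab] = float((p_fd[:, k] > p_db[:, k]).mean())
        ties[lab] = float((p_fd[:, k] == p_db[:, k]).mean())
        sig[lab] = bool(exceed[lab] < alpha or exceed[lab] > 1.0 - alpha)
    return PairedComparison(n_iterations=n_iter, n_common_species=common.size,
                            exceedance=exceed, tie_mass=ties,
                            significant=sig, alpha=alpha)


def frequency_null_test(stream: IterationStream, species: pd.DataFrame,
                        seed: int = 0) -> FrequencyNullResult:
    """Median-frequency null model over the iteration stream.

    Per iteration the median frequency of the species in each class is
    compared with the median of an equally sized random species set (a
    permutation of the class labels); the P value per class is the share of
    iterations where the null median is strictly larger.  Classes empty in
    an iteration contribute nothing to that iteration's comparison; a class
    empty in all iterations is reported as undefined (NaN), not an error.
    """
    freq_by_name = dict(zip(species["accepted_name"], species["frequency"]))
    missing = [s for s in stream.species if s not in freq_by_name]
    if missing:
        raise ValidationError(f"species without frequency: {missing[:5]}")
    freqs = np.array([float(freq_by_name[s]) for s in stream.species])
    rng = np.random.default_rng(substream_seed(seed, "frequency_null"))
    n_iter = stream.n_iterations
    emp = np.full((n_iter, _N_CLASSES), np.nan)
    null_greater = np.zeros((n_iter, _N_CLASSES))
    defined = np.zeros((n_iter, _N_CLASSES), dtype=bool)
    for t in range(n_iter):
        assign = stream.classes[:, t]
        perm = rng.permutation(len(freqs))
        for k, cls in enumerate(CLASS_ORDER):
            mask = assign == int(cls)
            if not mask.any():
                continue
            emp[t, k] = np.median(freqs[mask])
            # null: same class sizes, species drawn at random — permute the
            # frequency vector against the same membership mask
            null_med = np.median(freqs[perm][mask])
            defined[t, k] = True
            null_greater[t, k] = null_med > emp[t, k]
    med, pval = {}, {}
    for k, lab in enumerate(CLASS_LABELS):
        if defined[:, k].any():
            med[lab] = float(np.median(emp[defined[:, k], k]))
            pval[lab] = float(null_greater[defined[:, k], k].mean())
        else:
            med[lab] = float("nan")
            pval[lab] = float("nan")
    return FrequencyNullResult(median_frequency=med, p_value=pval)
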