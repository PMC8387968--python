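"""Training-image and frequency association analyses.

Species-level identification success (share of a species' observations
scored at species level) is correlated with the natural log of the number
of training images behind the classifier, and the training-image counts are
compared among species groups (families, growth forms, life forms,
habitats) with a type III F test on a linear model of ln(count) plus
Holm-adjusted pairwise contrasts and compact letters.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import IdentificationClass
from .errors import ValidationError
from .glmm import _holm, compact_letter_display

logger = logging.getLogger("florastat")

__all__ = ["CorrelationResult", "species_success", "training_correlation",
           "group_training_comparison", "GroupTrainingResult"]


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_value: float
    transform: str = "ln(n_training_images)"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"r": self.r, "n": self.n,
                              "p_value": self.p_value,
                              "transform": self.transform}])


def species_success(observations: pd.DataFrame) -> pd.DataFrame:
    """Per-species proportion of observations identified to species level.

    Returns columns ``verified_name``, ``n_obs``, ``success``; every species
    enters unweighted by its observation count in downstream analyses.
    """
    ok = observations["class_code"] == int(IdentificationClass.SPECIES)
    grp = observations.assign(_ok=ok.astype(float)).groupby(
        "verified_name", sort=True)
    out = grp["_ok"].agg(["size", "mean"]).reset_index()
    out.columns = ["verified_name", "n_obs", "success"]
    return out


def training_correlation(success: pd.DataFrame,
                         species: pd.DataFrame) -> CorrelationResult:
    """Pearson correlation of success proportion with ln(training images)."""
    merged = success.merge(
        species[["accepted_name", "n_training_images"]],
        left_on="verified_name", right_on="accepted_name", how="inner")
    pos = merged["n_training_images"] > 0
    if (~pos).any():
        logger.warning("%d species with zero training images excluded from "
                       "the ln-transformed correlation", int((~pos).sum()))
        merged = merged[pos]
    if len(merged) < 3:
        raise ValidationError("need at least 3 species for a correlation")
    x = np.log(merged["n_training_images"].to_numpy(float))
    y = merged["success"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance; correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=len(merged),
                             p_value=float(res.pvalue))


@dataclass
class GroupTrainingResult:
    grouping: str
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    means: pd.DataFrame         # group, n, mean_ln_train, se, letters
    contrasts: pd.DataFrame

    def anova_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "grouping": self.grouping, "F": self.f_statistic,
            "df_num": self.df_num, "df_den": self.df_den,
            "p_value": self.p_value,
        }])


def group_training_comparison(species: pd.DataFrame, grouping: str,
                              alpha: float = 0.05) -> GroupTrainingResult:
    """Does ln(training images) differ among species groups?

    One-factor linear model with a type III F test (identical to the overall
    factor test here, as the factor is the only term), group means with
    model SEs, Holm-adjusted pairwise t contrasts and compact letters.
    Groups with a single species are dropped with a warning.
    """
    df = species[species["n_training_images"] > 0].copy()
    df["ln_train"] = np.log(df["n_training_images"].to_numpy(float))
    sizes = df[grouping].value_counts()
    small = sizes.index[sizes < 2]
    if len(small):
        logger.warning("groups with a single species dropped from %s "
                       "comparison: %s", grouping, list(small))
        df = df[~df[grouping].isin(small)]
    groups = sorted(df[grouping].unique().tolist())
    if len(groups) < 2:
        raise ValidationError(
            f"need >= 2 groups with >= 2 species for grouping {grouping!r}")

    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    fit = ols("ln_train ~ C(Q('group_'))",
              data=df.rename(columns={grouping: "group_"})).fit()
    anova = sm.stats.anova_lm(fit, typ=3)
    row = anova.loc["C(Q('group_'))"]
    f_stat = float(row["F"])
    df_num = int(row["df"])
    df_den = int(anova.loc["Residual", "df"])
    p_val = float(row["PR(>F)"])

    g = df.groupby(grouping)["ln_train"]
    n = g.size()
    mean = g.mean()
    resid_var = fit.mse_resid
    se = np.sqrt(resid_var / n)

    pairs = list(itertools.combinations(groups, 2))
    est, ses, zs, ps = [], [], [], []
    for a, b in pairs:
        d = float(mean[a] - mean[b])
        sd = float(np.sqrt(resid_var * (1.0 / n[a] + 1.0 / n[b])))
        t = d / sd
        est.append(d); ses.append(sd); zs.append(t)
        ps.append(float(2.0 * stats.t.sf(abs(t), df_den)))
    p_adj = _holm(np.asarray(ps)) if pairs else np.array([])
    contrasts = pd.DataFrame({
        "level_1": [a for a, _ in pairs], "level_2": [b for _, b in pairs],
        "estimate": est, "se": ses, "z": zs, "p": ps, "p_holm": p_adj,
    })
    letters = compact_letter_display((groups, contrasts), alpha=alpha)
    means = pd.DataFrame({
        "group": groups,
        "n_species": [int(n[x]) for x in groups],
        "mean_ln_train": [float(mean[x]) for x in groups],
        "se": [float(se[x]) for x in groups],
        "letters": [letters[x] for x in groups],
    })
    return GroupTrainingResult(grouping=grouping, f_statistic=f_stat,
                               df_num=df_num, df_den=df_den, p_value=p_val,
                               means=means, contrasts=contrasts)
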