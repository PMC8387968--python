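"""Fixed-marginal randomization machinery for group × class cross tables.

Under the null hypothesis that identification class is independent of the
grouping (family, growth form, …), a contingency table conditioned on its
row and column sums follows the multiple hypergeometric law.  This module
implements, from scratch:

* a Patefield-style sampler drawing tables from that law by sequential
  conditional (scalar) hypergeometric draws, vectorized over many tables;
* the exact table probability and a Fisher exact test, by full enumeration
  for small tables and Monte-Carlo estimation otherwise;
* the per-cell randomization test: z-score of each observed cell against
  the mean and standard deviation of its randomized counterparts, with the
  lower-tail normal probability Φ(z) flagged outside (0.05, 0.95);
* the grouped analysis that applies all of the above across the iterated
  one-per-species subsamples.

Averaged cross tables have non-integer cells; their margins are integerized
by largest-remainder rounding before sampling, while the observed cell
values stay real-valued for the z computation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtr

from ._random import substream
from .data_model import CLASS_LABELS
from .errors import ValidationError

logger = logging.getLogger("florastat")

__all__ = [
    "sample_fixed_margin_table", "sample_fixed_margin_tables",
    "table_log_prob", "enumerate_tables", "fisher_exact_enum",
    "fisher_exact_mc", "fisher_pvalue", "FisherSummary",
    "CellRandomization", "cell_randomization_test", "integerize_margins",
    "grouped_class_analysis", "GroupedClassResult",
]

_LOG_TIE_TOL = 1e-9


# ---------------------------------------------------------------------------
# Patefield sampler
# ---------------------------------------------------------------------------


def _check_margins(rows: np.ndarray, cols: np.ndarray) -> None:
    if (rows < 0).any() or (cols < 0).any():
        raise ValidationError("margins must be nonnegative")
    if rows.sum() != cols.sum():
        raise ValidationError(
            f"row total {int(rows.sum())} != column total {int(cols.sum())}")


def sample_fixed_margin_tables(row_margins, col_margins, size: int,
                               rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` tables with the given margins from the multiple
    hypergeometric (independence) distribution.

    Cells are filled row by row, left to right; each cell is a conditional
    hypergeometric draw given the remaining row quota and remaining column
    margins (Patefield's scheme).  The loop runs over cells only — all
    ``size`` tables advance through each cell in one vectorized draw.
    """
    rows = np.asarray(row_margins, dtype=np.int64)
    cols = np.asarray(col_margins, dtype=np.int64)
    _check_margins(rows, cols)
    r, c = rows.size, cols.size
    out = np.zeros((size, r, c), dtype=np.int64)
    colrem = np.tile(cols, (size, 1))
    for i in range(r):
        rowrem = np.full(size, rows[i], dtype=np.int64)
        pool = colrem.sum(axis=1)
        for j in range(c - 1):
            ngood = colrem[:, j]
            x = rng.hypergeometric(ngood, pool - ngood, rowrem)
            out[:, i, j] = x
            rowrem -= x
            pool -= ngood
            colrem[:, j] = ngood - x
        out[:, i, c - 1] = rowrem
        colrem[:, c - 1] -= rowrem
    return out


def sample_fixed_margin_table(row_margins, col_margins,
                              rng: np.random.Generator) -> np.ndarray:
    """Single Patefield draw, shape (r, c)."""
    return sample_fixed_margin_tables(row_margins, col_margins, 1, rng)[0]


def table_log_prob(tables: np.ndarray, row_margins, col_margins) -> np.ndarray:
    """Log multiple-hypergeometric probability of each table in ``tables``
    (shape (..., r, c)) under independence given the margins."""
    rows = np.asarray(row_margins, dtype=np.int64)
    cols = np.asarray(col_margins, dtype=np.int64)
    n = rows.sum()
    const = (gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
             - gammaln(n + 1))
    t = np.asarray(tables, dtype=np.int64)
    return const - gammaln(t + 1.0).sum(axis=(-2, -1))


# ---------------------------------------------------------------------------
# Fisher exact test (enumeration + Monte Carlo)
# ---------------------------------------------------------------------------


def enumeration_bound(row_margins, n_cols: int) -> float:
    """Cheap upper bound on the number of feasible tables."""
    bound = 1
    for r in np.asarray(row_margins):
        bound *= math.comb(int(r) + n_cols - 1, n_cols - 1)  # exact int math
        if bound > 10 ** 18:
            return math.inf
    return float(bound)


def enumerate_tables(row_margins, col_margins):
    """Yield every nonnegative integer table with the given margins."""
    rows = np.asarray(row_margins, dtype=np.int64)
    cols = np.asarray(col_margins, dtype=np.int64)
    _check_margins(rows, cols)
    r, c = rows.size, cols.size
    table = np.zeros((r, c), dtype=np.int64)

    def fill_row(i: int, colrem: np.ndarray):
        if i == r - 1:
            # last row forced by the column remainders
            if (colrem >= 0).all() and colrem.sum() == rows[i]:
                table[i, :] = colrem
                yield table.copy()
            return
        for comp in _compositions(int(rows[i]), colrem):
            table[i, :] = comp
            yield from fill_row(i + 1, colrem - comp)

    def _compositions(total: int, bounds: np.ndarray):
        c_ = bounds.size
        comp = np.zeros(c_, dtype=np.int64)

        def rec(j: int, remaining: int):
            if j == c_ - 1:
                if remaining <= bounds[j]:
                    comp[j] = remaining
                    yield comp
                return
            hi = min(remaining, int(bounds[j]))
            for v in range(hi + 1):
                comp[j] = v
                yield from rec(j + 1, remaining - v)

        yield from rec(0, total)

    yield from fill_row(0, cols.copy())


def fisher_exact_enum(table) -> float:
    """Exact Fisher P by full enumeration: total probability of tables no
    more probable than the observed one."""
    t = np.asarray(table, dtype=np.int64)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if rows.sum() == 0:
        logger.info("degenerate table (grand total 0); Fisher P set to 1")
        return 1.0
    obs_lp = table_log_prob(t, rows, cols)
    p = 0.0
    for cand in enumerate_tables(rows, cols):
        lp = table_log_prob(cand, rows, cols)
        if lp <= obs_lp + _LOG_TIE_TOL:
            p += math.exp(lp)
    return min(1.0, float(p))


def fisher_exact_mc(table, B: int = 2000,
                    rng: np.random.Generator | None = None) -> float:
    """Monte-Carlo Fisher P: ``(1 + #{draws with prob <= observed}) / (B+1)``
    over ``B`` fixed-margin draws."""
    t = np.asarray(table, dtype=np.int64)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if rows.sum() == 0:
        logger.info("degenerate table (grand total 0); Fisher P set to 1")
        return 1.0
    if rng is None:
        rng = np.random.default_rng()
    obs_lp = table_log_prob(t, rows, cols)
    draws = sample_fixed_margin_tables(rows, cols, B, rng)
    lps = table_log_prob(draws, rows, cols)
    return float((1 + (lps <= obs_lp + _LOG_TIE_TOL).sum()) / (B + 1))


def fisher_pvalue(table, B: int = 2000, rng: np.random.Generator | None = None,
                  exact_cap: int = 500) -> float:
    """Fisher P with automatic dispatch: full enumeration when the table
    count bound is at most ``exact_cap``, Monte Carlo otherwise."""
    t = np.asarray(table, dtype=np.int64)
    rows = t.sum(axis=1)
    if rows.sum() == 0:
        return 1.0
    if enumeration_bound(rows, t.shape[1]) <= exact_cap:
        return fisher_exact_enum(t)
    return fisher_exact_mc(t, B=B, rng=rng)


@dataclass
class FisherSummary:
    """Across-iteration Fisher exact test results."""

    p_values: np.ndarray

    @property
    def median_p(self) -> float:
        return float(np.median(self.p_values))

    @property
    def max_p(self) -> float:
        return float(np.max(self.p_values))


# ---------------------------------------------------------------------------
# Cell randomization test
# ---------------------------------------------------------------------------


def integerize_margins(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Largest-remainder rounding of the row and column sums of a real-valued
    table so that both integer margin vectors share the same total."""
    v = np.asarray(values, dtype=float)
    total = int(round(v.sum()))

    def round_to(x: np.ndarray, target: int) -> np.ndarray:
        base = np.floor(x).astype(np.int64)
        short = target - int(base.sum())
        if short < 0:  # rounding the total down crossed a floor boundary
            order = np.argsort(x - base, kind="stable")
            base[order[:-short]] -= 1
            return base
        order = np.argsort(-(x - base), kind="stable")
        base[order[:short]] += 1
        return base

    return round_to(v.sum(axis=1), total), round_to(v.sum(axis=0), total)


@dataclass
class CellRandomization:
    """Per-cell randomization results: z-scores against fixed-margin draws.

    ``prob`` is the lower-tail standard normal probability Φ(z); cells with
    prob > 0.95 are flagged ``higher``, prob < 0.05 ``lower``.
    """

    observed: np.ndarray
    mean_random: np.ndarray
    sd_random: np.ndarray
    z: np.ndarray
    prob: np.ndarray
    flag: np.ndarray          # object array of {"higher","lower","none"}
    n_random: int

    def to_frame(self, row_labels=None, col_labels=None) -> pd.DataFrame:
        r, c = self.observed.shape
        rows = row_labels if row_labels is not None else [str(i) for i in range(r)]
        cols = col_labels if col_labels is not None else [str(j) for j in range(c)]
        recs = []
        for i in range(r):
            for j in range(c):
                recs.append({
                    "group": rows[i], "id_class": cols[j],
                    "observed": self.observed[i, j],
                    "mean_random": self.mean_random[i, j],
                    "sd_random": self.sd_random[i, j],
                    "z": self.z[i, j], "prob": self.prob[i, j],
                    "flag": self.flag[i, j],
                })
        return pd.DataFrame(recs)


def cell_randomization_test(observed, n_rand: int = 1000,
                            rng: np.random.Generator | None = None,
                            row_margins=None, col_margins=None,
                            lower: float = 0.05, upper: float = 0.95,
                            ) -> CellRandomization:
    """z-score each observed cell against ``n_rand`` fixed-margin tables.

    ``observed`` may be real-valued (an averaged table); unless explicit
    integer margins are given, margins are integerized by largest-remainder
    rounding.  Cells whose randomized values have zero spread get z = 0 and
    prob = 0.5 (no evidence either way), logged.
    """
    obs = np.asarray(observed, dtype=float)
    if rng is None:
        rng = np.random.default_rng()
    if row_margins is None or col_margins is None:
        rows, cols = integerize_margins(obs)
    else:
        rows = np.asarray(row_margins, dtype=np.int64)
        cols = np.asarray(col_margins, dtype=np.int64)
    draws = sample_fixed_margin_tables(rows, cols, n_rand, rng)
    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1)
    z = np.zeros_like(obs)
    ok = sd > 0
    z[ok] = (obs[ok] - mean[ok]) / sd[ok]
    if (~ok).any():
        logger.info("%d cell(s) with zero randomization spread; z set to 0",
                    int((~ok).sum()))
    prob = np.where(ok, ndtr(z), 0.5)
    flag = np.full(obs.shape, "none", dtype=object)
    flag[prob > upper] = "higher"
    flag[prob < lower] = "lower"
    return CellRandomization(observed=obs, mean_random=mean, sd_random=sd,
                             z=z, prob=prob, flag=flag, n_random=n_rand)


# ---------------------------------------------------------------------------
# Grouped analysis over the iteration stream
# ---------------------------------------------------------------------------


@dataclass
class GroupedClassResult:
    grouping: str
    groups: list[str]
    group_sizes: dict[str, int]
    fisher: FisherSummary
    cells: CellRandomization
    averaged_table: np.ndarray            # (n_groups, 4) mean counts
    percentages: pd.DataFrame             # group x class percent of species

    def cells_frame(self) -> pd.DataFrame:
        frame = self.cells.to_frame(self.groups, list(CLASS_LABELS))
        sizes = frame["group"].map(self.group_sizes)
        frame.insert(1, "n_species", sizes)
        return frame


def grouped_class_analysis(stream, species: pd.DataFrame, grouping: str,
                           min_group_size: int = 10, fisher_B: int = 2000,
                           n_rand: int = 1000, seed: int = 0,
                           exact_cap: int = 500) -> GroupedClassResult:
    """Cross-table analysis of identification class against a species trait.

    Per subsampling iteration a group × class count table is built and
    Fisher-tested; the across-iteration averaged table is integerized and
    passed to the cell randomization test.  Groups with fewer than
    ``min_group_size`` species are dropped before any computation.
    """
    if grouping not in ("family", "growth_form", "life_form", "habitat"):
        raise ValidationError(f"unknown grouping {grouping!r}")
    trait = dict(zip(species["accepted_name"], species[grouping]))
    missing = [s for s in stream.species if s not in trait]
    if missing:
        raise ValidationError(f"species without {grouping}: {missing[:5]}")
    labels = np.array([trait[s] for s in stream.species], dtype=object)
    uniq, counts = np.unique(labels, return_counts=True)
    keep = uniq[counts >= min_group_size]
    if keep.size < 2:
        raise ValidationError(
            f"fewer than 2 groups with >= {min_group_size} species for "
            f"grouping {grouping!r}")
    sel = np.isin(labels, keep)
    groups = sorted(keep.tolist())
    gidx = np.array([groups.index(l) for l in labels[sel]])
    classes = stream.classes[sel, :]
    n_groups, n_iter = len(groups), classes.shape[1]
    n_cls = len(CLASS_LABELS)
    # class_code 3..0 -> column 0..3 (best-first ordering)
    col_of_code = np.array([3, 2, 1, 0])

    rng_fisher = substream(seed, "grouped", grouping, "fisher")
    tables = np.zeros((n_iter, n_groups, n_cls), dtype=np.int64)
    pvals = np.empty(n_iter)
    for t in range(n_iter):
        cols_t = col_of_code[classes[:, t]]
        tab = np.bincount(gidx * n_cls + cols_t,
                          minlength=n_groups * n_cls).reshape(n_groups, n_cls)
        tables[t] = tab
        pvals[t] = fisher_pvalue(tab, B=fisher_B, rng=rng_fisher,
                                 exact_cap=exact_cap)

    averaged = tables.mean(axis=0)
    rows_int, cols_int = integerize_margins(averaged)
    cells = cell_randomization_test(
        averaged, n_rand=n_rand,
        rng=substream(seed, "grouped", grouping, "cells"),
        row_margins=rows_int, col_margins=cols_int)

    sizes = {g: int((labels[sel] == g).sum()) for g in groups}
    pct = pd.DataFrame(
        averaged / np.array([sizes[g] for g in groups])[:, None] * 100.0,
        index=groups, columns=list(CLASS_LABELS)).rename_axis("group")
    return GroupedClassResult(grouping=grouping, groups=groups,
                              group_sizes=sizes,
                              fisher=FisherSummary(p_values=pvals),
                              cells=cells, averaged_table=averaged,
                              percentages=pct)
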