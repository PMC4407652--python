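"""Cohort-level trait statistics.

Works on a *trait table*: one row per plant with identifier columns
(``plant_id``, ``line_id``, ``experiment_id``) followed by the 25 trait
columns.  Provides per-line summaries (mean, standard error, n with NaN
values excluded pairwise), a Welch two-sample comparison between lines,
a pairwise-complete Spearman rank-correlation matrix with raw and
Benjamini–Hochberg-adjusted p-values, and a partition of traits into
correlation classes: connected components of the graph joining trait pairs
with rho at or above a threshold (default 0.7, matching the convention of
calling rho in [0.7, 0.99] a strong association).

An optional fixed-effect centering by experiment is provided in place of
full mixed-model (BLUE/BLUP) adjustment, which is deliberately out of scope.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import SchemaError
from .traits import TRAIT_NAMES, TraitVector

ID_COLUMNS = ("plant_id", "line_id", "experiment_id")


def trait_table(vectors: list[TraitVector]) -> pd.DataFrame:
    """Assemble TraitVectors into the canonical trait table."""
    if not vectors:
        raise SchemaError("no trait vectors to tabulate")
    df = pd.DataFrame([v.as_row() for v in vectors],
                      columns=list(ID_COLUMNS) + list(TRAIT_NAMES))
    if df["plant_id"].duplicated().any():
        dup = sorted(df.loc[df["plant_id"].duplicated(), "plant_id"].unique())
        raise SchemaError(f"duplicate plant_id(s) in trait table: {dup}")
    return df


def _check_table(table: pd.DataFrame, traits=None) -> list[str]:
    traits = list(traits) if traits is not None else list(TRAIT_NAMES)
    missing = [t for t in traits if t not in table.columns]
    if missing:
        raise SchemaError(f"trait table missing column(s): {missing}")
    return traits


def line_summary(table: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Per-line mean, standard error of the mean, and n for each trait.

    Undefined (NaN) values are excluded per trait; ``n`` reflects the
    exclusions.  SE is NaN when n < 2.
    """
    traits = _check_table(table, traits)
    if table.empty:
        raise SchemaError("empty trait table")
    rows = []
    for line_id, group in table.groupby("line_id", dropna=False, sort=True):
        for trait in traits:
            x = group[trait].dropna().to_numpy(dtype=float)
            n = len(x)
            mean = float(np.mean(x)) if n else np.nan
            se = float(np.std(x, ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
            rows.append({"line_id": line_id, "trait": trait,
                         "mean": mean, "se": se, "n": n})
    return pd.DataFrame(rows)


@dataclass
class LineComparison:
    """Welch two-sample comparison of one trait between two lines."""

    trait: str
    line_a: str
    line_b: str
    mean_a: float
    mean_b: float
    difference: float          # mean_a − mean_b
    percent_difference: float  # 100 · difference / mean_b
    statistic: float
    pvalue: float
    n_a: int
    n_b: int


def compare_lines(table: pd.DataFrame, line_a: str, line_b: str,
                  trait: str) -> LineComparison:
    """Welch's unequal-variance t comparison of ``trait`` between two lines."""
    _check_table(table, [trait])
    groups = {}
    for line in (line_a, line_b):
        x = table.loc[table["line_id"] == line, trait].dropna().to_numpy(float)
        if len(x) < 2:
            raise SchemaError(
                f"line {line!r}: need >= 2 non-missing observations of "
                f"{trait}, got {len(x)}")
        groups[line] = x
    a, b = groups[line_a], groups[line_b]
    if np.var(a) == 0.0 and np.var(b) == 0.0 and np.mean(a) == np.mean(b):
        stat, p = 0.0, 1.0  # identical constant groups: no evidence, not NaN
    else:
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    diff = mean_a - mean_b
    pct = 100.0 * diff / mean_b if mean_b != 0 else np.nan
    return LineComparison(trait=trait, line_a=line_a, line_b=line_b,
                          mean_a=mean_a, mean_b=mean_b, difference=diff,
                          percent_difference=pct, statistic=float(stat),
                          pvalue=float(p), n_a=len(a), n_b=len(b))


@dataclass
class CorrelationMatrix:
    """Pairwise-complete Spearman structure of a trait table.

    ``rho``/``pvalues``/``fdr``/``n`` are square DataFrames indexed by trait;
    ``reasons`` maps (trait_i, trait_j) to a code when rho is undefined
    (constant trait, too few complete pairs).
    """

    traits: list[str]
    rho: pd.DataFrame
    pvalues: pd.DataFrame
    fdr: pd.DataFrame
    n: pd.DataFrame
    reasons: dict[tuple[str, str], str]


def spearman_matrix(table: pd.DataFrame, traits=None,
                    min_pairs: int = 3) -> CorrelationMatrix:
    """Spearman rank correlation (average ranks for ties) for all trait pairs.

    Each pair uses its pairwise-complete observations; pairs with fewer than
    ``min_pairs`` complete rows, or with a constant trait, are NaN with a
    reason code.  Off-diagonal p-values are two-sided tests of rho = 0;
    ``fdr`` holds Benjamini–Hochberg-adjusted p-values over the
    k(k−1)/2 unique pairs.
    """
    traits = _check_table(table, traits)
    k = len(traits)
    rho = np.eye(k)
    pval = np.full((k, k), np.nan)
    np.fill_diagonal(pval, 0.0)
    npairs = np.zeros((k, k), dtype=int)
    reasons: dict[tuple[str, str], str] = {}
    data = table[traits].to_numpy(dtype=float)
    np.fill_diagonal(npairs, np.sum(~np.isnan(data), axis=0))
    upper: list[tuple[int, int]] = [(i, j) for i in range(k)
                                    for j in range(i + 1, k)]
    for i, j in upper:
        ok = ~np.isnan(data[:, i]) & ~np.isnan(data[:, j])
        x, y = data[ok, i], data[ok, j]
        npairs[i, j] = npairs[j, i] = len(x)
        if len(x) < min_pairs:
            rho[i, j] = rho[j, i] = np.nan
            reasons[(traits[i], traits[j])] = "too_few_complete_pairs"
            continue
        if np.all(x == x[0]) or np.all(y == y[0]):
            rho[i, j] = rho[j, i] = np.nan
            reasons[(traits[i], traits[j])] = "constant_trait"
            continue
        r, p = stats.spearmanr(x, y)
        rho[i, j] = rho[j, i] = r
        pval[i, j] = pval[j, i] = p
    # BH adjustment over defined unique pairs
    fdr = np.full((k, k), np.nan)
    np.fill_diagonal(fdr, 0.0)
    defined = [(i, j) for i, j in upper if not np.isnan(pval[i, j])]
    if defined:
        adj = stats.false_discovery_control(
            [pval[i, j] for i, j in defined], method="bh")
        for (i, j), q in zip(defined, adj):
            fdr[i, j] = fdr[j, i] = q

    def frame(a):
        return pd.DataFrame(a, index=traits, columns=traits)

    return CorrelationMatrix(traits=list(traits), rho=frame(rho),
                             pvalues=frame(pval), fdr=frame(fdr),
                             n=frame(npairs), reasons=reasons)


def trait_classes(matrix: CorrelationMatrix,
                  threshold: float = 0.7) -> list[list[str]]:
    """Partition traits into correlation classes.

    Traits i and j are linked when rho_ij >= ``threshold`` (NaN never
    links); classes are the connected components of that graph, each sorted
    in canonical trait order, returned with largest classes first.
    """
    traits = matrix.traits
    k = len(traits)
    rho = matrix.rho.to_numpy()
    adj = np.zeros((k, k))
    with np.errstate(invalid="ignore"):
        mask = np.nan_to_num(rho, nan=-np.inf) >= threshold
    np.fill_diagonal(mask, False)
    adj[mask] = 1.0
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    classes = [[traits[i] for i in range(k) if labels[i] == c]
               for c in range(n_comp)]
    classes.sort(key=lambda cls: (-len(cls), traits.index(cls[0])))
    return classes


def center_by_experiment(table: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Fixed-effect centering: per trait, subtract each experiment's mean and
    add back the grand mean.  A labelled, simple stand-in for mixed-model
    adjustment of experiment effects; rows with missing experiment_id are
    left unchanged."""
    traits = _check_table(table, traits)
    out = table.copy()
    for trait in traits:
        grand = out[trait].mean(skipna=True)
        known = out["experiment_id"].notna()
        shifted = out.loc[known].groupby("experiment_id")[trait] \
            .transform(lambda s: s - s.mean())
        out.loc[known, trait] = shifted + grand
    return out
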