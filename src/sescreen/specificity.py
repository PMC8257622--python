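"""Tissue-specificity screen: SI, permutation pSI, TSI and the two-axis filter.

The specificity index SI(g, t) of gene g for tissue t is the mean, over all
other tissues u, of g's rank (1 = best, average ranks on ties) when genes are
ordered by descending expression ratio

    r(g) = (mean_t(g) + pseudocount) / (mean_u(g) + pseudocount),

computed on group-mean expression.  Low SI means g's expression is
consistently enriched in t.  pSI(g, t) is a permutation p-value for SI built
by shuffling the sample -> tissue assignment, recomputing SI, and pooling the
null SI values per tissue across genes; the add-one correction keeps pSI in
(0, 1].  TSI aggregates a gene's pSI row to a single score,
``-log10(max pSI)``; with the optional ``max_psi`` mask, tissues where the
gene is not called specific (pSI above the cutoff) are excluded from the max,
mirroring the convention of specificity-index software in which
non-candidate entries are undefined.  Genes with no specific tissue then get
TSI = 0.

The candidate screen intersects high TSI (computed on normal-tissue
expression) with high expression variance across a tumor cohort (sample
variance of log2(x + 1)), emulating a two-axis scatter selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class ExpressionMatrix:
    """A gene x sample abundance table with optional per-sample group labels.

    ``values`` holds non-negative abundances (TPM-like units) indexed by
    gene id; ``groups`` maps each sample (column) to its tissue/group label
    and is required for specificity analysis (>= 2 groups, every group
    non-empty) but not for cohort variance.
    """

    values: pd.DataFrame
    groups: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.values.columns)
            if self.groups.isna().any():
                missing = list(self.values.columns[self.groups.isna()])
                raise ValueError(f"samples without a group label: {missing}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def tissues(self) -> List[str]:
        if self.groups is None:
            raise ValueError("no group labels attached")
        return list(pd.unique(self.groups))

    def group_codes(self) -> Tuple[np.ndarray, List[str]]:
        tissues = self.tissues
        index = {t: i for i, t in enumerate(tissues)}
        codes = np.array([index[g] for g in self.groups], dtype=np.intp)
        return codes, tissues

    def group_means(self) -> pd.DataFrame:
        codes, tissues = self.group_codes()
        means = _group_means(self.values.to_numpy(dtype=float), codes, len(tissues))
        return pd.DataFrame(means, index=self.genes, columns=tissues)


@dataclass
class SpecificityResult:
    """SI / pSI matrices and per-gene TSI from one permutation run."""

    si: pd.DataFrame
    psi: pd.DataFrame
    tsi: pd.Series
    n_perm: int
    seed: int


@dataclass
class ScreenResult:
    """The retained two-axis table and the thresholded candidate list."""

    table: pd.DataFrame  # columns: tsi, variance, candidate
    tsi_min: float
    var_min: float
    candidates: List[str]


def _group_means(values: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Column-group means of a genes x samples array (groups per column)."""
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    if np.any(counts == 0):
        raise ValueError("every group needs at least one sample")
    sums = np.zeros((values.shape[0], n_groups))
    np.add.at(sums.T, codes, values.T)
    return sums / counts


def _si_from_means(means: np.ndarray, pseudocount: float) -> np.ndarray:
    """SI matrix (genes x tissues) from a group-mean matrix.

    All T*(T-1) pairwise comparisons are ranked in one call: gene ranks by
    descending ratio (rank 1 = most enriched, average ranks on ties),
    averaged over the T-1 comparisons of each tissue.
    """
    n_genes, n_tissues = means.shape
    shifted = means + pseudocount
    cols_t, cols_u = [], []
    for t in range(n_tissues):
        for u in range(n_tissues):
            if u != t:
                cols_t.append(t)
                cols_u.append(u)
    ratios = shifted[:, cols_t] / shifted[:, cols_u]
    ranks = rankdata(-ratios, axis=0, method="average")
    return ranks.reshape(n_genes, n_tissues, n_tissues - 1).mean(axis=2)


def specificity_index(
    expr: ExpressionMatrix, tissue: str, pseudocount: float = 1.0
) -> pd.Series:
    """Per-gene SI for one tissue (lower = more specific)."""
    mat = specificity_index_matrix(expr, pseudocount=pseudocount)
    if tissue not in mat.columns:
        raise ValueError(f"tissue {tissue!r} not present")
    return mat[tissue]


def specificity_index_matrix(
    expr: ExpressionMatrix, pseudocount: float = 1.0
) -> pd.DataFrame:
    codes, tissues = expr.group_codes()
    if len(tissues) < 2:
        raise ValueError("specificity analysis needs at least 2 groups")
    si = _si_from_means(
        _group_means(expr.values.to_numpy(dtype=float), codes, len(tissues)),
        pseudocount,
    )
    return pd.DataFrame(si, index=expr.genes, columns=tissues)


def _count_distinct_permutations(codes: np.ndarray) -> int:
    counts = np.bincount(codes)
    total = math.factorial(len(codes))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def _distinct_permutations(codes: np.ndarray) -> Iterator[np.ndarray]:
    """All distinct permutations of a label vector, lexicographic order."""
    seq = sorted(int(c) for c in codes)
    n = len(seq)
    while True:
        yield np.array(seq, dtype=np.intp)
        # next lexicographic permutation
        i = n - 2
        while i >= 0 and seq[i] >= seq[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while seq[j] <= seq[i]:
            j -= 1
        seq[i], seq[j] = seq[j], seq[i]
        seq[i + 1 :] = reversed(seq[i + 1 :])


def psi(
    expr: ExpressionMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Gene x tissue permutation p-values of the specificity index.

    The null pools SI values per tissue across genes and label
    permutations; pSI(g, t) = (1 + #{null <= SI(g, t)}) / (1 + N_null).
    When the number of distinct label permutations is <= ``n_perm`` the
    null is enumerated exhaustively (and is then seed-independent),
    otherwise ``n_perm`` random label shuffles are drawn from ``seed``.
    """
    return specificity(expr, n_perm=n_perm, seed=seed, pseudocount=pseudocount).psi


def specificity(
    expr: ExpressionMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> SpecificityResult:
    """Run the full SI -> pSI -> TSI computation (TSI here is unmasked)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    codes, tissues = expr.group_codes()
    n_tissues = len(tissues)
    if n_tissues < 2:
        raise ValueError("specificity analysis needs at least 2 groups")
    values = expr.values.to_numpy(dtype=float)
    n_genes = values.shape[0]

    si_obs = _si_from_means(_group_means(values, codes, n_tissues), pseudocount)

    if _count_distinct_permutations(codes) <= n_perm:
        perms: List[np.ndarray] = list(_distinct_permutations(codes))
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(codes) for _ in range(n_perm)]

    null = np.empty((len(perms) * n_genes, n_tissues))
    for k, perm in enumerate(perms):
        si_p = _si_from_means(_group_means(values, perm, n_tissues), pseudocount)
        null[k * n_genes : (k + 1) * n_genes] = si_p

    n_null = null.shape[0]
    psi_mat = np.empty_like(si_obs)
    for t in range(n_tissues):
        pool = np.sort(null[:, t])
        leq = np.searchsorted(pool, si_obs[:, t], side="right")
        psi_mat[:, t] = (1.0 + leq) / (1.0 + n_null)

    psi_df = pd.DataFrame(psi_mat, index=expr.genes, columns=tissues)
    si_df = pd.DataFrame(si_obs, index=expr.genes, columns=tissues)
    return SpecificityResult(
        si=si_df, psi=psi_df, tsi=tsi(psi_df), n_perm=len(perms), seed=seed
    )


def tsi(psi_matrix, max_psi: Optional[float] = None):
    """Tissue specificity index: ``-log10(max pSI)`` per gene.

    ``psi_matrix`` may be a DataFrame/2-D array (one row per gene; returns a
    Series/array) or a single row (returns a scalar).  All entries must lie
    in (0, 1].  With ``max_psi`` set, entries above the cutoff are treated
    as "not specific in this tissue" and excluded from the max; genes with
    no remaining entry get max pSI = 1, i.e. TSI = 0.
    """
    is_frame = isinstance(psi_matrix, pd.DataFrame)
    arr = np.asarray(psi_matrix, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, :]
    if arr.size == 0:
        raise ValueError("empty pSI matrix")
    if np.any(arr <= 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
        raise ValueError("pSI values must lie in (0, 1]")
    if max_psi is None:
        row_max = arr.max(axis=1)
    else:
        masked = np.where(arr <= max_psi, arr, 0.0)
        row_max = masked.max(axis=1)
        row_max = np.where(row_max == 0.0, 1.0, row_max)  # no specific tissue
    out = -np.log10(row_max)
    out = np.maximum(out, 0.0)  # clip -0.0
    if is_frame:
        return pd.Series(out, index=psi_matrix.index, name="tsi")
    return float(out[0]) if squeeze else out


def specificity_ranking(tsi_values: pd.Series, si: pd.DataFrame) -> pd.Index:
    """Genes ordered by descending TSI, most specific first.

    A permutation pSI is quantized to multiples of 1/(1 + N_null), so genes
    whose SI undercuts the finite null pool collapse onto the same TSI even
    when their underlying statistics differ; ties are therefore broken by
    the gene's best (smallest) SI across tissues — the statistic the
    p-value summarizes — and then by gene id for determinism.
    """
    if not tsi_values.index.equals(si.index):
        raise ValueError("tsi and si must be indexed by the same genes")
    best_si = si.min(axis=1)
    order = sorted(
        tsi_values.index, key=lambda g: (-tsi_values[g], best_si[g], g)
    )
    return pd.Index(order)


def expression_variance(cohort: ExpressionMatrix) -> pd.Series:
    """Per-gene sample variance (ddof=1) of log2(value + 1) across samples."""
    if cohort.values.shape[1] < 2:
        raise ValueError("variance needs at least 2 samples")
    logged = np.log2(cohort.values.to_numpy(dtype=float) + 1.0)
    return pd.Series(
        logged.var(axis=1, ddof=1), index=cohort.genes, name="variance"
    )


def screen(
    tsi_values: pd.Series,
    variance: pd.Series,
    tsi_min: Optional[float] = None,
    var_min: Optional[float] = None,
    percentile: float = 90.0,
) -> ScreenResult:
    """Two-axis candidate selection: high TSI and high cohort variance.

    Candidates are exactly the genes with ``tsi >= tsi_min`` and
    ``variance >= var_min``, sorted by descending TSI then variance.
    Thresholds default to the given percentile of each axis.
    """
    if not tsi_values.index.equals(variance.index):
        if set(tsi_values.index) != set(variance.index):
            raise ValueError("tsi and variance must be indexed by the same genes")
        variance = variance.reindex(tsi_values.index)
    if tsi_min is None:
        tsi_min = float(np.percentile(tsi_values.to_numpy(), percentile))
    if var_min is None:
        var_min = float(np.percentile(variance.to_numpy(), percentile))
    table = pd.DataFrame({"tsi": tsi_values, "variance": variance})
    table["candidate"] = (table["tsi"] >= tsi_min) & (table["variance"] >= var_min)
    cand = (
        table[table["candidate"]]
        .sort_values(["tsi", "variance"], ascending=False)
        .index.tolist()
    )
    return ScreenResult(
        table=table, tsi_min=float(tsi_min), var_min=float(var_min), candidates=cand
    )
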