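"""Ordination and inferential statistics for plate-vs-rumen consortia.

Covers Euclidean sample distances, classical principal coordinates
analysis (PCoA) with a per-axis variance decomposition, a two-way
PERMANOVA with sequential sums of squares on the Gower-centered distance
matrix, exact small-sample Wilcoxon tests (signed-rank and rank-sum),
Kruskal-Wallis, Holm-Bonferroni correction, and the percentile-binned
Pearson correlation between an OTU's relative abundance in the plated
sample and how many OTUs of a cultured subset fall in each abundance
percentile.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .core import OtuTable


# ---------------------------------------------------------------------------
# distances and ordination


def euclidean_distances(table: OtuTable) -> DistanceMatrix:
    """Pairwise Euclidean distances between sample rows.

    Meant for tables rarefied to a common depth; a warning is raised when
    sample totals differ, since Euclidean distances on unequal library
    sizes conflate depth with composition.
    """
    totals = table.sample_totals().to_numpy()
    if not table.relative and len(totals) > 1 and not np.all(totals == totals[0]):
        warnings.warn(
            "sample totals differ; Euclidean distances expect a rarefied table",
            stacklevel=2,
        )
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(table.data.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(d, ids=table.sample_ids)


@dataclass
class Ordination:
    """Classical-scaling embedding: coordinates, eigenvalues, variance shares."""

    coordinates: pd.DataFrame        # samples x axes (positive eigenvalues only)
    eigenvalues: np.ndarray          # all eigenvalues, descending
    proportion_explained: np.ndarray  # lambda_i / sum of positive lambdas


def pcoa(D: DistanceMatrix) -> Ordination:
    """Principal coordinates analysis by classical scaling.

    Double-centers -0.5 * D^2, eigendecomposes, and scales eigenvectors by
    the square roots of the positive eigenvalues.  Axes are ordered by
    eigenvalue descending; each axis's sign is fixed so that its
    largest-magnitude loading is positive.  Eigenvalues within numerical
    noise of zero are floored at zero.
    """
    d = np.asarray(D.data, dtype=float)
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    g = (g + g.T) / 2
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    eigvals[np.abs(eigvals) < tol] = 0.0
    positive = eigvals > 0
    pos_vals = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(pos_vals)
    for k in range(coords.shape[1]):
        if coords[np.argmax(np.abs(coords[:, k])), k] < 0:
            coords[:, k] = -coords[:, k]
    proportion = pos_vals / pos_vals.sum() if pos_vals.size else pos_vals
    return Ordination(
        coordinates=pd.DataFrame(
            coords,
            index=list(D.ids),
            columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
        ),
        eigenvalues=eigvals,
        proportion_explained=proportion,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaFactor:
    name: str
    sum_of_squares: float
    df: int
    pseudo_F: float
    p_value: float
    variance_explained: float


@dataclass
class PermanovaResult:
    factors: list[PermanovaFactor]
    residual_ss: float
    residual_df: int
    total_ss: float
    B: int
    seed: int

    def factor(self, name: str) -> PermanovaFactor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)


def _dummies(labels: np.ndarray) -> np.ndarray:
    levels = pd.unique(labels)
    return np.column_stack(
        [(labels == lev).astype(float) for lev in levels[1:]]
    ) if len(levels) > 1 else np.empty((len(labels), 0))


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())))
    q = q[:, :rank]
    return q @ q.T


def permanova_two_way(
    D: DistanceMatrix,
    factor_a: Sequence | pd.Series,
    factor_b: Sequence | pd.Series,
    B: int = 1000,
    seed: int = 0,
    names: tuple[str, str] = ("factorA", "factorB"),
) -> PermanovaResult:
    """Two-factor additive PERMANOVA with sequential (Type I) sums of squares.

    The distance matrix is Gower-centered; sums of squares are partitioned
    sequentially in the declared factor order, each factor's pseudo-F is
    tested against the residual, and P-values come from free permutation
    of sample labels (rows/columns of D), with the same B permutations
    reused for both factors.  Swap the argument order to obtain the other
    sequential decomposition.
    """

    def _align(labels) -> np.ndarray:
        if isinstance(labels, pd.Series):
            return labels.loc[list(D.ids)].to_numpy()
        arr = np.asarray(labels)
        if len(arr) != len(D.ids):
            raise ValueError("labels must cover all samples in D")
        return arr

    a = _align(factor_a)
    b = _align(factor_b)
    n = len(a)
    d = np.asarray(D.data, dtype=float)
    g = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ g @ j
    g = (g + g.T) / 2
    total_ss = float(np.trace(g))

    ones = np.ones((n, 1))
    xa = np.hstack([ones, _dummies(a)])
    xab = np.hstack([xa, _dummies(b)])
    df_a = np.linalg.matrix_rank(xa) - 1
    df_ab = np.linalg.matrix_rank(xab) - 1
    df_b = df_ab - df_a
    levels_b = len(pd.unique(b))
    if levels_b > 1 and df_b < levels_b - 1:
        raise ValueError(
            f"factors {names[0]!r} and {names[1]!r} are aliased: "
            f"{names[1]!r} adds only {df_b} of {levels_b - 1} degrees of freedom"
        )
    df_res = n - 1 - df_ab
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    ha = _hat(xa)
    hab = _hat(xab)

    def decompose(gm: np.ndarray) -> tuple[float, float, float]:
        tr_a = float((ha * gm).sum())
        tr_ab = float((hab * gm).sum())
        return tr_a, tr_ab - tr_a, float(np.trace(gm)) - tr_ab

    ss_a, ss_b, ss_res = decompose(g)

    def fstat(ss: float, df: int) -> float:
        if df == 0:
            return float("nan")
        return (ss / df) / (ss_res / df_res)

    f_a, f_b = fstat(ss_a, df_a), fstat(ss_b, df_b)

    rng = np.random.default_rng(seed)
    count_a = count_b = 0
    for _ in range(B):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        pa, pb, pres = decompose(gp)
        if df_a and (pa / df_a) / (pres / df_res) >= f_a:
            count_a += 1
        if df_b and (pb / df_b) / (pres / df_res) >= f_b:
            count_b += 1

    def pval(df: int, count: int) -> float:
        return 1.0 if df == 0 else (1 + count) / (B + 1)

    factors = [
        PermanovaFactor(names[0], ss_a, df_a, f_a, pval(df_a, count_a),
                        ss_a / total_ss if total_ss else 0.0),
        PermanovaFactor(names[1], ss_b, df_b, f_b, pval(df_b, count_b),
                        ss_b / total_ss if total_ss else 0.0),
    ]
    return PermanovaResult(
        factors=factors,
        residual_ss=ss_res,
        residual_df=df_res,
        total_ss=total_ss,
        B=B,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rank tests


def _doubled_ranks(values: np.ndarray) -> np.ndarray:
    """Midranks doubled to integers so tied data stay exactly representable."""
    ranks = sps.rankdata(values)
    doubled = np.round(ranks * 2).astype(np.int64)
    return doubled


def wilcoxon_signed_rank_exact(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided paired signed-rank P (enumeration for n <= 25).

    Zero differences are dropped before ranking; tied absolute differences
    take midranks.  For n <= 25 the full sign-assignment distribution of
    the positive-rank sum is enumerated (via convolution over the 2^n
    assignments); larger n falls back to the tie-corrected normal
    approximation.  The two-sided P doubles the smaller tail, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero; no signed-rank test")
    doubled = _doubled_ranks(np.abs(d))
    w2 = int(doubled[d > 0].sum())
    if n <= 25:
        total = int(doubled.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in doubled:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: total + 1 - r]
            counts = counts + shifted
        denom = 2.0**n
        p_le = counts[: w2 + 1].sum() / denom
        p_ge = counts[w2:].sum() / denom
        return min(1.0, 2.0 * min(p_le, p_ge))
    # normal approximation with tie correction
    w = w2 / 2.0
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(doubled, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (
        (tie_counts**3 - tie_counts).sum() / 48.0
    )
    z = (w - mean) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def wilcoxon_rank_sum_exact(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided rank-sum P (full enumeration when n + m <= 12).

    Ties take midranks; in the exact regime every assignment of ranks to
    the first group is enumerated, and the two-sided P doubles the smaller
    tail of the rank-sum statistic.  Larger samples use the tie-corrected
    normal approximation of the Mann-Whitney statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    n, m = len(x), len(y)
    combined = np.concatenate([x, y])
    doubled = _doubled_ranks(combined)
    w2 = int(doubled[:n].sum())
    if n + m <= 12:
        sums = [
            sum(doubled[i] for i in combo)
            for combo in itertools.combinations(range(n + m), n)
        ]
        sums = np.array(sums)
        total = len(sums)
        p_le = (sums <= w2).sum() / total
        p_ge = (sums >= w2).sum() / total
        return min(1.0, 2.0 * min(p_le, p_ge))
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H and chi-square P with midrank tie correction.

    Returns ``(H, p)``; identical values across all groups give (0, 1).
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def holm_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted P-values, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# abundance-cultivability correlation


def percentile_cultivability_correlation(
    sample_counts: pd.Series,
    cultured_sets: Mapping[str, Iterable[str]],
    n_bins: int = 100,
    mean_abundance_x: bool = True,
) -> dict[str, dict]:
    """Pearson correlation of cultured-OTU counts against abundance percentiles.

    The OTUs detected in ``sample_counts`` (one sample's counts, indexed by
    OTU id) are ranked by relative abundance and split into ``n_bins``
    equal-count rank bins (ties resolved by stable sort order).  For each
    cultured subset, ``y_b`` is the number of its members landing in bin b
    and ``x_b`` is the bin's mean relative abundance (or the bin index when
    ``mean_abundance_x`` is False); the result holds Pearson's r and its
    t-distribution P with n_bins - 2 degrees of freedom.  Subset members
    not detected in the sample (e.g. plate-only OTUs) are ignored with a
    warning.  Multiple-testing adjustment across an analysis run is the
    caller's job.
    """
    counts = sample_counts[sample_counts > 0]
    n_detected = len(counts)
    if n_detected == 0:
        raise ValueError("sample detected no OTUs")
    if n_bins > n_detected:
        raise ValueError(
            f"n_bins={n_bins} exceeds the {n_detected} detected OTUs; "
            "lower n_bins explicitly"
        )
    rel = counts / counts.sum()
    order = np.argsort(rel.to_numpy(), kind="stable")
    bins = np.array_split(order, n_bins)
    rel_values = rel.to_numpy()
    otu_ids = rel.index.to_numpy()
    x = np.array(
        [rel_values[b].mean() if mean_abundance_x else i for i, b in enumerate(bins)]
    )
    detected_set = set(otu_ids)
    bin_of = {}
    for b_idx, b in enumerate(bins):
        for i in b:
            bin_of[otu_ids[i]] = b_idx
    out: dict[str, dict] = {}
    for label, members in cultured_sets.items():
        members = set(members)
        ignored = members - detected_set
        if ignored:
            warnings.warn(
                f"subset {label!r}: {len(ignored)} OTUs not detected in the "
                "sample were ignored",
                stacklevel=2,
            )
        y = np.zeros(n_bins)
        for otu in members & detected_set:
            y[bin_of[otu]] += 1
        if np.all(y == y[0]) or np.all(x == x[0]):
            r, p = float("nan"), 1.0
        else:
            r, p = sps.pearsonr(x, y)
        out[label] = {
            "r": float(r),
            "p_raw": float(p),
            "n_bins": n_bins,
            "n_ignored": len(ignored),
        }
    return out


def apply_significance(
    cells: list[dict], r_threshold: float = 0.3, alpha: float = 0.05
) -> None:
    """Holm-adjust ``p_raw`` across cells in place and flag significance.

    A cell is significant when |r| exceeds the threshold *and* its
    Holm-adjusted P is below alpha.
    """
    if not cells:
        return
    adjusted = holm_bonferroni([c["p_raw"] for c in cells])
    for cell, p_adj in zip(cells, adjusted):
        cell["p_adjusted"] = float(p_adj)
        r = cell["r"]
        cell["significant"] = bool(
            not np.isnan(r) and abs(r) > r_threshold and p_adj < alpha
        )
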