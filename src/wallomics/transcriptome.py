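"""Microarray preprocessing, moderated differential expression, enrichment.

One-colour probe-level intensities are log2-transformed, normalized within
array by the weighted global median (bad spots carry weight 0 and are
excluded), quantile-normalized across arrays, and summarised per gene by the
median of replicate probes.  Differential expression between strains uses a
moderated t-test: per-gene variances are shrunk toward a prior estimated by
empirical Bayes (method of moments on log sample variances), the associated
p-values are Benjamini–Hochberg adjusted, and genes passing a fold-change
and p-value cut are intersected across strains.  Gene clusters are scored
against flat annotation categories with the upper-tail hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

__all__ = [
    "ExpressionMatrix",
    "EnrichmentResult",
    "preprocess",
    "quantile_normalize",
    "estimate_variance_prior",
    "moderated_ttest",
    "bh_adjust",
    "differential_expression",
    "de_filter",
    "common_set",
    "hypergeometric_enrichment",
]


@dataclass
class ExpressionMatrix:
    """Probes × arrays log2 intensities with spot weights and maps.

    ``values``: DataFrame (probe_id × array); ``weights``: same-shape 0/1
    DataFrame; ``probe_to_gene``: probe_id → gene symbol; ``array_to_group``:
    array name → strain.
    """

    values: pd.DataFrame
    weights: pd.DataFrame
    probe_to_gene: dict
    array_to_group: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != self.weights.shape:
            raise ValueError("values and weights must have identical shape")
        w = self.weights.to_numpy()
        if not np.isin(w, (0, 1)).all():
            raise ValueError("weights must be 0 or 1")
        unmapped = set(self.values.index) - set(self.probe_to_gene)
        if unmapped:
            raise ValueError(f"{len(unmapped)} probes lack a gene mapping")


@dataclass
class EnrichmentResult:
    """Hypergeometric overlap of one gene cluster with one category."""

    category: str
    k: int  # cluster genes in the category
    n: int  # cluster size
    f: int  # category size
    N: int  # universe size
    p: float  # upper-tail P(X >= k)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix) -> pd.DataFrame:
    """Force every array (column) onto the common quantile distribution.

    The target distribution is the row-mean of the column-sorted matrix;
    each value is replaced by the target value at its within-column rank,
    with tied ranks averaged (linear interpolation between adjacent targets).
    """
    df = pd.DataFrame(matrix).astype(float)
    arr = df.to_numpy()
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    grid = np.arange(arr.shape[0], dtype=float)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, target)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def preprocess(raw: pd.DataFrame, weights: pd.DataFrame, probe_to_gene: dict,
               array_to_group: dict | None = None,
               quantile_scope: str = "per_strain") -> pd.DataFrame:
    """Probe intensities → gene × array matrix of normalized log2 expression.

    Pipeline order: log2 transform → subtract each array's weighted global
    median (weight-1 spots only) → impute weight-0 spots with the array
    median (quantile normalization needs complete columns) → quantile
    normalize (within each strain by default, across all arrays with
    ``quantile_scope="all"``) → per-gene median over replicate probes.
    The gene-level median uses weight-1 spots only; the imputed values exist
    solely to complete the quantile step and re-enter a gene summary only
    when an array has no good spot at all for that gene (otherwise they
    would shrink that gene's apparent variance and miscalibrate the test).
    """
    if (weights.sum(axis=0) == 0).any():
        bad = list(weights.columns[weights.sum(axis=0) == 0])
        raise ValueError(f"arrays with all-zero weights: {bad}")
    w = weights.to_numpy().astype(bool)
    vals = raw.to_numpy(dtype=float)
    if np.any(vals[w] <= 0):
        raise ValueError("raw intensities must be positive where weight=1")
    log2 = np.where(w, np.log2(vals, where=vals > 0, out=np.full_like(vals, np.nan)),
                    np.nan)
    # weighted global median per array (weight-1 spots only)
    med = np.nanmedian(log2, axis=0)
    log2 = log2 - med
    # impute bad spots at the (now zero-centred) per-array median
    col_med = np.nanmedian(log2, axis=0)
    log2 = np.where(np.isnan(log2), col_med, log2)
    df = pd.DataFrame(log2, index=raw.index, columns=raw.columns)
    if quantile_scope == "per_strain" and array_to_group:
        groups: dict = {}
        for arr_name in df.columns:
            groups.setdefault(array_to_group[arr_name], []).append(arr_name)
        parts = [quantile_normalize(df[cols]) for cols in groups.values()]
        df = pd.concat(parts, axis=1)[raw.columns]
    else:
        df = quantile_normalize(df)
    gene = pd.Series({p: probe_to_gene[p] for p in df.index}, name="gene")
    good = df.where(weights.astype(bool))
    summary = good.groupby(gene).median()
    fallback = df.groupby(gene).median()
    return summary.fillna(fallback)


# ---------------------------------------------------------------------------
# Moderated t-test
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve polygamma(1, x) = y for x > 0 (Newton, monotone decreasing)."""
    if y <= 0:
        return float("inf")
    # Newton on f(x) = 1/trigamma(x), which is nearly linear in x
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = polygamma(1, x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x = max(x + step, 1e-8)
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(sample_vars: np.ndarray, dg: float) -> tuple[float, float]:
    """Method-of-moments prior (d0, s0²) from per-gene sample variances.

    On the scaled-F model s_g² ~ s0²·F(dg, d0), z = log s² has
    E[z] = log s0² + ψ(dg/2) − log(dg/2) − ψ(d0/2) + log(d0/2) and
    Var[z] = ψ'(dg/2) + ψ'(d0/2).  Matching the empirical mean and variance
    of z gives d0 via the trigamma inverse and s0² from the mean.  Returns
    ``d0 = inf`` when the variance of z is no larger than ψ'(dg/2) (no
    evidence of variance heterogeneity).
    """
    v = np.asarray(sample_vars, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size < 2:
        raise ValueError("need at least 2 positive sample variances")
    z = np.log(v)
    e = z - digamma(dg / 2.0) + np.log(dg / 2.0)
    excess = float(np.var(e, ddof=1)) - float(polygamma(1, dg / 2.0))
    if excess <= 0:
        return float("inf"), float(np.exp(e.mean()))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0sq = float(np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def moderated_ttest(groupA: np.ndarray, groupB: np.ndarray,
                    d0: float | None = None, s0sq: float | None = None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene moderated two-sample t statistics and two-sided p-values.

    ``groupA``/``groupB`` are genes × replicate matrices on the log2 scale.
    The pooled per-gene variance s_g² (dg = nA+nB−2 df) is shrunk toward the
    prior: s̃_g² = (d0·s0² + dg·s_g²)/(d0+dg); t = Δmean / (s̃·√(1/nA+1/nB))
  with d0+dg degrees of freedom.  When ``d0``/``s0sq`` are not supplied they
    are estimated from the data by :func:`estimate_variance_prior`.  ``d0=0``
    reduces to the ordinary pooled t-test.
    """
    A = np.atleast_2d(np.asarray(groupA, dtype=float))
    B = np.atleast_2d(np.asarray(groupB, dtype=float))
    nA, nB = A.shape[1], B.shape[1]
    if nA < 2 or nB < 2:
        raise ValueError("need at least 2 arrays per group")
    dg = nA + nB - 2
    varA = A.var(axis=1, ddof=1)
    varB = B.var(axis=1, ddof=1)
    s2 = ((nA - 1) * varA + (nB - 1) * varB) / dg
    if d0 is None or s0sq is None:
        if np.all(s2 <= 0):
            raise ValueError("all genes have zero variance; cannot estimate prior")
        est_d0, est_s0sq = estimate_variance_prior(s2, dg)
        d0 = est_d0 if d0 is None else d0
        s0sq = est_s0sq if s0sq is None else s0sq
    d0_eff = min(d0, 1e12)
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0sq)
    else:
        s2_tilde = (d0 * s0sq + dg * s2) / (d0 + dg)
    diff = A.mean(axis=1) - B.mean(axis=1)
    se = np.sqrt(s2_tilde * (1.0 / nA + 1.0 / nB))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    df_total = min(d0_eff + dg, 1e12)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR), input order kept.

    q(i) = min_{j>=i} m·p(j)/j over the ascending sort, clipped to [0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def differential_expression(expr: pd.DataFrame, array_to_group: dict,
                            group: str, reference: str,
                            d0: float | None = None,
                            s0sq: float | None = None) -> pd.DataFrame:
    """DE table (gene, log2_fc, t_mod, p, q) for one strain vs. a reference.

    ``expr`` is the gene × array matrix from :func:`preprocess`; fold change
    is the difference of group means on the log2 scale.
    """
    colsA = [c for c in expr.columns if array_to_group[c] == group]
    colsB = [c for c in expr.columns if array_to_group[c] == reference]
    if len(colsA) < 2 or len(colsB) < 2:
        raise ValueError("need >=2 arrays in each group")
    A, B = expr[colsA].to_numpy(), expr[colsB].to_numpy()
    t, p = moderated_ttest(A, B, d0=d0, s0sq=s0sq)
    return pd.DataFrame({
        "gene": expr.index,
        "log2_fc": A.mean(axis=1) - B.mean(axis=1),
        "t_mod": t,
        "p": p,
        "q": bh_adjust(p),
    }).set_index("gene")


def de_filter(results: pd.DataFrame, fc_threshold: float = 2.0,
              p_threshold: float = 0.01) -> set:
    """Genes with |log2 FC| ≥ log2(fc_threshold) and p < p_threshold."""
    if len(results) == 0:
        return set()
    mask = (results["log2_fc"].abs() >= np.log2(fc_threshold)) & \
           (results["p"] < p_threshold)
    return set(results.index[mask])


def common_set(sets: list) -> dict:
    """Full Venn partition of ≥2 gene sets.

    Returns ``{"intersection": genes in every set, "exclusive": [genes only
    in set i, ...], "partition": {membership tuple: genes}}`` where the
    membership tuple has one bool per input set.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    sets = [set(s) for s in sets]
    universe = set().union(*sets)
    partition: dict = {}
    for g in universe:
        key = tuple(g in s for s in sets)
        partition.setdefault(key, set()).add(g)
    k = len(sets)
    return {
        "intersection": partition.get((True,) * k, set()),
        "exclusive": [partition.get(tuple(i == j for j in range(k)), set())
                      for i in range(k)],
        "partition": partition,
    }


def hypergeometric_enrichment(cluster, category, universe_size: int,
                              name: str = "") -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of a gene cluster in a category.

    With N genes in the universe, f of them in the category and a cluster of
    n genes containing k category members, p = P(X ≥ k) for
    X ~ Hypergeometric(N, f, n).
    """
    cluster, category = set(cluster), set(category)
    n, f = len(cluster), len(category)
    if universe_size < n or universe_size < f:
        raise ValueError("universe smaller than cluster or category")
    k = len(cluster & category)
    p = float(stats.hypergeom.sf(k - 1, universe_size, f, n))
    return EnrichmentResult(category=name, k=k, n=n, f=f, N=universe_size,
                            p=min(max(p, 0.0), 1.0))
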