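"""Sparse-PLS two-block integration of gene expression with phenotypes.

Sparse partial least squares finds pairs of sparse loading vectors
(u_h, v_h) maximizing the covariance between linear combinations of the
gene block X and phenotype block Y, with an L1-style soft-threshold keeping
only the ``keepX``/``keepY`` largest loadings per component — variable
selection performed jointly with the search for correlated variables.
Downstream views are the correlation circle (variable correlations with the
first two latent scores) and the clustered image map (cross-block
similarities, hierarchically clustered and cut into variable groups).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "OmicsBlocks",
    "SplsModel",
    "SimilarityMap",
    "center_unit_scale",
    "spls_fit",
    "correlation_circle",
    "similarity_map",
]


@dataclass
class OmicsBlocks:
    """Paired samples × variables blocks (X genes, Y phenotypes), standardized."""

    X: pd.DataFrame
    Y: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.Y.index):
            raise ValueError("X and Y must share the same sample index (rows)")


@dataclass
class SplsModel:
    """Per-component sparse loadings and latent scores.

    ``u`` (genes × ncomp) and ``v`` (phenotypes × ncomp) are unit-norm sparse
    loading vectors; ``scores_x``/``scores_y`` the latent variables
    t_h = X_h u_h and s_h = Y_h v_h computed on the deflated blocks.
    """

    u: pd.DataFrame
    v: pd.DataFrame
    scores_x: pd.DataFrame
    scores_y: pd.DataFrame
    keepX: list
    keepY: list
    converged: list = field(default_factory=list)
    iterations: list = field(default_factory=list)

    @property
    def ncomp(self) -> int:
        return self.u.shape[1]

    def selected_x(self, comp: int = 0) -> list:
        """Gene names with nonzero loading on component ``comp`` (0-based)."""
        col = self.u.iloc[:, comp]
        return list(col.index[col != 0])


@dataclass
class SimilarityMap:
    """Phenotype × gene similarity matrix with clustered groupings."""

    matrix: pd.DataFrame  # phenotypes (rows) × genes (cols)
    row_groups: pd.Series  # phenotype → group id (1..k_pheno)
    col_groups: pd.Series  # gene → group id (1..k_gene)
    row_linkage: np.ndarray
    col_linkage: np.ndarray


# ---------------------------------------------------------------------------

def center_unit_scale(block: pd.DataFrame) -> pd.DataFrame:
    """Center each column to mean 0 and scale to SD 1 (ddof=1).

    Constant columns carry no correlation information; they are dropped with
    a warning rather than propagated as NaNs.
    """
    df = pd.DataFrame(block).astype(float)
    if df.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    sd = df.std(axis=0, ddof=1)
    constant = sd[sd == 0].index
    if len(constant):
        warnings.warn(f"dropping constant columns: {list(constant)}")
        df = df.drop(columns=constant)
        sd = sd.drop(constant)
    return (df - df.mean(axis=0)) / sd


def _soft_threshold_keep(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold so that at most ``keep`` entries stay nonzero."""
    if keep >= w.size:
        return w.copy()
    lam = np.sort(np.abs(w))[-(keep + 1)]  # (keep+1)-th largest magnitude
    return np.sign(w) * np.clip(np.abs(w) - lam, 0.0, None)


def _orient(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sign convention: largest-|entry| of u positive (deterministic output)."""
    i = int(np.argmax(np.abs(u)))
    if u[i] < 0:
        return -u, -v
    return u, v


def spls_fit(blocks: OmicsBlocks, ncomp: int = 2,
             keepX: int | list | None = None,
             keepY: int | list | None = None,
             max_iter: int = 500, tol: float = 1e-9) -> SplsModel:
    """Fit sparse PLS in regression mode (X predicts Y).

    Per component: alternate u ← soft_threshold(M v, keepX), u ← u/‖u‖ and
    v ← soft_threshold(Mᵀ u, keepY), v ← v/‖v‖ with M = XᵀY until the
    loadings move less than ``tol``; then deflate both blocks against the X
    score t = Xu (regression mode: X ← X − t pᵀ, Y ← Y − t cᵀ with p, c the
    regressions of X and Y on t).  With ``keepX=keepY=None`` (all variables)
    component 1 equals the leading singular-vector pair of XᵀY.
    """
    X = blocks.X.to_numpy(dtype=float).copy()
    Y = blocks.Y.to_numpy(dtype=float).copy()
    px, py = X.shape[1], Y.shape[1]
    kx = [px] * ncomp if keepX is None else \
        ([keepX] * ncomp if np.isscalar(keepX) else list(keepX))
    ky = [py] * ncomp if keepY is None else \
        ([keepY] * ncomp if np.isscalar(keepY) else list(keepY))
    for k, pmax, nm in ((kx, px, "keepX"), (ky, py, "keepY")):
        if any(not 1 <= v <= pmax for v in k):
            raise ValueError(f"{nm} entries must lie in [1, {pmax}]")

    U = np.zeros((px, ncomp))
    V = np.zeros((py, ncomp))
    T = np.zeros((X.shape[0], ncomp))
    S = np.zeros((X.shape[0], ncomp))
    converged, iterations = [], []
    for h in range(ncomp):
        M = X.T @ Y
        # initialize from the leading right singular vector of M
        _, _, Vt = np.linalg.svd(M, full_matrices=False)
        v = Vt[0]
        u = np.zeros(px)
        it, ok = 0, False
        for it in range(1, max_iter + 1):
            u_new = _soft_threshold_keep(M @ v, kx[h])
            nu = np.linalg.norm(u_new)
            if nu == 0:
                break
            u_new /= nu
            v_new = _soft_threshold_keep(M.T @ u_new, ky[h])
            nv = np.linalg.norm(v_new)
            if nv == 0:
                break
            v_new /= nv
            if np.linalg.norm(u_new - u) < tol and np.linalg.norm(v_new - v) < tol:
                u, v = u_new, v_new
                ok = True
                break
            u, v = u_new, v_new
        u, v = _orient(u, v)
        t = X @ u
        s = Y @ v
        tt = float(t @ t)
        if tt > 0:  # regression-mode deflation
            p_load = X.T @ t / tt
            c_load = Y.T @ t / tt
            X = X - np.outer(t, p_load)
            Y = Y - np.outer(t, c_load)
        U[:, h], V[:, h], T[:, h], S[:, h] = u, v, t, s
        converged.append(ok)
        iterations.append(it)
    comp_names = [f"comp{h + 1}" for h in range(ncomp)]
    return SplsModel(
        u=pd.DataFrame(U, index=blocks.X.columns, columns=comp_names),
        v=pd.DataFrame(V, index=blocks.Y.columns, columns=comp_names),
        scores_x=pd.DataFrame(T, index=blocks.X.index, columns=comp_names),
        scores_y=pd.DataFrame(S, index=blocks.X.index, columns=comp_names),
        keepX=kx, keepY=ky, converged=converged, iterations=iterations,
    )


def _variable_score_correlations(model: SplsModel, block: pd.DataFrame,
                                 ncomp: int) -> pd.DataFrame:
    """Pearson correlation of every block column with each X score t_h."""
    T = model.scores_x.iloc[:, :ncomp].to_numpy()
    B = block.to_numpy(dtype=float)
    Bc = B - B.mean(axis=0)
    Tc = T - T.mean(axis=0)
    sd_b = Bc.std(axis=0, ddof=0)
    sd_t = Tc.std(axis=0, ddof=0)
    keep = sd_b > 0
    R = np.full((B.shape[1], ncomp), np.nan)
    denom = np.outer(sd_b[keep], sd_t) * B.shape[0]
    R[keep] = (Bc[:, keep].T @ Tc) / denom
    return pd.DataFrame(R, index=block.columns,
                        columns=[f"comp{h + 1}" for h in range(ncomp)])


def correlation_circle(model: SplsModel, blocks: OmicsBlocks,
                       radius: float = 0.5) -> pd.DataFrame:
    """Correlation-circle coordinates of every variable in both blocks.

    Each variable is placed at (r1, r2) — its Pearson correlations with the
    first two latent scores — and flagged ``outside`` when
    √(r1² + r2²) > ``radius`` (well-represented on the first two
    components).  Zero-variance variables are excluded.
    """
    if model.ncomp < 2:
        raise ValueError("correlation circle needs at least 2 components")
    rows = []
    for name, block in (("gene", blocks.X), ("phenotype", blocks.Y)):
        R = _variable_score_correlations(model, block, 2)
        R = R.dropna()
        for var, (r1, r2) in R.iterrows():
            rows.append((var, name, r1, r2, float(np.hypot(r1, r2))))
    df = pd.DataFrame(rows, columns=["variable", "block", "r1", "r2", "radius"])
    df["outside"] = df["radius"] > radius
    return df.set_index("variable")


def similarity_map(model: SplsModel, blocks: OmicsBlocks,
                   k_pheno: int = 4, k_gene: int = 6,
                   genes: list | None = None) -> SimilarityMap:
    """Clustered image map: cross-block similarity with hierarchical groups.

    The similarity between phenotype j and gene i is
    Σ_h r_h(gene i)·r_h(pheno j) over the model's components, where r_h is
    the variable's correlation with score t_h.  Rows and columns are
    clustered (complete linkage, Euclidean distance on similarity profiles)
    and the trees cut into ``k_pheno`` and ``k_gene`` groups.  ``genes``
    restricts the gene axis (default: genes selected on any component).
    """
    ncomp = model.ncomp
    if genes is None:
        genes = sorted({g for h in range(ncomp) for g in model.selected_x(h)})
    if not genes:
        genes = list(blocks.X.columns)
    Rg = _variable_score_correlations(model, blocks.X[genes], ncomp).dropna()
    Rp = _variable_score_correlations(model, blocks.Y, ncomp).dropna()
    sim = pd.DataFrame(Rp.to_numpy() @ Rg.to_numpy().T,
                       index=Rp.index, columns=Rg.index)
    if k_pheno > sim.shape[0] or k_gene > sim.shape[1]:
        raise ValueError("requested more groups than variables on an axis")
    row_link = linkage(sim.to_numpy(), method="complete", metric="euclidean")
    col_link = linkage(sim.to_numpy().T, method="complete", metric="euclidean")
    row_groups = pd.Series(fcluster(row_link, k_pheno, criterion="maxclust"),
                           index=sim.index, name="group")
    col_groups = pd.Series(fcluster(col_link, k_gene, criterion="maxclust"),
                           index=sim.columns, name="group")
    return SimilarityMap(sim, row_groups, col_groups, row_link, col_link)
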