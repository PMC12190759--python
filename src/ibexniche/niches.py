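"""Compositional analysis of lesion immune membership.

Per-lesion immune counts are compositional (more of one type means
relatively less of another), so counts are re-expressed as centered
log-ratios (CLR) and then standardized per cell type to remove abundance
differences. Pairwise correlations of the standardized CLRs across lesions,
cut into modules by hierarchical clustering, recover co-occurring immune
niches; PCA on the same matrix summarizes each lesion's niche character as
its PC1 score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass
class NicheTable:
    """Lesion-by-type count, CLR, and standardized-CLR matrices."""

    counts: pd.DataFrame       # lesions x types, raw member counts
    clr: pd.DataFrame
    standardized: pd.DataFrame
    covariates: pd.DataFrame   # lesion_id, sample_id, genotype, size


@dataclass
class NicheModules:
    """Correlation modules and PCA of the standardized CLR matrix."""

    correlation: pd.DataFrame
    linkage: np.ndarray
    modules: pd.Series             # cell type -> module label (1..n_modules)
    loadings: pd.DataFrame         # types x PCs, unit norm columns
    scores: pd.DataFrame           # lesions x PCs + covariates
    variance_explained: np.ndarray


def clr_transform(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio per lesion: ln(x_i) - mean_j ln(x_j), x = count + pc.

    Rows sum to zero by construction. A pseudocount keeps zero counts
    finite; with pseudocount 0 every lesion must have all-positive counts.
    """
    x = counts.to_numpy(dtype=float) + pseudocount
    if np.any(x <= 0):
        bad = counts.index[(x <= 0).any(axis=1)].tolist()
        raise ValueError(
            f"zero counts with pseudocount {pseudocount}; lesions {bad[:5]} "
            "need a positive pseudocount"
        )
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=counts.index, columns=counts.columns)


def standardize_clr(clr: pd.DataFrame) -> pd.DataFrame:
    """Standardize each cell-type column to mean 0, SD 1 (ddof=1)."""
    if len(clr) < 2:
        raise ValueError("need >= 2 lesions to standardize")
    mu = clr.mean(axis=0)
    sd = clr.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"zero-variance cell types set to 0: {list(clr.columns[zero])}"
        )
        sd = sd.mask(zero, 1.0)
    out = (clr - mu) / sd
    out.loc[:, zero] = 0.0
    return out


def correlation_modules(standardized: pd.DataFrame,
                        n_modules: int = 2) -> tuple[pd.DataFrame, np.ndarray, pd.Series]:
    """Pearson correlations across lesions, cut into co-occurrence modules.

    Average-linkage hierarchical clustering on distance 1 - r; the tree is
    cut to exactly ``n_modules`` clusters.
    """
    types = list(standardized.columns)
    if len(standardized) < 3 or len(types) < 2:
        raise ValueError("need >= 3 lesions and >= 2 cell types")
    if n_modules > len(types):
        raise ValueError(f"n_modules={n_modules} exceeds {len(types)} cell types")
    corr = standardized.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=n_modules, criterion="maxclust")
    return corr, Z, pd.Series(labels, index=types, name="module")


def niche_pca(standardized: pd.DataFrame,
              covariates: pd.DataFrame | None = None) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of the standardized CLR matrix via SVD.

    Columns are centered (already near-zero mean), decomposed by SVD, and
    each component's sign is fixed so its largest-|loading| cell type loads
    positively. Returns (loadings, scores, variance_explained).
    """
    if len(standardized) < 3:
        raise ValueError("need >= 3 lesions for PCA")
    X = standardized.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = Vt.shape[0]
    # deterministic orientation
    for j in range(k):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    var = S**2 / max(len(X) - 1, 1)
    var_explained = var / var.sum() if var.sum() > 0 else var
    pcs = [f"PC{j + 1}" for j in range(k)]
    loadings = pd.DataFrame(Vt.T, index=standardized.columns, columns=pcs)
    scores = pd.DataFrame(U * S, index=standardized.index, columns=pcs)
    if covariates is not None:
        scores = pd.concat([covariates.set_index(scores.index), scores], axis=1)
    return loadings, scores, var_explained


def build_niche_table(lesion_df: pd.DataFrame,
                      pseudocount: float = 1.0) -> NicheTable:
    """Assemble the NicheTable from a lesion table with n_<type> columns."""
    count_cols = [c for c in lesion_df.columns if c.startswith("n_")]
    counts = lesion_df[count_cols].copy()
    counts.columns = [c[2:] for c in count_cols]
    counts.index = lesion_df["lesion_id"].to_numpy()
    clr = clr_transform(counts, pseudocount)
    std = standardize_clr(clr)
    cov_cols = [c for c in ("lesion_id", "sample_id", "genotype", "size",
                            "dormancy_class") if c in lesion_df.columns]
    return NicheTable(counts=counts, clr=clr, standardized=std,
                      covariates=lesion_df[cov_cols].copy())


def analyze_niches(table: NicheTable, n_modules: int = 2) -> NicheModules:
    """Run the module discovery and PCA on a built NicheTable."""
    corr, Z, modules = correlation_modules(table.standardized, n_modules)
    loadings, scores, var = niche_pca(table.standardized, table.covariates)
    return NicheModules(correlation=corr, linkage=Z, modules=modules,
                        loadings=loadings, scores=scores,
                        variance_explained=var)


def plot_niches(modules: NicheModules, heatmap_path=None, pca_path=None) -> None:
    """Correlation heatmap with module annotation and a PC1/PC2 scatter."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if heatmap_path is not None:
        order = modules.modules.sort_values().index
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(modules.correlation.loc[order, order], vmin=-1, vmax=1,
                       cmap="RdBu_r")
        ax.set_xticks(range(len(order)), order, rotation=90, fontsize=7)
        ax.set_yticks(range(len(order)), order, fontsize=7)
        fig.colorbar(im, ax=ax, label="Pearson r")
        fig.tight_layout()
        fig.savefig(heatmap_path)
        plt.close(fig)
    if pca_path is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        sc = modules.scores
        colors = {"control": "tab:blue", "ko": "tab:orange"}
        for geno, grp in sc.groupby("genotype"):
            ax.scatter(grp["PC1"], grp["PC2"], s=12, alpha=0.7,
                       label=geno, c=colors.get(geno))
        ax.set_xlabel(f"PC1 ({100 * modules.variance_explained[0]:.0f}%)")
        ax.set_ylabel(f"PC2 ({100 * modules.variance_explained[1]:.0f}%)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(pca_path)
        plt.close(fig)
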