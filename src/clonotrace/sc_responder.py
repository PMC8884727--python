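"""Single-cell responder analysis.

Starting from a raw cells-by-genes count matrix with control/EPO group
labels: QC filtering (noninformative gene-name patterns, minimum detected
genes per cell, mitochondrial-fraction ceiling), library-size
log-normalization, logistic-regression differential expression with a
DEG-count permutation null, signature module scoring with
expression-matched background correction, a composite up-minus-down
response score, 90th-percentile responder calling within the treated
group, and kNN projection of query cells onto a reference PCA/embedding.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_QC_PATTERNS = (r"^Gm\d", r"Rik$", r"^Rp[sl]")


@dataclass(frozen=True)
class ScParams:
    """Parameters of the single-cell arm.

    QC: gene-name discard patterns, minimum detected genes per cell,
    maximum mitochondrial read fraction (mt- prefix).  Normalization:
    library-size scale factor.  DE: prefilters (minimum expressing
    fraction, minimum absolute log-mean difference), alpha and adjustment.
    Module scoring: expression bins and control genes per signature gene.
    Responders: percentile within the treated group.  Mapping: number of
    PCs and neighbors.
    """

    qc_patterns: tuple[str, ...] = DEFAULT_QC_PATTERNS
    mito_prefix: str = "mt-"
    min_genes_per_cell: int = 1000
    max_mito_fraction: float = 0.10
    scale_factor: float = 1e4
    de_alpha: float = 0.05
    adjust_method: str = "bonferroni"
    min_pct: float = 0.1
    logfc_min: float = 0.25
    ridge: float = 1e-6
    nbins: int = 24
    nctrl: int = 100
    responder_percentile: float = 90.0
    n_pcs: int = 10
    n_hvg: int = 2000
    k_neighbors: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in [0, 1]")
        if not 0 < self.responder_percentile < 100:
            raise ValueError("responder_percentile must be in (0, 100)")
        if self.nbins < 1 or self.nctrl < 1 or self.n_pcs < 1 or self.k_neighbors < 1:
            raise ValueError("nbins, nctrl, n_pcs and k_neighbors must be positive")


@dataclass(frozen=True)
class GeneSignature:
    """Up- and downregulated gene lists of a response signature."""

    up: tuple[str, ...]
    down: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("up and down gene lists overlap")

    @classmethod
    def from_deg_table(cls, deg: pd.DataFrame) -> "GeneSignature":
        """Signature from a DEG table: flagged genes split by effect sign."""
        hits = deg[deg["deg"]]
        return cls(
            up=tuple(hits.index[hits["mean_diff"] > 0]),
            down=tuple(hits.index[hits["mean_diff"] < 0]),
        )


# ---------------------------------------------------------------------------
# QC and normalization


def _dense(X) -> np.ndarray:
    import scipy.sparse as sp

    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def qc_filter(adata, params: ScParams = ScParams()):
    """Drop noninformative genes and low-quality cells.

    Genes matching any of the QC name patterns are removed; cells with
    fewer detected genes than ``min_genes_per_cell`` or a mitochondrial
    read fraction above ``max_mito_fraction`` are removed.  Mitochondrial
    genes themselves are retained.  Returns (filtered AnnData, report).
    """
    pats = [re.compile(p) for p in params.qc_patterns]
    genes = pd.Index(adata.var_names)
    bad_genes = genes[[any(p.search(g) for p in pats) for g in genes]]
    kept = adata[:, ~genes.isin(bad_genes)].copy()

    X = _dense(kept.X)
    detected = (X > 0).sum(axis=1)
    mito_mask = pd.Index(kept.var_names).str.startswith(params.mito_prefix)
    totals = X.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, X[:, mito_mask].sum(axis=1) / np.maximum(totals, 1), 0.0)

    low_gene = detected < params.min_genes_per_cell
    high_mito = mito_frac > params.max_mito_fraction
    keep_cells = ~(low_gene | high_mito)
    report = {
        "n_genes_removed_pattern": int(len(bad_genes)),
        "genes_removed": [str(g) for g in bad_genes],
        "n_cells_removed_low_genes": int(low_gene.sum()),
        "n_cells_removed_high_mito": int((high_mito & ~low_gene).sum()),
        "cells_removed": [str(c) for c in kept.obs_names[~keep_cells]],
        "n_cells_kept": int(keep_cells.sum()),
        "n_genes_kept": int(kept.n_vars),
    }
    out = kept[keep_cells].copy()
    if out.n_obs == 0 or out.n_vars == 0:
        raise ValueError(f"QC filtering removed everything: {report}")
    return out, report


def log_normalize(adata, params: ScParams = ScParams()):
    """log(1 + count / cell_total * scale_factor), per cell."""
    X = _dense(adata.X).astype(float)
    totals = X.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("all-zero cell encountered; QC should remove such cells first")
    out = adata.copy()
    out.X = np.log1p(X / totals * params.scale_factor)
    out.uns["normalized"] = True
    return out


# ---------------------------------------------------------------------------
# differential expression


def _logistic_lrt(X: np.ndarray, y: np.ndarray, ridge: float, max_iter: int = 60) -> np.ndarray:
    """Vectorized per-gene logistic-regression likelihood-ratio p-values.

    For every gene g, fits logit P(group=1) = b0 + b1 * x_g by Newton
    iteration (a tiny ridge on the slope keeps perfectly separating genes
    finite) and compares to the intercept-only model with a chi-square(1)
    likelihood-ratio test.  X is cells x genes; y is 0/1.
    """
    n, G = X.shape
    y = y.astype(float)
    p_bar = y.mean()
    ll0 = n * (p_bar * np.log(p_bar) + (1 - p_bar) * np.log(1 - p_bar))

    b0 = np.full(G, np.log(p_bar / (1 - p_bar)))
    b1 = np.zeros(G)
    Xt = X.T  # genes x cells
    for _ in range(max_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * Xt, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        resid = y[None, :] - mu
        g0 = resid.sum(axis=1)
        g1 = (resid * Xt).sum(axis=1) - ridge * b1
        h00 = w.sum(axis=1)
        h01 = (w * Xt).sum(axis=1)
        h11 = (w * Xt**2).sum(axis=1) + ridge
        det = h00 * h11 - h01**2
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        step = np.maximum(1.0, np.maximum(np.abs(d0), np.abs(d1)) / 5.0)
        b0 += d0 / step
        b1 += d1 / step
        if max(np.abs(d0).max(initial=0), np.abs(d1).max(initial=0)) < 1e-8:
            break

    eta = np.clip(b0[:, None] + b1[:, None] * Xt, -30, 30)
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    ll1 = (y[None, :] * np.log(mu) + (1 - y[None, :]) * np.log(1 - mu)).sum(axis=1)
    lr = np.maximum(2.0 * (ll1 - ll0), 0.0)
    return sps.chi2.sf(lr, df=1)


def de_logistic(adata, group_key: str = "group", reference: str = "control",
                params: ScParams = ScParams()) -> pd.DataFrame:
    """Logistic-regression differential expression between two groups.

    Genes passing the prefilters (expressed in at least ``min_pct`` of
    either group and with absolute difference of group means of the
    log-normalized values at least ``logfc_min``) are tested with a
    likelihood-ratio test of group ~ expression vs intercept-only; p-values
    are Bonferroni-adjusted over the tested genes.  Returns a table
    indexed by gene with mean_diff, pct.1/pct.2, p_val, p_val_adj and the
    DEG flag (adjusted p below alpha).
    """
    if not adata.uns.get("normalized", False):
        raise ValueError("de_logistic expects log-normalized data")
    groups = pd.Series(adata.obs[group_key].astype(str).to_numpy(), index=adata.obs_names)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    other = [g for g in levels if g != reference][0]
    y = (groups == other).to_numpy()
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("each group needs at least two cells")

    X = _dense(adata.X)
    pct1 = (X[y] > 0).mean(axis=0)
    pct0 = (X[~y] > 0).mean(axis=0)
    mean_diff = X[y].mean(axis=0) - X[~y].mean(axis=0)
    tested = (np.maximum(pct0, pct1) >= params.min_pct) & (np.abs(mean_diff) >= params.logfc_min)
    genes = pd.Index(adata.var_names)

    pvals = _logistic_lrt(X[:, tested], y.astype(int), ridge=params.ridge)
    n_tested = int(tested.sum())
    if params.adjust_method == "bonferroni":
        padj = np.minimum(pvals * n_tested, 1.0)
    else:
        from statsmodels.stats.multitest import multipletests

        padj = multipletests(pvals, method=params.adjust_method)[1]

    table = pd.DataFrame(
        {
            "mean_diff": mean_diff[tested],
            "pct.1": pct1[tested],
            "pct.2": pct0[tested],
            "p_val": pvals,
            "p_val_adj": padj,
        },
        index=genes[tested],
    )
    table["deg"] = table["p_val_adj"] < params.de_alpha
    table = table.sort_values("p_val")
    table.attrs["n_tested"] = n_tested
    table.attrs["comparison"] = f"{other} vs {reference}"
    return table


def deg_count_permutation(
    adata,
    group_key: str = "group",
    reference: str = "control",
    params: ScParams = ScParams(),
    n_perm: int = 100,
    seed: int = 0,
) -> dict:
    """Permutation null for the number of differentially expressed genes.

    Group labels are permuted across cells ``n_perm`` times and the DEG
    count recomputed with identical settings each time; the p-value uses
    the add-one rule p = (1 + #{null >= observed}) / (1 + n_perm), so the
    smallest attainable p is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    observed = int(de_logistic(adata, group_key, reference, params)["deg"].sum())
    rng = np.random.default_rng(seed)
    labels = adata.obs[group_key].to_numpy()
    null_counts = np.empty(n_perm, dtype=int)
    shuffled = adata.copy()
    for j in range(n_perm):
        shuffled.obs[group_key] = rng.permutation(labels)
        null_counts[j] = int(de_logistic(shuffled, group_key, reference, params)["deg"].sum())
    p = (1.0 + int((null_counts >= observed).sum())) / (1.0 + n_perm)
    return {
        "observed_deg_count": observed,
        "null_counts": null_counts,
        "p_value": p,
        "n_perm": n_perm,
        "seed": seed,
    }


# ---------------------------------------------------------------------------
# module scoring and responder calling


def module_score(
    adata,
    gene_set: Sequence[str],
    params: ScParams = ScParams(),
    seed: int = 0,
) -> pd.Series:
    """Background-corrected per-cell mean expression of a gene set.

    All genes are ranked by mean expression across cells and cut into
    ``nbins`` equal-frequency bins; for each signature gene, up to
    ``nctrl`` control genes are drawn (uniformly, without replacement,
    excluding signature genes) from the same bin; the score is the mean
    expression over the signature genes minus the mean over the pooled
    control genes.  Deterministic for a given seed.
    """
    genes = pd.Index(adata.var_names)
    in_set = [g for g in gene_set if g in genes]
    missing = sorted(set(gene_set) - set(in_set))
    if not in_set:
        raise ValueError("gene set has no overlap with the matrix")
    if missing:
        warnings.warn(f"{len(missing)} signature genes absent from matrix: {missing[:5]}...")

    X = _dense(adata.X)
    data_avg = X.mean(axis=0)
    order = pd.Series(data_avg, index=genes).rank(method="first")
    bins = pd.qcut(order, q=min(params.nbins, len(genes)), labels=False)

    rng = np.random.default_rng(seed)
    set_idx = genes.get_indexer(in_set)
    set_set = set(in_set)
    control: set[str] = set()
    for g in in_set:
        bin_id = bins[g]
        pool = [x for x in genes[bins == bin_id] if x not in set_set]
        if not pool:
            continue
        take = min(params.nctrl, len(pool))
        control.update(rng.choice(pool, size=take, replace=False))
    if not control:
        raise ValueError("no control genes available for background correction")
    ctrl_idx = genes.get_indexer(sorted(control))

    score = X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
    out = pd.Series(score, index=adata.obs_names, name="module_score")
    out.attrs.update(nbins=params.nbins, nctrl=params.nctrl, seed=seed)
    return out


def composite_response_score(up_scores: pd.Series, down_scores: pd.Series) -> pd.Series:
    """Composite response score: upregulated minus downregulated module score."""
    if not up_scores.index.equals(down_scores.index):
        raise ValueError("up and down scores cover different cells")
    out = up_scores - down_scores
    out.name = "response_score"
    return out


def call_responders(
    scores: pd.Series,
    groups: pd.Series,
    treated: str = "EPO",
    params: ScParams = ScParams(),
) -> pd.Series:
    """Flag treated-group cells above the group's score percentile.

    The threshold is the ``responder_percentile`` quantile of the composite
    scores among treated cells; treated cells strictly above it are
    responders.  Control cells are never flagged.
    """
    groups = groups.astype(str)
    treated_mask = groups == treated
    n_treated = int(treated_mask.sum())
    if n_treated < 2:
        raise ValueError("too few treated cells to define the percentile")
    thr = float(np.percentile(scores[treated_mask], params.responder_percentile))
    flags = pd.Series(False, index=scores.index, name="responder")
    flags[treated_mask & (scores > thr)] = True
    flags.attrs["threshold"] = thr
    return flags


# ---------------------------------------------------------------------------
# reference mapping


@dataclass
class ReferenceMap:
    """Precomputed reference atlas for kNN mapping.

    Per-gene mean/SD of the (log-normalized) reference, PCA loadings over
    those genes, reference-cell PCA coordinates and a 2-D embedding per
    reference cell.
    """

    genes: pd.Index
    mean: np.ndarray
    std: np.ndarray
    loadings: np.ndarray  # genes x n_pcs
    ref_pcs: np.ndarray  # cells x n_pcs
    embedding: np.ndarray  # cells x 2
    cell_ids: pd.Index
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.loadings.shape[0] != len(self.genes):
            raise ValueError("loadings rows must match genes")
        if self.ref_pcs.shape[0] != len(self.cell_ids) or self.embedding.shape[0] != len(self.cell_ids):
            raise ValueError("every reference cell needs PCA and embedding coordinates")

    @property
    def n_pcs(self) -> int:
        return self.loadings.shape[1]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"gene": self.genes, "mean": self.mean, "std": self.std}).to_csv(
            out / "gene_stats.tsv", sep="\t", index=False
        )
        pd.DataFrame(self.loadings, index=self.genes).rename_axis("gene").to_csv(
            out / "loadings.tsv", sep="\t"
        )
        pd.DataFrame(self.ref_pcs, index=self.cell_ids).rename_axis("cell").to_csv(
            out / "pca_coords.tsv", sep="\t"
        )
        pd.DataFrame(self.embedding, index=self.cell_ids, columns=["e1", "e2"]).rename_axis(
            "cell"
        ).to_csv(out / "embedding.tsv", sep="\t")
        manifest = {"n_pcs": self.n_pcs, "n_genes": len(self.genes), "n_cells": len(self.cell_ids)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, in_dir: str | Path) -> "ReferenceMap":
        d = Path(in_dir)
        gs = pd.read_csv(d / "gene_stats.tsv", sep="\t")
        loadings = pd.read_csv(d / "loadings.tsv", sep="\t", index_col=0)
        pcs = pd.read_csv(d / "pca_coords.tsv", sep="\t", index_col=0)
        emb = pd.read_csv(d / "embedding.tsv", sep="\t", index_col=0)
        return cls(
            genes=pd.Index(gs["gene"]),
            mean=gs["mean"].to_numpy(),
            std=gs["std"].to_numpy(),
            loadings=loadings.to_numpy(),
            ref_pcs=pcs.to_numpy(),
            embedding=emb.to_numpy(),
            cell_ids=pcs.index,
        )


def build_reference_map(
    adata,
    params: ScParams = ScParams(),
    embedding: np.ndarray | None = None,
) -> ReferenceMap:
    """Build a reference map from a log-normalized reference matrix.

    Selects the top ``n_hvg`` genes by variance, stores their mean/SD,
    computes a deterministic PCA (``n_pcs`` components, signs fixed so the
    largest-magnitude loading of each component is positive) and attaches
    a 2-D embedding per reference cell — externally supplied, or the first
    two PCs as a deterministic stand-in.
    """
    from sklearn.decomposition import PCA

    if adata.n_obs <= params.n_pcs:
        raise ValueError("need more reference cells than principal components")
    X = _dense(adata.X)
    genes = pd.Index(adata.var_names)
    if len(genes) > params.n_hvg:
        variances = X.var(axis=0)
        top = np.sort(np.argsort(variances)[::-1][: params.n_hvg])
        X = X[:, top]
        genes = genes[top]
    else:
        warnings.warn("fewer genes than requested highly variable genes; using all")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std_safe = np.where(std > 1e-12, std, 1.0)
    Z = (X - mean) / std_safe

    n_pcs = min(params.n_pcs, min(Z.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    pcs = pca.fit_transform(Z)
    loadings = pca.components_.T  # genes x n_pcs
    # deterministic sign convention per component
    for j in range(n_pcs):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            pcs[:, j] *= -1

    if embedding is None:
        embedding = pcs[:, :2].copy()
    embedding = np.asarray(embedding, dtype=float)
    return ReferenceMap(
        genes=genes,
        mean=mean,
        std=std_safe,
        loadings=loadings,
        ref_pcs=pcs,
        embedding=embedding,
        cell_ids=pd.Index(adata.obs_names),
    )


def map_to_reference(
    adata,
    reference: ReferenceMap,
    params: ScParams = ScParams(),
) -> pd.DataFrame:
    """Project query cells into the reference PCA space and map by kNN.

    Query cells are restricted to the reference gene list, centered and
    scaled by the reference per-gene statistics (genes absent from the
    query contribute zero after scaling), projected through the reference
    loadings, and placed at the arithmetic mean of the embedding
    coordinates of their ``k_neighbors`` nearest reference cells
    (Euclidean distance in PCA space).
    """
    from sklearn.neighbors import NearestNeighbors

    q_genes = pd.Index(adata.var_names)
    shared = reference.genes.intersection(q_genes)
    if len(shared) == 0:
        raise ValueError("query and reference share no genes")
    if len(shared) < len(reference.genes):
        warnings.warn(
            f"{len(reference.genes) - len(shared)} reference genes absent from query; "
            "imputed as zero after scaling"
        )
    X = _dense(adata.X)
    Z = np.zeros((adata.n_obs, len(reference.genes)))
    ref_pos = {g: i for i, g in enumerate(reference.genes)}
    q_idx = q_genes.get_indexer(shared)
    r_idx = np.array([ref_pos[g] for g in shared])
    Z[:, r_idx] = (X[:, q_idx] - reference.mean[r_idx]) / reference.std[r_idx]

    pcs = Z @ reference.loadings
    k = min(params.k_neighbors, reference.ref_pcs.shape[0])
    nn = NearestNeighbors(n_neighbors=k).fit(reference.ref_pcs)
    _dist, nbr = nn.kneighbors(pcs)
    mapped = reference.embedding[nbr].mean(axis=1)
    out = pd.DataFrame(mapped, index=adata.obs_names, columns=["e1", "e2"])
    out["neighbors"] = [",".join(reference.cell_ids[row]) for row in nbr]
    return out
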