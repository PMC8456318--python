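"""Unsigned weighted co-expression network analysis.

Soft-power adjacency |PCC|^beta on log2(FPKM+1), topological overlap,
average-linkage module detection with a documented height-scan tree cut,
eigengene-based module merging, and module-trait/module-sample statistics
(gene significance and module membership).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .expression_profiles import ExpressionMatrix, log_expr
from .io_core import RunConfig

__all__ = [
    "AdjacencyMatrix",
    "ModuleSet",
    "ModuleTraitCor",
    "UNASSIGNED",
    "filter_expressed",
    "soft_adjacency",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "merge_modules",
    "module_trait_stats",
    "select_key_modules",
    "run_wgcna",
]

UNASSIGNED = -1  # reserved label for genes not in any module

# eigengene-correlation threshold for reattaching leftover genes after the cut
_REASSIGN_COR = 0.3


@dataclass
class AdjacencyMatrix:
    weights: pd.DataFrame  # genes x genes in [0,1], unit diagonal
    beta: float

    def __post_init__(self) -> None:
        w = self.weights.to_numpy()
        if not np.allclose(w, w.T):
            raise ValueError("adjacency must be symmetric")
        if (w < -1e-12).any() or (w > 1 + 1e-12).any():
            raise ValueError("adjacency weights outside [0,1]")


@dataclass
class ModuleSet:
    labels: pd.Series  # gene -> int label, UNASSIGNED for grey
    eigengenes: pd.DataFrame  # module label (column) x sample (index)

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {UNASSIGNED})

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])

    @property
    def sizes(self) -> dict[int, int]:
        return {m: int((self.labels == m).sum()) for m in self.module_ids}


@dataclass
class ModuleTraitCor:
    module_trait_cor: pd.DataFrame
    module_trait_p: pd.DataFrame
    module_sample_cor: pd.DataFrame
    gene_significance: pd.DataFrame  # genes x traits
    module_membership: pd.DataFrame  # genes x modules


def filter_expressed(expr: ExpressionMatrix, fpkm_min: float = 5.0) -> ExpressionMatrix:
    """Keep genes whose mean FPKM over the retained samples exceeds the cutoff."""
    keep = expr.fpkm.mean(axis=1) > fpkm_min
    if not keep.any():
        raise ValueError("no genes pass the expression filter")
    return ExpressionMatrix(expr.fpkm.loc[keep])


def soft_adjacency(expr: ExpressionMatrix, beta: float = 14.0) -> AdjacencyMatrix:
    """a_ij = |cor(x_i, x_j)|^beta with unit diagonal; zero-variance genes dropped."""
    log = log_expr(expr)
    variable = log.std(axis=1) > 0
    log = log.loc[variable]
    corr = np.corrcoef(log.to_numpy())
    corr = np.clip(corr, -1.0, 1.0)
    w = np.abs(corr) ** beta
    np.fill_diagonal(w, 1.0)
    genes = list(log.index)
    return AdjacencyMatrix(weights=pd.DataFrame(w, index=genes, columns=genes), beta=beta)


def tom_similarity(adj: AdjacencyMatrix) -> pd.DataFrame:
    """Unsigned topological overlap.

    omega_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij) with the
    sum over u != i,j and connectivity k_i excluding the diagonal; unit
    diagonal.
    """
    a = adj.weights.to_numpy().copy()
    np.fill_diagonal(a, 0.0)
    shared = a @ a  # includes u = i and u = j terms, which are zero off-diagonal
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = (shared + a) / (kmin + 1.0 - a)
    omega = np.nan_to_num(omega, nan=0.0)
    np.fill_diagonal(omega, 1.0)
    return pd.DataFrame(omega, index=adj.weights.index, columns=adj.weights.columns)


def _cut_heights(merge_heights: np.ndarray, n_scan: int = 120) -> np.ndarray:
    # scan the full merge-height range; high TOM powers compress heights near 1
    qs = np.linspace(0.05, 0.9999, n_scan)
    return np.unique(np.quantile(merge_heights, qs))


def _try_split(
    expr: ExpressionMatrix,
    tom: pd.DataFrame,
    members: list[str],
    min_module_size: int,
    split_cor_max: float,
) -> list[list[str]]:
    """Recursively re-cut a detected cluster on its own sub-dendrogram.

    A split is accepted when the best sub-cut yields >= 2 viable parts whose
    eigengenes are not all strongly correlated; genes falling into small
    fragments stay attached to the most correlated part.  Halves of a genuine
    module that do get split re-merge in the later eigengene merge step.
    """
    if len(members) < 2 * min_module_size:
        return [members]
    sub = 1.0 - tom.loc[members, members].to_numpy()
    np.fill_diagonal(sub, 0.0)
    z = linkage(squareform(sub, checks=False), method="average")
    best_parts: list[list[str]] | None = None
    for h in _cut_heights(z[:, 2], n_scan=60):
        cand = fcluster(z, t=h, criterion="distance")
        sizes = np.bincount(cand)
        count = int((sizes >= min_module_size).sum())
        if count >= 2 and (best_parts is None or count > len(best_parts)):
            big = {cl for cl in np.unique(cand) if sizes[cl] >= min_module_size}
            best_parts = [
                [g for g, c in zip(members, cand) if c == cl] for cl in sorted(big)
            ]
            leftovers = [g for g, c in zip(members, cand) if c not in big]
            best_parts_leftovers = leftovers
    if best_parts is None:
        return [members]
    eg = [module_eigengene(expr, p) for p in best_parts]
    cors = [
        abs(_pearson(eg[i], eg[j]))
        for i in range(len(eg))
        for j in range(i + 1, len(eg))
    ]
    if min(cors) >= split_cor_max:
        return [members]
    log = log_expr(expr)
    for g in best_parts_leftovers:
        x = log.loc[g].to_numpy()
        cs = [abs(_pearson(x, e)) for e in eg]
        best_parts[int(np.argmax(cs))].append(g)
    out = []
    for p in best_parts:
        out.extend(_try_split(expr, tom, p, min_module_size, split_cor_max))
    return out


def detect_modules(
    expr: ExpressionMatrix,
    tom: pd.DataFrame,
    min_module_size: int = 40,
    split_cor_max: float = 0.7,
) -> ModuleSet:
    """Average-linkage clustering on TOM dissimilarity with a height-scan cut.

    The dendrogram is cut at the height (scanned over merge-height quantiles)
    that yields the most clusters of size >= ``min_module_size``; each kept
    cluster is then recursively split while both halves stay viable and their
    eigengenes correlate below ``split_cor_max`` (average linkage chains
    weakly related blocks, and the later merge step would re-join halves of a
    genuine module).  Clusters below the size floor are dissolved and each
    leftover gene is reattached to the module whose eigengene correlates with
    it above 0.3 (else it stays unassigned).
    """
    genes = list(tom.index)
    n = len(genes)
    if n < min_module_size:
        labels = pd.Series(UNASSIGNED, index=genes)
        return ModuleSet(labels=labels, eigengenes=pd.DataFrame(index=expr.sample_ids))
    dissim = 1.0 - tom.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")

    best_labels, best_count = None, -1
    for h in _cut_heights(z[:, 2]):
        cand = fcluster(z, t=h, criterion="distance")
        sizes = np.bincount(cand)
        count = int((sizes >= min_module_size).sum())
        if count > best_count:
            best_count, best_labels = count, cand
    assert best_labels is not None

    labels = pd.Series(UNASSIGNED, index=genes, dtype=int)
    next_id = 0
    for cl in np.unique(best_labels):
        members = [g for g, b in zip(genes, best_labels) if b == cl]
        if len(members) < min_module_size:
            continue
        for part in _try_split(expr, tom, members, min_module_size, split_cor_max):
            labels[part] = next_id
            next_id += 1

    mods = ModuleSet(labels=labels, eigengenes=_all_eigengenes(expr, labels))

    # reattach leftovers by eigengene correlation
    if mods.module_ids and (labels == UNASSIGNED).any():
        log = log_expr(expr)
        eg = mods.eigengenes
        for g in labels.index[labels == UNASSIGNED]:
            x = log.loc[g].to_numpy()
            if x.std() == 0:
                continue
            cors = {m: _pearson(x, eg[m].to_numpy()) for m in mods.module_ids}
            best = max(cors, key=lambda m: cors[m])
            if cors[best] > _REASSIGN_COR:
                labels[g] = best
        mods = ModuleSet(labels=labels, eigengenes=_all_eigengenes(expr, labels))
    return mods


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def module_eigengene(expr: ExpressionMatrix, member_genes: list[str]) -> np.ndarray:
    """First right singular vector of the z-scored member expression.

    Unit norm over samples; sign chosen so the mean correlation with member
    genes is >= 0.  A single-gene module returns that gene's z-score profile
    (normalized).
    """
    if not member_genes:
        raise ValueError("empty module")
    log = log_expr(expr).loc[member_genes].to_numpy()
    mu = log.mean(axis=1, keepdims=True)
    sd = log.std(axis=1, keepdims=True)
    z = np.divide(log - mu, sd, out=np.zeros_like(log), where=sd > 0)
    if len(member_genes) == 1:
        v = z[0]
        nrm = np.linalg.norm(v)
        return v / nrm if nrm > 0 else v
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eg = vt[0]
    cors = np.array([_pearson(row, eg) for row in z])
    if cors.mean() < 0:
        eg = -eg
    return eg


def _all_eigengenes(expr: ExpressionMatrix, labels: pd.Series) -> pd.DataFrame:
    mods = sorted(set(labels) - {UNASSIGNED})
    data = {
        m: module_eigengene(expr, list(labels.index[labels == m])) for m in mods
    }
    return pd.DataFrame(data, index=expr.sample_ids)


def merge_modules(
    expr: ExpressionMatrix, mods: ModuleSet, merge_cut_height: float = 0.3
) -> ModuleSet:
    """Merge modules whose eigengene dissimilarity (1 - cor) falls below the cut.

    Single-linkage over eigengene dissimilarity, cut at ``merge_cut_height``;
    eigengenes are recomputed after merging and the procedure iterates until
    no further merges occur.
    """
    labels = mods.labels.copy()
    while True:
        module_ids = sorted(set(labels) - {UNASSIGNED})
        if len(module_ids) < 2:
            break
        eg = _all_eigengenes(expr, labels)
        cor = np.corrcoef(eg.to_numpy().T)
        dissim = np.clip(1.0 - cor, 0.0, None)
        np.fill_diagonal(dissim, 0.0)
        z = linkage(squareform(dissim, checks=False), method="single")
        groups = fcluster(z, t=merge_cut_height, criterion="distance")
        if len(set(groups)) == len(module_ids):
            break
        remap = {}
        for new_id, grp in enumerate(sorted(set(groups))):
            for m, g in zip(module_ids, groups):
                if g == grp:
                    remap[m] = new_id
        labels = labels.map(lambda m: remap.get(m, UNASSIGNED))
    return ModuleSet(labels=labels, eigengenes=_all_eigengenes(expr, labels))


def module_trait_stats(
    expr: ExpressionMatrix, mods: ModuleSet, traits: pd.DataFrame
) -> ModuleTraitCor:
    """Module-trait and module-sample correlations plus per-gene GS and MM."""
    samples = expr.sample_ids
    missing = [s for s in samples if s not in traits.index]
    if missing:
        raise ValueError(f"traits missing for samples: {missing}")
    traits = traits.loc[samples]
    eg = mods.eigengenes
    n = len(samples)
    mt_cor = pd.DataFrame(index=mods.module_ids, columns=traits.columns, dtype=float)
    mt_p = pd.DataFrame(index=mods.module_ids, columns=traits.columns, dtype=float)
    for m in mods.module_ids:
        for t in traits.columns:
            tv = traits[t].to_numpy(dtype=float)
            if np.std(tv) == 0:
                mt_cor.loc[m, t] = np.nan
                mt_p.loc[m, t] = np.nan
                continue
            r, p = stats.pearsonr(eg[m].to_numpy(), tv)
            mt_cor.loc[m, t] = r
            mt_p.loc[m, t] = p
    onehot = pd.get_dummies(pd.Series(samples, index=samples)).astype(float)
    ms_cor = pd.DataFrame(
        {
            s: [_pearson(eg[m].to_numpy(), onehot[s].to_numpy()) for m in mods.module_ids]
            for s in samples
        },
        index=mods.module_ids,
    )
    log = log_expr(expr)
    gs = pd.DataFrame(
        {
            t: [
                _pearson(log.loc[g].to_numpy(), traits[t].to_numpy(dtype=float))
                for g in log.index
            ]
            for t in traits.columns
        },
        index=log.index,
    )
    mm = pd.DataFrame(
        {
            m: [_pearson(log.loc[g].to_numpy(), eg[m].to_numpy()) for g in log.index]
            for m in mods.module_ids
        },
        index=log.index,
    )
    return ModuleTraitCor(
        module_trait_cor=mt_cor,
        module_trait_p=mt_p,
        module_sample_cor=ms_cor,
        gene_significance=gs,
        module_membership=mm,
    )


def select_key_modules(mtc: ModuleTraitCor, mods: ModuleSet) -> dict[str, int]:
    """Per trait, the module with the largest |PCC|.

    Ties break toward smaller p, then larger module size.
    """
    sizes = mods.sizes
    out = {}
    for t in mtc.module_trait_cor.columns:
        best = None
        for m in mtc.module_trait_cor.index:
            r = mtc.module_trait_cor.loc[m, t]
            p = mtc.module_trait_p.loc[m, t]
            if np.isnan(r):
                continue
            key = (abs(r), -p if not np.isnan(p) else 0.0, sizes.get(m, 0))
            if best is None or key > best[0]:
                best = (key, m)
        if best is not None:
            out[t] = best[1]
    return out


def run_wgcna(
    expr: ExpressionMatrix, traits: pd.DataFrame, config: RunConfig
) -> tuple[ModuleSet, ModuleTraitCor, dict[str, int]]:
    """Filter, build the network, detect + merge modules, and correlate with traits."""
    kept = filter_expressed(expr, config.fpkm_min_expressed)
    adj = soft_adjacency(kept, config.soft_power)
    kept = ExpressionMatrix(kept.fpkm.loc[adj.weights.index])  # drop zero-variance genes
    tom = tom_similarity(adj)
    mods = detect_modules(kept, tom, config.min_module_size)
    mods = merge_modules(kept, mods, config.merge_cut_height)
    mtc = module_trait_stats(kept, mods, traits)
    key = select_key_modules(mtc, mods)
    return mods, mtc, key
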