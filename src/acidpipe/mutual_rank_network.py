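"""Mutual-rank TF-candidate regulatory networks, one per variety.

The mutual rank of a gene pair is the geometric mean of the two directed
ranks of their Pearson correlation (each gene's partners sorted by
descending PCC, self excluded, best partner rank 1).  Edges are kept only
when the PCC clears the floor and both directed ranks clear the ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expression_profiles import ExpressionMatrix, log_expr

__all__ = [
    "MREdge",
    "MRNetwork",
    "pcc_matrix",
    "mutual_rank",
    "build_trn",
    "network_comparison",
]


@dataclass(frozen=True)
class MREdge:
    gene_a: str
    gene_b: str
    pcc: float
    rank_ab: float
    rank_ba: float

    @property
    def mr(self) -> float:
        return float(np.sqrt(self.rank_ab * self.rank_ba))


@dataclass
class MRNetwork:
    variety: str
    edges: list[MREdge]
    tfs: set[str]
    candidates: set[str]

    @property
    def tf_nodes(self) -> set[str]:
        present = {e.gene_a for e in self.edges} | {e.gene_b for e in self.edges}
        return present & self.tfs

    def partners_of(self, gene: str) -> set[str]:
        out = set()
        for e in self.edges:
            if e.gene_a == gene:
                out.add(e.gene_b)
            elif e.gene_b == gene:
                out.add(e.gene_a)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "nodeA": e.gene_a,
                    "nodeB": e.gene_b,
                    "pcc": e.pcc,
                    "rank_ab": e.rank_ab,
                    "rank_ba": e.rank_ba,
                    "mr": e.mr,
                }
                for e in self.edges
            ]
        )


def pcc_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Pearson correlation of log2(FPKM+1) profiles; zero-variance genes excluded."""
    if expr.fpkm.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    log = log_expr(expr)
    variable = log.std(axis=1) > 0
    log = log.loc[variable]
    corr = np.clip(np.corrcoef(log.to_numpy()), -1.0, 1.0)
    genes = list(log.index)
    return pd.DataFrame(corr, index=genes, columns=genes)


def mutual_rank(pcc: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Directed ranks and the mutual-rank matrix.

    Returns ``(ranks, mr)``: ``ranks[a, b]`` is b's position in a's
    descending-PCC partner list (self excluded, ties -> average ranks);
    ``mr`` is the symmetric geometric mean of the two directions.
    """
    c = pcc.to_numpy()
    n = c.shape[0]
    if n < 2:
        raise ValueError("need >= 2 genes")
    ranks = np.zeros_like(c)
    for i in range(n):
        row = np.delete(c[i], i)
        r = rankdata(-row, method="average")
        ranks[i, np.arange(n) != i] = r
    mr = np.sqrt(ranks * ranks.T)
    np.fill_diagonal(mr, 0.0)
    idx = pcc.index
    return (
        pd.DataFrame(ranks, index=idx, columns=idx),
        pd.DataFrame(mr, index=idx, columns=idx),
    )


def build_trn(
    pcc: pd.DataFrame,
    ranks: pd.DataFrame,
    tf_list: list[str],
    candidate_genes: list[str],
    variety: str = "",
    mr_pcc_min: float = 0.3,
    mr_rank_max: int = 5,
    include_tf_tf: bool = False,
) -> MRNetwork:
    """Retain TF-candidate edges with PCC >= floor and both directed ranks <= ceiling.

    By default only TF-candidate pairs are considered; ``include_tf_tf``
    additionally keeps TF-TF pairs (the network is always restricted to pairs
    with at least one TF).
    """
    if not candidate_genes:
        raise ValueError("empty candidate list")
    universe = set(pcc.index)
    tfs = [t for t in tf_list if t in universe]
    cands = [c for c in candidate_genes if c in universe]
    edges = []
    seen = set()
    pairs = [(t, c) for t in tfs for c in cands if t != c]
    if include_tf_tf:
        pairs += [(a, b) for i, a in enumerate(tfs) for b in tfs[i + 1:]]
    for a, b in pairs:
        key = tuple(sorted((a, b)))
        if key in seen:
            continue
        seen.add(key)
        r_ab = float(ranks.loc[a, b])
        r_ba = float(ranks.loc[b, a])
        p = float(pcc.loc[a, b])
        if p >= mr_pcc_min and r_ab <= mr_rank_max and r_ba <= mr_rank_max:
            edges.append(MREdge(gene_a=key[0], gene_b=key[1], pcc=p, rank_ab=r_ab, rank_ba=r_ba))
    return MRNetwork(variety=variety, edges=edges, tfs=set(tfs), candidates=set(cands))


def network_comparison(
    net_a: MRNetwork, net_d: MRNetwork, tf_families: dict[str, str] | None = None
) -> dict:
    """Shared/unique TF sets between two variety networks plus family histograms."""
    tfs_a, tfs_d = net_a.tf_nodes, net_d.tf_nodes
    out = {
        "shared_tfs": sorted(tfs_a & tfs_d),
        "unique_a": sorted(tfs_a - tfs_d),
        "unique_d": sorted(tfs_d - tfs_a),
        "n_tfs_a": len(tfs_a),
        "n_tfs_d": len(tfs_d),
    }
    if tf_families is not None:
        def hist(tfs: set[str]) -> dict[str, int]:
            h: dict[str, int] = {}
            for t in tfs:
                fam = tf_families.get(t, "unknown")
                h[fam] = h.get(fam, 0) + 1
            return dict(sorted(h.items()))

        out["family_hist_a"] = hist(tfs_a)
        out["family_hist_d"] = hist(tfs_d)
    return out
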