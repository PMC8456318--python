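"""Expression quantification and differential expression.

FPKM from fragment counts and merged exonic lengths, replicate QC and PCA on
log2(FPKM+1), a negative-binomial Wald test (median-of-ratios size factors,
method-of-moments dispersion, delta-method standard errors), DEG calling under
the joint FPKM/FDR/fold-change rule, pairwise contrast bookkeeping, and
hypergeometric enrichment against a user-supplied annotation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import (
    CountMatrix,
    GeneModel,
    MetadataMismatchError,
    RunConfig,
    SampleSheet,
    STAGES,
)

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "Contrast",
    "DEResult",
    "EnrichmentResult",
    "compute_fpkm",
    "log_expr",
    "replicate_qc",
    "pca_samples",
    "size_factors",
    "nb_wald_test",
    "call_degs",
    "pairwise_contrast_table",
    "tca_deg_matrix",
    "hypergeom_enrichment",
    "load_tca_deg_table",
]

# dispersion bounds for the method-of-moments estimate
_ALPHA_FLOOR = 1e-8
_ALPHA_CEIL = 10.0


@dataclass
class ExpressionMatrix:
    """FPKM values, genes x samples."""

    fpkm: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.fpkm.to_numpy()
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise ValueError("FPKM must be finite and >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fpkm.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.fpkm[list(sample_ids)])


def compute_fpkm(counts: CountMatrix, models: Sequence[GeneModel]) -> ExpressionMatrix:
    """FPKM[g,s] = count[g,s] / (totals[s]/1e6 * exonic_length_bp[g]/1e3)."""
    lengths = {m.gene_id: m.exonic_length_bp for m in models}
    missing = [g for g in counts.gene_ids if g not in lengths]
    if missing:
        raise MetadataMismatchError(f"genes without models: {missing[:10]}")
    len_kb = np.array([lengths[g] / 1e3 for g in counts.gene_ids])
    if (len_kb <= 0).any():
        raise ValueError("non-positive exonic lengths")
    mapped_millions = counts.totals.to_numpy(dtype=float) / 1e6
    if (mapped_millions <= 0).any():
        raise ValueError("non-positive mapped totals")
    fpkm = counts.counts.to_numpy(dtype=float) / (mapped_millions[None, :] * len_kb[:, None])
    return ExpressionMatrix(pd.DataFrame(fpkm, index=counts.counts.index, columns=counts.counts.columns))


def log_expr(expr: ExpressionMatrix) -> pd.DataFrame:
    """log2(FPKM + 1), the working scale for QC, PCA and all correlations."""
    return np.log2(expr.fpkm + 1.0)


def replicate_qc(
    expr: ExpressionMatrix, meta: SampleSheet, qc_pcc_min: float = 0.8
) -> list[str]:
    """Flag samples whose mean correlation with same-condition replicates is low.

    Within each condition the worst sample (lowest mean PCC of log2(FPKM+1)
    against the other replicates) is flagged and removed, and the criterion is
    re-evaluated on the remainder; a lone surviving replicate cannot be
    assessed and is retained.  One-shot flagging would discard good replicates
    dragged down by a single outlier.  Returns sample ids to exclude from
    downstream network construction.
    """
    log = log_expr(expr)
    flagged = []
    for cond, ids in meta.conditions().items():
        ids = [i for i in ids if i in log.columns]
        if len(ids) < 2:
            continue  # single replicate: nothing to compare against
        corr = log[ids].corr()
        remaining = list(ids)
        while len(remaining) >= 2:
            means = {
                sid: corr.loc[sid, [i for i in remaining if i != sid]].mean()
                for sid in remaining
            }
            worst = min(means, key=lambda s: means[s])
            if means[worst] >= qc_pcc_min:
                break
            flagged.append(worst)
            remaining.remove(worst)
    return flagged


def pca_samples(expr: ExpressionMatrix, n_components: int = 2, scale: bool = False):
    """Sample coordinates on the leading PCs of gene-centered log expression.

    Returns ``(coords, pct_variance)`` where coords is a samples x n_components
    DataFrame.  Sign convention: the sample coordinate of largest magnitude on
    each PC is positive.
    """
    if expr.fpkm.shape[1] < 3:
        raise ValueError("need >= 3 samples for PCA")
    x = log_expr(expr).to_numpy()
    x = x - x.mean(axis=1, keepdims=True)
    if scale:
        sd = x.std(axis=1, keepdims=True)
        x = np.divide(x, sd, out=np.zeros_like(x), where=sd > 0)
    if np.allclose(x, 0):
        raise ValueError("constant expression matrix")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total_var = float((s ** 2).sum())
    k = min(n_components, len(s))
    coords = (vt[:k].T * s[:k])  # samples x k
    for j in range(k):
        if coords[np.argmax(np.abs(coords[:, j])), j] < 0:
            coords[:, j] = -coords[:, j]
    pct = 100.0 * (s[:k] ** 2) / total_var
    cdf = pd.DataFrame(coords, index=expr.sample_ids, columns=[f"PC{i+1}" for i in range(k)])
    return cdf, pct


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    Falls back to total-count ratios when no gene is nonzero in every sample.
    """
    mat = counts.counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if all_nonzero.any():
        ref = mat[all_nonzero]
        log_geomean = np.log(ref).mean(axis=1, keepdims=True)
        ratios = np.exp(np.log(ref) - log_geomean)
        factors = np.median(ratios, axis=0)
    else:
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("empty sample column; cannot derive size factors")
        factors = totals
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.counts.columns)


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison; log2FC is numerator over denominator."""

    name: str
    numerator: tuple[str, ...]  # sample ids
    denominator: tuple[str, ...]


@dataclass
class DEResult:
    contrast: str
    table: pd.DataFrame  # baseMeanA baseMeanB log2FC z p padj testable

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)


def nb_wald_test(
    counts: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    contrast_name: str | None = None,
) -> DEResult:
    """Per-gene negative-binomial Wald test of group A vs group B.

    Counts are normalized by median-of-ratios size factors; the log2 fold
    change is ``log2((muA + pc)/(muB + pc))`` with pseudocount ``pc = 0.5``
    (0.5 divided by the geometric-mean size factor, which is 1 after
    normalization).  Dispersion is estimated per gene by method of moments on
    normalized counts pooled within groups, clipped to [1e-8, 10] and floored
    at the genome-wide median (small-n calibration); the standard error of
    the log fold change comes from the delta method under NB variance
    mu + alpha*mu^2.  P-values are two-sided normal; multiplicity
    adjustment is applied by the caller (genome-wide BH in :func:`call_degs`,
    Holm for targeted gene lists).
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    sub = counts.counts[group_a + group_b]
    sf = size_factors(
        CountMatrix(counts=sub, totals=counts.totals[group_a + group_b])
    )
    q = sub.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    na, nb = len(group_a), len(group_b)
    qa, qb = q[:, :na], q[:, na:]
    mu_a, mu_b = qa.mean(axis=1), qb.mean(axis=1)

    pc = 0.5
    log2fc = np.log2((mu_a + pc) / (mu_b + pc))

    # MoM dispersion from within-group residual variance
    resid_ss = ((qa - mu_a[:, None]) ** 2).sum(axis=1) + ((qb - mu_b[:, None]) ** 2).sum(axis=1)
    pooled_var = resid_ss / (na + nb - 2)
    pooled_mean = (na * mu_a + nb * mu_b) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - pooled_mean) / pooled_mean ** 2
    alpha = np.clip(np.nan_to_num(alpha, nan=_ALPHA_FLOOR), _ALPHA_FLOOR, _ALPHA_CEIL)
    # per-gene MoM dispersions are noisy at small n and underestimates inflate
    # the Wald statistic; floor them at the genome-wide median
    expressed = pooled_mean > 0
    if expressed.any():
        alpha = np.maximum(alpha, np.median(alpha[expressed]))

    inv_sf_a = (1.0 / sf.to_numpy()[:na]).sum()
    inv_sf_b = (1.0 / sf.to_numpy()[na:]).sum()
    var_mu_a = (mu_a * inv_sf_a / na ** 2) + alpha * mu_a ** 2 / na
    var_mu_b = (mu_b * inv_sf_b / nb ** 2) + alpha * mu_b ** 2 / nb
    ln2 = np.log(2.0)
    se = np.sqrt(var_mu_a / (mu_a + pc) ** 2 + var_mu_b / (mu_b + pc) ** 2) / ln2

    testable = (sub.to_numpy().sum(axis=1) > 0) & (se > 0)
    z = np.zeros(len(log2fc))
    p = np.ones(len(log2fc))
    z[testable] = log2fc[testable] / se[testable]
    p[testable] = 2.0 * stats.norm.sf(np.abs(z[testable]))
    log2fc[~testable] = 0.0

    table = pd.DataFrame(
        {
            "baseMeanA": mu_a,
            "baseMeanB": mu_b,
            "log2FC": log2fc,
            "z": z,
            "p": p,
            "testable": testable,
        },
        index=sub.index,
    )
    return DEResult(contrast=contrast_name or "A vs B", table=table)


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(p, method="fdr_bh")[1]


def adjust_holm(p: np.ndarray) -> np.ndarray:
    """Bonferroni-Holm adjusted p-values (targeted gene lists)."""
    return multipletests(p, method="holm")[1]


def call_degs(
    de: DEResult,
    expr: ExpressionMatrix,
    config: RunConfig,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Apply the joint DEG rule and annotate directions.

    DEG iff max(group-mean FPKM) > deg_fpkm_min AND BH-adjusted p <
    deg_fdr_max AND |log2FC| > deg_abs_lfc_min.  Direction '+' means higher
    in the numerator group (group A).
    """
    if list(de.table.index) != list(expr.gene_ids):
        raise MetadataMismatchError("DE table and expression matrix gene sets differ")
    out = de.table.copy()
    out["padj"] = np.ones(len(out))
    mask = out["testable"].to_numpy()
    out.loc[mask, "padj"] = adjust_bh(out.loc[mask, "p"].to_numpy())
    mean_a = expr.fpkm[list(group_a)].mean(axis=1)
    mean_b = expr.fpkm[list(group_b)].mean(axis=1)
    out["maxFPKM"] = np.maximum(mean_a, mean_b)
    out["deg"] = (
        (out["maxFPKM"] > config.deg_fpkm_min)
        & (out["padj"] < config.deg_fdr_max)
        & (out["log2FC"].abs() > config.deg_abs_lfc_min)
        & out["testable"]
    )
    out["direction"] = np.where(out["log2FC"] > 0, "+", "-")
    return out


def pairwise_contrast_table(meta: SampleSheet) -> list[Contrast]:
    """All within-variety stage pairs plus the four parallel-stage contrasts.

    Parallel contrasts are named ``DSi vs ASi`` with AMT as numerator so a
    positive log2FC means up-regulation in AMT; within-variety contrasts put
    the later stage in the numerator.
    """
    cond = meta.conditions()
    varieties = sorted({s.variety for s in meta})
    contrasts: list[Contrast] = []
    for v in varieties:
        stages = [st for st in STAGES if (v, st) in cond]
        prefix = v[0]
        for s1, s2 in itertools.combinations(stages, 2):
            contrasts.append(
                Contrast(
                    name=f"{prefix}{s1} vs {prefix}{s2}",
                    numerator=tuple(cond[(v, s2)]),
                    denominator=tuple(cond[(v, s1)]),
                )
            )
    if set(varieties) == {"AMT", "DSHS"}:
        for st in STAGES:
            if ("AMT", st) in cond and ("DSHS", st) in cond:
                contrasts.append(
                    Contrast(
                        name=f"D{st} vs A{st}",
                        numerator=tuple(cond[("AMT", st)]),
                        denominator=tuple(cond[("DSHS", st)]),
                    )
                )
    return contrasts


def parallel_contrast_names() -> list[str]:
    return [f"D{st} vs A{st}" for st in STAGES]


def tca_deg_matrix(
    deg_tables: Mapping[str, pd.DataFrame], pathway_map: Mapping[str, str], label: str = "TCA"
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene up/down matrix over parallel contrasts for one pathway label.

    ``deg_tables`` maps parallel-contrast name -> the output of
    :func:`call_degs`.  Rows are pathway genes that are DEGs in >= 1 parallel
    contrast; entries are '+', '-' or ''.  Summary counts follow the printed
    conventions: total rows, rows with >= 1 '+', rows with >= 1 '-', rows
    all-'+'.
    """
    genes = sorted(g for g, lab in pathway_map.items() if lab == label)
    contrast_names = [c for c in parallel_contrast_names() if c in deg_tables]
    rows = {}
    for g in genes:
        entries = {}
        for cname in contrast_names:
            t = deg_tables[cname]
            if g in t.index and bool(t.loc[g, "deg"]):
                entries[cname] = t.loc[g, "direction"]
            else:
                entries[cname] = ""
        if any(entries.values()):
            rows[g] = entries
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=contrast_names).fillna("")
    counts = summarize_updown_matrix(matrix)
    return matrix, counts


def summarize_updown_matrix(matrix: pd.DataFrame) -> dict[str, int]:
    """Counts over a per-gene +/- matrix (any column set)."""
    if matrix.empty:
        return {"total": 0, "any_up": 0, "any_down": 0, "all_up": 0}
    vals = matrix.to_numpy()
    any_up = int(((vals == "+").any(axis=1)).sum())
    any_down = int(((vals == "-").any(axis=1)).sum())
    all_up = int(((vals == "+").all(axis=1)).sum())
    return {"total": len(matrix), "any_up": any_up, "any_down": any_down, "all_up": all_up}


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # term genes in the set
    n: int  # set size
    K: int  # term genes in the background
    N: int  # background size
    p: float
    padj: float
    rich_factor: float


def hypergeom_enrichment(
    gene_set: Sequence[str],
    annotation: Mapping[str, Sequence[str]],
    background: Sequence[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each term in ``gene_set``.

    ``annotation`` maps term -> genes (restricted to the background); p is
    the upper tail P(X >= k); BH correction across terms; rich factor k/K.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    gs = set(gene_set) & bg
    if not set(gene_set) <= bg:
        raise ValueError("gene set must be contained in the background")
    N, n = len(bg), len(gs)
    rows = []
    for term, genes in annotation.items():
        term_genes = set(genes) & bg
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & gs)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, min(p, 1.0)))
    if not rows:
        return []
    padj = adjust_bh(np.array([r[3] for r in rows]))
    return [
        EnrichmentResult(term=t, k=k, n=n, K=K, N=N, p=p, padj=float(a), rich_factor=k / K)
        for (t, k, K, p), a in zip(rows, padj)
    ]


def load_tca_deg_table() -> pd.DataFrame:
    """Packaged per-gene up/down matrix for the TCA pathway (parallel contrasts)."""
    with resources.files("acidpipe.data").joinpath("table2.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0, keep_default_na=False, dtype=str)
    return df
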