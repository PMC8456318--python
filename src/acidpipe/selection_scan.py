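"""Population-genetic layer.

GATK-style hard filtering of annotated SNPs, Weir-Cockerham two-population
F_ST variance components with ratio-of-sums windowing, a composite-likelihood
(XP-CLR-style) window score for frequency differentiation toward fixation,
LD-decay curves, percentile sweep-region calling, and gene-region overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import GeneModel, PopulationMap, VariantTable, merge_intervals

__all__ = [
    "VariantTable",
    "GenomeScan",
    "SweepRegionSet",
    "HARD_FILTER_RULES",
    "hard_filter",
    "wc_fst_per_snp",
    "windowed_fst_scan",
    "xpclr_window_score",
    "ld_decay",
    "half_decay_distance",
    "call_sweeps",
    "genes_in_regions",
]

# (field, comparator, threshold): a SNP is dropped when the comparison holds.
# All inequalities are strict, so boundary values pass.
HARD_FILTER_RULES = (
    ("MQRankSum", "lt", -12.5),
    ("QUAL", "lt", 30.0),
    ("QD", "lt", 2.0),
    ("FS", "gt", 60.0),
    ("MQ", "lt", 40.0),
    ("ReadPosRankSum", "lt", -8.0),
)


@dataclass
class GenomeScan:
    statistic: str  # FST or XPCLR
    windows: pd.DataFrame  # chrom, start, end (1-based incl.), n_snps, value, defined


@dataclass
class SweepRegionSet:
    statistic: str
    threshold: float
    top_fraction: float
    regions: pd.DataFrame  # chrom, start, end (1-based incl.), n_windows

    def __post_init__(self) -> None:
        for _, grp in self.regions.groupby("chrom"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            order = np.argsort(starts)
            if np.any(starts[order][1:] <= ends[order][:-1]):
                raise ValueError("sweep regions overlap after merging")


def hard_filter(variants: VariantTable) -> tuple[VariantTable, dict[str, int]]:
    """Drop SNPs failing any hard-filter rule; report per-criterion fail counts.

    Missing annotations pass the corresponding criterion.
    """
    n = variants.n_sites
    drop = np.zeros(n, dtype=bool)
    counts: dict[str, int] = {}
    for field, op, thr in HARD_FILTER_RULES:
        vals = variants.qual if field == "QUAL" else variants.info[field].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            fail = (vals < thr) if op == "lt" else (vals > thr)
        fail &= np.isfinite(vals)
        counts[field] = int(fail.sum())
        drop |= fail
    counts["total_dropped"] = int(drop.sum())
    return variants.subset_sites(~drop), counts


def _pop_indices(variants: VariantTable, popmap: PopulationMap, pop: str) -> list[int]:
    inds = [i for i in popmap.individuals(pop) if i in variants.individuals]
    if len(inds) < 2:
        raise ValueError(f"population {pop!r} has <2 genotyped individuals")
    return [variants.individuals.index(i) for i in inds]


def wc_fst_per_snp(
    variants: VariantTable, popmap: PopulationMap, pop_a: str, pop_b: str
) -> pd.DataFrame:
    """Weir-Cockerham (1984) two-population variance components per SNP.

    Returns a frame with columns chrom, pos, a, b, c, theta, defined.  Missing
    genotypes are excluded per site; sites with fewer than two genotyped
    diploids in either population, or with a + b + c = 0 (monomorphic), are
    flagged undefined.
    """
    idx_a = _pop_indices(variants, popmap, pop_a)
    idx_b = _pop_indices(variants, popmap, pop_b)
    comp = np.full((variants.n_sites, 3), np.nan)
    defined = np.zeros(variants.n_sites, dtype=bool)
    g = variants.genotypes.astype(float)
    g[g < 0] = np.nan
    ga, gb = g[:, idx_a], g[:, idx_b]
    r = 2.0
    for s in range(variants.n_sites):
        n1 = np.count_nonzero(~np.isnan(ga[s]))
        n2 = np.count_nonzero(~np.isnan(gb[s]))
        if n1 < 2 or n2 < 2:
            continue
        p1 = np.nansum(ga[s]) / (2 * n1)
        p2 = np.nansum(gb[s]) / (2 * n2)
        h1 = np.count_nonzero(ga[s] == 1) / n1
        h2 = np.count_nonzero(gb[s] == 1) / n2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        comp[s] = (a, b, c)
        defined[s] = (a + b + c) != 0
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = comp[:, 0] / comp.sum(axis=1)
    return pd.DataFrame(
        {
            "chrom": variants.chrom,
            "pos": variants.pos,
            "a": comp[:, 0],
            "b": comp[:, 1],
            "c": comp[:, 2],
            "theta": theta,
            "defined": defined,
        }
    )


def _window_starts(length: int, window_bp: int, step_bp: int) -> np.ndarray:
    return np.arange(1, length + 1, step_bp, dtype=np.int64)


def windowed_fst_scan(
    per_snp: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    window_bp: int = 10_000,
    step_bp: int = 1_000,
    min_snps_per_window: int = 3,
) -> GenomeScan:
    """Sliding-window F_ST as the ratio of sums of the variance components.

    Windows start at 1, 1+step, ... while start <= chrom length; the last
    windows are truncated at the chromosome end.  Windows with fewer than
    ``min_snps_per_window`` defined SNPs (or zero denominator) are undefined.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        sub = per_snp[(per_snp["chrom"] == chrom) & per_snp["defined"]]
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos)
        pos = pos[order]
        a = sub["a"].to_numpy()[order]
        abc = (sub["a"] + sub["b"] + sub["c"]).to_numpy()[order]
        cum_a = np.concatenate([[0.0], np.cumsum(a)])
        cum_abc = np.concatenate([[0.0], np.cumsum(abc)])
        for start in _window_starts(length, window_bp, step_bp):
            end = min(start + window_bp - 1, length)
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            n = hi - lo
            denom = cum_abc[hi] - cum_abc[lo]
            ok = n >= min_snps_per_window and denom != 0
            value = (cum_a[hi] - cum_a[lo]) / denom if ok else np.nan
            rows.append((chrom, int(start), int(end), int(n), value, bool(ok)))
    return GenomeScan(
        statistic="FST",
        windows=pd.DataFrame(
            rows, columns=["chrom", "start", "end", "n_snps", "value", "defined"]
        ),
    )


DEFAULT_C_GRID = np.arange(0.0, 1.0, 0.05)


def estimate_drift_scale(p_ref: np.ndarray, p_obj: np.ndarray) -> float:
    """Genome-wide drift variance scale: median of (p_obj-p_ref)^2 / (p_ref(1-p_ref)).

    Sites with reference frequency 0 or 1 are excluded.
    """
    ok = np.isfinite(p_ref) & np.isfinite(p_obj) & (p_ref > 0) & (p_ref < 1)
    if not ok.any():
        raise ValueError("no informative sites to estimate drift scale")
    ratio = (p_obj[ok] - p_ref[ok]) ** 2 / (p_ref[ok] * (1 - p_ref[ok]))
    return float(max(np.median(ratio), 1e-6))


def xpclr_window_score(
    variants: VariantTable,
    popmap: PopulationMap,
    chrom_lengths: Mapping[str, int],
    ref_pop: str = "POP_BRET",
    obj_pop: str = "POP_SINK",
    window_bp: int = 10_000,
    step_bp: int = 1_000,
    min_snps_per_window: int = 3,
    c_grid: np.ndarray = DEFAULT_C_GRID,
    omega: float | None = None,
) -> GenomeScan:
    """Composite-likelihood window score for sweep-like differentiation.

    Under neutrality the object-population frequency of each SNP is modelled
    as normal around the reference frequency with variance
    omega * p(1-p); under the alternative the mean is pulled toward the
    locally major allele by a shared factor c: mu(c) = (1-c) p + c 1[p>=0.5].
    The window score is 2 * (max over the c grid of the summed log-likelihood
    minus the value at c = 0), floored at 0.
    """
    ref_inds = popmap.individuals(ref_pop)
    obj_inds = popmap.individuals(obj_pop)
    if len(ref_inds) < 2 or len(obj_inds) < 2:
        raise ValueError("both populations need >= 2 individuals")
    p_ref = variants.allele_freq(ref_inds)
    p_obj = variants.allele_freq(obj_inds)
    if omega is None:
        omega = estimate_drift_scale(p_ref, p_obj)

    usable = np.isfinite(p_ref) & np.isfinite(p_obj) & (p_ref > 0) & (p_ref < 1)
    sd = np.sqrt(omega * p_ref * (1 - p_ref))
    c_grid = np.asarray(c_grid, dtype=float)
    if c_grid[0] != 0.0:
        raise ValueError("c grid must start at 0")
    # loglik[s, j]: normal log density of p_obj under sweep strength c_j.
    # The density is NOT renormalized over [0,1]: the truncation mass term
    # rewards pushing mu toward the boundary even when the populations are
    # identical, which would break "identical populations -> score 0".
    target = np.where(p_ref >= 0.5, 1.0, 0.0)
    loglik = np.full((variants.n_sites, len(c_grid)), np.nan)
    u = np.where(usable)[0]
    for j, c in enumerate(c_grid):
        mu = (1 - c) * p_ref[u] + c * target[u]
        loglik[u, j] = stats.norm.logpdf(p_obj[u], mu, sd[u])

    rows = []
    for chrom, length in chrom_lengths.items():
        on_chrom = (variants.chrom == chrom) & usable
        pos = variants.pos[on_chrom]
        ll = loglik[on_chrom]
        order = np.argsort(pos)
        pos, ll = pos[order], ll[order]
        cum = np.concatenate([np.zeros((1, len(c_grid))), np.cumsum(ll, axis=0)])
        for start in _window_starts(length, window_bp, step_bp):
            end = min(start + window_bp - 1, length)
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            n = hi - lo
            if n >= min_snps_per_window:
                sums = cum[hi] - cum[lo]
                score = max(2.0 * (sums.max() - sums[0]), 0.0)
                rows.append((chrom, int(start), int(end), int(n), score, True))
            else:
                rows.append((chrom, int(start), int(end), int(n), np.nan, False))
    return GenomeScan(
        statistic="XPCLR",
        windows=pd.DataFrame(
            rows, columns=["chrom", "start", "end", "n_snps", "value", "defined"]
        ),
    )


def ld_decay(
    variants: VariantTable,
    popmap: PopulationMap,
    pop: str,
    max_dist_bp: int = 300_000,
    bin_bp: int = 1_000,
) -> pd.DataFrame:
    """Mean r^2 between SNP pairs, binned by physical distance.

    r^2 is the squared Pearson correlation of genotype dosages within the
    population; monomorphic SNPs are skipped and missing genotypes are
    mean-imputed per site.  Returns columns bin_midpoint_bp, mean_r2, n_pairs.
    """
    idx = _pop_indices(variants, popmap, pop)
    g = variants.genotypes[:, idx].astype(float)
    g[g < 0] = np.nan
    row_mean = np.nanmean(g, axis=1, keepdims=True)
    fill = np.where(np.isnan(g), row_mean, g)
    sd = fill.std(axis=1)
    poly = sd > 0
    n_ind = fill.shape[1]
    z = np.zeros_like(fill)
    z[poly] = (fill[poly] - fill[poly].mean(axis=1, keepdims=True)) / sd[poly, None]

    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom in np.unique(variants.chrom):
        mask = (variants.chrom == chrom) & poly
        pos = variants.pos[mask]
        zc = z[mask]
        order = np.argsort(pos)
        pos, zc = pos[order], zc[order]
        m = len(pos)
        for i in range(m - 1):
            hi = np.searchsorted(pos, pos[i] + max_dist_bp, side="right")
            if hi <= i + 1:
                continue
            r = zc[i + 1 : hi] @ zc[i] / n_ind
            d = pos[i + 1 : hi] - pos[i]
            bins = np.minimum((d - 1) // bin_bp, n_bins - 1)
            np.add.at(sums, bins, r ** 2)
            np.add.at(counts, bins, 1)
    mids = (np.arange(n_bins) + 0.5) * bin_bp
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out = pd.DataFrame({"bin_midpoint_bp": mids, "mean_r2": mean_r2, "n_pairs": counts})
    return out[out["n_pairs"] > 0].reset_index(drop=True)


def half_decay_distance(curve: pd.DataFrame) -> float:
    """Distance at which the excess of mean r^2 over its long-range baseline
    first drops to half its short-range value.

    The baseline is the mean over the farthest 10% of bins; without it a
    population whose r^2 sits at the sampling-noise floor would never appear
    to decay.
    """
    if curve.empty:
        return float("nan")
    n_tail = max(1, len(curve) // 10)
    tail = float(curve["mean_r2"].iloc[-n_tail:].mean())
    r0 = float(curve["mean_r2"].iloc[0])
    half = tail + (r0 - tail) / 2.0
    below = curve[curve["mean_r2"] <= half]
    if below.empty:
        return float(curve["bin_midpoint_bp"].iloc[-1])
    return float(below["bin_midpoint_bp"].iloc[0])


def call_sweeps(scan: GenomeScan, top_fraction: float) -> SweepRegionSet:
    """Select the top fraction of defined windows and merge them into regions.

    The threshold is the value of the k-th largest window with
    k = max(1, floor(top_fraction * m)) over the m defined windows
    (nearest-rank); windows with value >= threshold are selected, so ties at
    the threshold can enlarge the selection.  Overlapping or book-ended
    selected windows merge into sweep regions.
    """
    defined = scan.windows[scan.windows["defined"]]
    if defined.empty:
        raise ValueError("no defined windows")
    m = len(defined)
    k = max(1, int(np.floor(top_fraction * m)))
    threshold = float(np.sort(defined["value"].to_numpy())[m - k])
    selected = defined[defined["value"] >= threshold]
    rows = []
    for chrom, grp in selected.groupby("chrom"):
        # book-ended in 1-based inclusive coords -> half-open touch after -1
        half_open = [(s - 1, e) for s, e in zip(grp["start"], grp["end"])]
        for s, e in merge_intervals(half_open):
            n_win = int(((grp["start"] - 1 >= s) & (grp["end"] <= e)).sum())
            rows.append((chrom, s + 1, e, n_win))
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_windows"])
    return SweepRegionSet(
        statistic=scan.statistic,
        threshold=threshold,
        top_fraction=top_fraction,
        regions=regions.sort_values(["chrom", "start"]).reset_index(drop=True),
    )


def genes_in_regions(
    models: Sequence[GeneModel], regions: SweepRegionSet
) -> pd.DataFrame:
    """Genes whose span overlaps any sweep region by >= 1 bp, with provenance."""
    rows = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions.regions.itertuples():
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for m in models:
        for start, end in by_chrom.get(m.chrom, ()):
            if m.start <= end and m.end >= start:
                rows.append(
                    {
                        "gene_id": m.gene_id,
                        "chrom": m.chrom,
                        "gene_start": m.start,
                        "gene_end": m.end,
                        "region_start": start,
                        "region_end": end,
                        "statistic": regions.statistic,
                    }
                )
                break
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "chrom",
            "gene_start",
            "gene_end",
            "region_start",
            "region_end",
            "statistic",
        ],
    )
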