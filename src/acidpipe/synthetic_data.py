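"""Seeded generator for every pipeline input.

Counts follow a negative-binomial model with block-correlated module
structure and planted variety effects; acid traits are tied to one module's
latent factor; genotypes come from a Balding-Nichols + founder-mosaic model
with a planted frequency sweep in one domesticated population.  Everything
is deterministic given the seed, and the ground truth is serialized next to
the fixtures.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io_core
from .io_core import (
    CountMatrix,
    GeneModel,
    PopulationMap,
    SampleMeta,
    SampleSheet,
    VariantTable,
)

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_counts",
    "simulate_traits",
    "simulate_genotypes",
    "simulate_annotations",
    "generate_dataset",
    "write_dataset",
]

_N_REPS = 3
_GENE_LEN = 600
_EXONS_REL = ((0, 250), (350, 600))  # half-open offsets within the gene span


@dataclass
class SimulationSpec:
    n_genes: int = 2000
    module_sizes: tuple[int, ...] = (300, 200, 150, 100, 60)
    module_intra_correlation: float = 0.8
    module_scale_log2: float = 1.0
    n_de_genes: int = 40
    variety_lfc: float = 3.0
    positive_extra_lfc: float = 2.0
    positive_factor_loading: float = 1.5
    acid_module_variety_shift: float = 1.5
    tf_link_scale_log2: float = 1.25
    nb_dispersion: float = 0.1
    library_size_range: tuple[float, float] = (8e6, 12e6)
    trait_module_index: int = 1
    trait_noise_sd: float = 0.3
    n_tf: int = 60
    n_true_tf: int = 5
    n_tca_genes: int = 33
    n_transporter_genes: int = 18
    chromosome: str = "chr1"
    chromosome_length_bp: int = 2_000_000
    n_snps: int = 5000
    pop_sizes: dict = field(
        default_factory=lambda: {"POP_BRET": 30, "POP_SINK": 10, "WILD": 20}
    )
    founder_haplotypes: dict = field(
        default_factory=lambda: {"POP_BRET": 12, "POP_SINK": 12, "WILD": 40}
    )
    bn_f: dict = field(
        default_factory=lambda: {"POP_BRET": 0.03, "POP_SINK": 0.03, "WILD": 0.01}
    )
    # per-bp founder-mosaic switch rate; scalar or per-population dict (the
    # wild group recombines over shorter segments -> faster LD decay)
    switch_rate: float | dict = field(
        default_factory=lambda: {"POP_BRET": 1e-5, "POP_SINK": 1e-5, "WILD": 4e-5}
    )
    sweep_pop: str = "POP_SINK"
    sweep_reference_pop: str = "POP_BRET"
    sweep_center_bp: int = 1_000_000
    sweep_c0: float = 1.0
    sweep_decay_length_bp: int = 100_000
    info_fail_rate: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if not 0 < self.module_intra_correlation < 1:
            raise ValueError("module_intra_correlation must be in (0,1)")
        if not 0 <= self.sweep_c0 <= 1:
            raise ValueError("sweep_c0 must be in [0,1]")
        if self.n_snps < 2:
            raise ValueError("need n_snps >= 2")
        if self.trait_module_index >= len(self.module_sizes):
            raise ValueError("trait_module_index out of range")
        if len(self.module_sizes) > 6:
            raise ValueError(
                "at most 6 modules (variety x stage cells minus centering and variety contrast)"
            )

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def sweep_interval(self) -> tuple[int, int]:
        """1-based inclusive interval one decay length either side of the center."""
        lo = max(1, self.sweep_center_bp - self.sweep_decay_length_bp)
        hi = min(self.chromosome_length_bp, self.sweep_center_bp + self.sweep_decay_length_bp)
        return lo, hi


@dataclass
class GroundTruth:
    module_labels: dict  # gene_id -> module index (-1 unassigned)
    acid_module: int
    de_up: list  # gene ids up-shifted in AMT
    de_down: list
    planted_lfc: dict  # gene -> log2 variety shift (AMT relative to DSHS)
    tf_ids: list
    true_tf_ids: list
    tf_targets: dict  # tf -> target gene ids
    pathway_map: dict  # gene -> TCA / transporter
    positive_genes: list  # planted pathway genes inside the sweep interval
    sweep_interval: tuple
    library_sizes: dict  # sample -> mapped fragments
    trait_factor: dict  # sample -> acid-module latent factor
    info_fail_label: list | None = None  # per-SNP hard-filter fail labels ('' = pass)
    alt_allele_totals: list | None = None  # per-SNP summed alt dosage (bookkeeping)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        raw["sweep_interval"] = tuple(raw["sweep_interval"])
        return cls(**raw)


def _rng(spec: SimulationSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.rng_seed, stream])


def _gene_ids(spec: SimulationSpec) -> list[str]:
    return [f"G{i:05d}" for i in range(spec.n_genes)]


def _gene_pitch(spec: SimulationSpec) -> int:
    pitch = spec.chromosome_length_bp // spec.n_genes
    if pitch < _GENE_LEN + 1:
        raise ValueError("genes do not fit on the chromosome")
    return pitch


def _gene_span(spec: SimulationSpec, index: int) -> tuple[int, int]:
    """1-based inclusive span of gene ``index``."""
    start = index * _gene_pitch(spec) + 1
    return start, start + _GENE_LEN - 1


def _sample_sheet() -> SampleSheet:
    samples = []
    for variety, prefix in (("AMT", "A"), ("DSHS", "D")):
        for stage in io_core.STAGES:
            for rep in range(1, _N_REPS + 1):
                samples.append(
                    SampleMeta(
                        sample_id=f"{prefix}-{io_core.STAGE_DAFB[stage]}-{rep}",
                        variety=variety,
                        stage=stage,
                        replicate=rep,
                    )
                )
    return SampleSheet(samples)


def plan(spec: SimulationSpec) -> GroundTruth:
    """Deterministic assignment of modules, DE genes, TFs, pathway labels and
    planted sweep positives; shared by all generator operations."""
    rng = _rng(spec, 0)
    genes = _gene_ids(spec)
    pitch = _gene_pitch(spec)

    labels = np.full(spec.n_genes, -1, dtype=int)
    # modules are interleaved across the chromosome so module membership is
    # not confounded with genomic position
    order = rng.permutation(spec.n_genes)
    offset = 0
    for m, size in enumerate(spec.module_sizes):
        labels[order[offset : offset + size]] = m
        offset += size

    acid = spec.trait_module_index
    lo, hi = spec.sweep_interval
    in_sweep = [
        i for i in range(spec.n_genes) if _gene_span(spec, i)[0] <= hi and _gene_span(spec, i)[1] >= lo
    ]
    if len(in_sweep) < 2:
        raise ValueError("sweep interval contains fewer than 2 genes")
    # plant one TCA and one transporter gene near the sweep center
    center_idx = min(in_sweep, key=lambda i: abs(_gene_span(spec, i)[0] - spec.sweep_center_bp))
    second_idx = min(
        (i for i in in_sweep if i != center_idx),
        key=lambda i: abs(_gene_span(spec, i)[0] - spec.sweep_center_bp),
    )
    positives = [genes[center_idx], genes[second_idx]]
    labels[center_idx] = acid
    labels[second_idx] = acid

    module_members = {m: [genes[i] for i in np.where(labels == m)[0]] for m in range(spec.n_modules)}

    # pathway labels: planted positives plus random acid-module and background genes
    pathway: dict[str, str] = {positives[0]: "TCA", positives[1]: "transporter"}
    gene_index = {g: i for i, g in enumerate(genes)}
    acid_pool = [g for g in module_members[acid] if g not in pathway]
    other_pool = [g for g in genes if labels[gene_index[g]] != acid and g not in pathway]
    n_tca_in_acid = min(8, len(acid_pool))
    tca_rest = spec.n_tca_genes - 1 - n_tca_in_acid
    chosen_acid = list(rng.choice(acid_pool, size=n_tca_in_acid, replace=False))
    chosen_other = list(rng.choice(other_pool, size=tca_rest, replace=False))
    for g in chosen_acid + chosen_other:
        pathway[g] = "TCA"
    transporter_pool = [g for g in genes if g not in pathway]
    n_tr_in_acid = 2
    tr_acid = [g for g in module_members[acid] if g in transporter_pool][:n_tr_in_acid]
    tr_other = list(
        rng.choice(
            [g for g in transporter_pool if g not in tr_acid],
            size=spec.n_transporter_genes - 1 - len(tr_acid),
            replace=False,
        )
    )
    for g in tr_acid + tr_other:
        pathway[g] = "transporter"

    # TFs: outside the pathway; the true regulators live in the acid module,
    # each tied 1-1 to a target (positives first, then acid-module pathway genes)
    tf_pool_acid = [g for g in module_members[acid] if g not in pathway]
    true_tfs = tf_pool_acid[: spec.n_true_tf]
    tf_pool_bg = [g for g in genes if g not in pathway and g not in true_tfs]
    extra_tfs = list(rng.choice(tf_pool_bg, size=spec.n_tf - len(true_tfs), replace=False))
    tf_ids = sorted(true_tfs + extra_tfs)
    target_pool = positives + [g for g in chosen_acid + tr_acid if g not in positives]
    tf_targets = {t: [target_pool[k % len(target_pool)]] for k, t in enumerate(true_tfs)}

    # planted variety effects on the log2 scale: positives and acid-module
    # pathway genes get a moderate extra shift (they already share the acid
    # factor's AMT offset), balanced background genes get +/- variety_lfc
    planted_lfc: dict[str, float] = {}
    for g in positives + chosen_acid[: n_tca_in_acid // 2] + tr_acid[:1]:
        planted_lfc[g] = spec.positive_extra_lfc
    pool = [g for g in genes if g not in planted_lfc and g not in tf_ids and g not in pathway]
    n_extra = max(spec.n_de_genes - len(planted_lfc), 0)
    extra = list(rng.choice(pool, size=n_extra, replace=False))
    half = len(extra) // 2
    for g in extra[:half]:
        planted_lfc[g] = spec.variety_lfc
    for g in extra[half:]:
        planted_lfc[g] = -spec.variety_lfc
    de_up = {g for g, l in planted_lfc.items() if l > 0}
    de_down = sorted(g for g, l in planted_lfc.items() if l < 0)

    lib_lo, lib_hi = spec.library_size_range
    lib = np.exp(rng.uniform(np.log(lib_lo), np.log(lib_hi), size=2 * 4 * _N_REPS))
    sheet = _sample_sheet()
    library_sizes = {s.sample_id: float(np.round(lib[k])) for k, s in enumerate(sheet)}

    return GroundTruth(
        module_labels={g: int(l) for g, l in zip(genes, labels)},
        acid_module=acid,
        de_up=sorted(de_up),
        de_down=de_down,
        planted_lfc=planted_lfc,
        tf_ids=tf_ids,
        true_tf_ids=sorted(true_tfs),
        tf_targets=tf_targets,
        pathway_map=pathway,
        positive_genes=positives,
        sweep_interval=spec.sweep_interval,
        library_sizes=library_sizes,
        trait_factor={},
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    if alpha < 1e-8:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(spec: SimulationSpec) -> tuple[CountMatrix, SampleSheet, GroundTruth]:
    """NB counts for 2 varieties x 4 stages x 3 replicates.

    Per gene the latent log2 mean is baseline + a shared module factor scaled
    for intra-module correlation rho + a variety shift for designated DE
    genes; the acid-linked module's factor carries an AMT offset so the
    linked traits separate the varieties.
    """
    truth = plan(spec)
    rng = _rng(spec, 1)
    sheet = _sample_sheet()
    genes = _gene_ids(spec)
    n_samples = len(sheet)
    is_amt = np.array([s.variety == "AMT" for s in sheet], dtype=float)

    # module factors vary at the condition (variety x stage) level with a
    # small replicate jitter, so biological structure is shared across
    # replicates and within-condition variance stays low
    cells = sorted({(s.variety, s.stage) for s in sheet})
    cell_idx = np.array([cells.index((s.variety, s.stage)) for s in sheet])
    # orthogonalized condition-level factors: with only 8 cells, independent
    # Gaussian draws would correlate between modules by chance and blur the
    # block structure
    # factors are orthogonalized against each other AND the variety contrast
    # (the acid module adds its variety shift on top), after centering so
    # orthogonality means zero Pearson correlation
    amt_cells = np.array([v == "AMT" for v, _ in cells], dtype=float)[:, None]
    raw = np.hstack([amt_cells, rng.standard_normal((len(cells), spec.n_modules))])
    raw -= raw.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(raw)
    cell_factors = q[:, 1 : spec.n_modules + 1].T * np.sqrt(len(cells))
    factors = cell_factors[:, cell_idx] + 0.2 * rng.standard_normal(
        (spec.n_modules, n_samples)
    )
    factors[spec.trait_module_index] += spec.acid_module_variety_shift * is_amt
    truth.trait_factor = {
        s.sample_id: float(factors[spec.trait_module_index, k]) for k, s in enumerate(sheet)
    }

    labels = np.array([truth.module_labels[g] for g in genes])
    in_module = labels >= 0
    # module genes sit well below the heaviest background genes so the
    # coherent module swings do not dominate the library mass (which would
    # couple all genes through the compositional FPKM term)
    baseline = np.where(
        in_module,
        rng.uniform(3.0, 6.5, size=spec.n_genes),
        rng.uniform(-4.0, 9.0, size=spec.n_genes),
    )
    rho = spec.module_intra_correlation
    noise = rng.standard_normal((spec.n_genes, n_samples))
    x = baseline[:, None] + spec.module_scale_log2 * np.sqrt(1 - rho) * noise
    for m in range(spec.n_modules):
        rows = labels == m
        x[rows] += spec.module_scale_log2 * np.sqrt(rho) * factors[m][None, :]
    # background genes carry gene-specific condition-level variation instead
    # of a shared factor: total variance matches module genes, but the
    # biological part is shared across replicates (keeping within-condition
    # dispersion realistic) and uncorrelated between genes
    bg = ~in_module
    cell_noise = rng.standard_normal((int(bg.sum()), len(cells)))[:, cell_idx]
    x[bg] += spec.module_scale_log2 * np.sqrt(rho) * cell_noise

    lfc = np.zeros(spec.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, l in truth.planted_lfc.items():
        lfc[gene_pos[g]] = l
    x += lfc[:, None] * is_amt[None, :]

    # the planted sweep positives track the acid module extra tightly: higher
    # factor loading, less idiosyncratic noise
    f_acid = factors[spec.trait_module_index]
    for g in truth.positive_genes:
        i = gene_pos[g]
        x[i] = (
            baseline[i]
            + spec.module_scale_log2
            * (spec.positive_factor_loading * np.sqrt(rho) * f_acid + 0.5 * np.sqrt(1 - rho) * noise[i])
            + lfc[i] * is_amt
        )

    # TF-target links: each true TF shares a dedicated latent factor with its
    # target so the pair is reciprocally each other's strongest partner
    for tf, targets in truth.tf_targets.items():
        h = rng.standard_normal(n_samples)
        x[gene_pos[tf]] += spec.tf_link_scale_log2 * h
        for tgt in targets:
            x[gene_pos[tgt]] += spec.tf_link_scale_log2 * h

    rel = 2.0 ** x
    lib = np.array([truth.library_sizes[s.sample_id] for s in sheet])
    mean = rel / rel.sum(axis=0, keepdims=True) * lib[None, :]
    counts = _nb_draw(rng, mean, spec.nb_dispersion).astype(np.int64)
    totals = np.maximum(lib, counts.sum(axis=0))  # mapped >= counted fragments
    truth.library_sizes = {s.sample_id: float(t) for s, t in zip(sheet, totals)}
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=[s.sample_id for s in sheet]),
        totals=pd.Series(totals.astype(float), index=[s.sample_id for s in sheet]),
    )
    return cm, sheet, truth


def simulate_traits(spec: SimulationSpec, truth: GroundTruth) -> pd.DataFrame:
    """OA/MA/CA per sample (mg/g FW): MA and CA share the acid-module factor,
    OA is independent noise."""
    if not truth.trait_factor:
        raise ValueError("simulate_counts must run first (trait factor missing)")
    rng = _rng(spec, 2)
    samples = list(truth.trait_factor)
    f = np.array([truth.trait_factor[s] for s in samples])
    sd = spec.trait_noise_sd
    ma = 3.5 + 1.2 * f + rng.normal(0, sd, size=len(f))
    ca = 1.2 + 0.4 * f + rng.normal(0, sd * 0.5, size=len(f))
    oa = 0.8 + rng.normal(0, sd, size=len(f))
    df = pd.DataFrame({"OA": oa, "MA": ma, "CA": ca}, index=pd.Index(samples, name="sample_id"))
    return df.clip(lower=0.01)


def _mosaic_haplotype(
    rng: np.random.Generator,
    founders: np.ndarray,
    pos: np.ndarray,
    switch_rate: float,
) -> np.ndarray:
    n_founders, n_snps = founders.shape
    gaps = np.diff(pos)
    p_switch = 1.0 - np.exp(-switch_rate * gaps)
    switches = rng.random(n_snps - 1) < p_switch
    idx = np.empty(n_snps, dtype=np.int64)
    cur = rng.integers(n_founders)
    idx[0] = cur
    for k in np.where(switches)[0]:
        cur = rng.integers(n_founders)
        idx[k + 1 :] = cur
    # fill non-switch positions by forward propagation
    if not switches.any():
        idx[:] = idx[0]
    else:
        last = idx[0]
        for k in range(1, n_snps):
            if switches[k - 1]:
                last = idx[k]
            idx[k] = last
    return founders[idx, np.arange(n_snps)]


def simulate_genotypes(
    spec: SimulationSpec,
) -> tuple[VariantTable, PopulationMap, GroundTruth]:
    """Balding-Nichols population frequencies, founder-mosaic diploids with
    realistic LD, a planted frequency sweep in one domesticated population,
    and labelled QUAL/INFO mixtures so the hard filters are exercisable."""
    truth = plan(spec)
    rng = _rng(spec, 3)
    pos = np.sort(rng.choice(spec.chromosome_length_bp, size=spec.n_snps, replace=False)) + 1
    p0 = rng.uniform(0.05, 0.95, size=spec.n_snps)

    assignments: dict[str, str] = {}
    for pop, size in spec.pop_sizes.items():
        for k in range(size):
            assignments[f"{pop}_{k:02d}"] = pop
    popmap = PopulationMap(assignments)

    c = spec.sweep_c0 * np.exp(-np.abs(pos - spec.sweep_center_bp) / spec.sweep_decay_length_bp)

    # Balding-Nichols frequencies for every population; the sweep pulls the
    # swept population toward the allele that is locally major in the
    # *realized* reference-group sample (the orientation a cross-population
    # scan contrasts), so the reference pop is generated first
    freqs: dict[str, np.ndarray] = {}
    for pop in spec.pop_sizes:
        f_pop = spec.bn_f[pop]
        shape1 = p0 * (1 - f_pop) / f_pop
        shape2 = (1 - p0) * (1 - f_pop) / f_pop
        freqs[pop] = rng.beta(shape1, shape2)

    pop_order = sorted(
        spec.pop_sizes, key=lambda p: (p != spec.sweep_reference_pop, p == spec.sweep_pop)
    )
    haplo_by_ind: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    ref_emp: np.ndarray | None = None
    for pop in pop_order:
        if pop == spec.sweep_pop and spec.sweep_c0 > 0:
            ref = ref_emp if ref_emp is not None else p0
            target = (ref >= 0.5).astype(float)
            freqs[pop] = (1 - c) * freqs[pop] + c * target
        n_founders = spec.founder_haplotypes[pop]
        founders = (rng.random((n_founders, spec.n_snps)) < freqs[pop][None, :]).astype(np.int8)
        if isinstance(spec.switch_rate, dict):
            switch = spec.switch_rate[pop]
        else:
            switch = spec.switch_rate
        dosage_sum = np.zeros(spec.n_snps)
        for ind in popmap.individuals(pop):
            h1 = _mosaic_haplotype(rng, founders, pos, switch)
            h2 = _mosaic_haplotype(rng, founders, pos, switch)
            haplo_by_ind[ind] = (h1, h2)
            dosage_sum += h1 + h2
        if pop == spec.sweep_reference_pop:
            ref_emp = dosage_sum / (2 * spec.pop_sizes[pop])

    individuals = list(assignments)
    genotypes = np.stack(
        [haplo_by_ind[i][0] + haplo_by_ind[i][1] for i in individuals], axis=1
    ).astype(np.int8)

    # annotation mixtures with known pass/fail labels
    n = spec.n_snps
    info = pd.DataFrame(
        {
            "QD": rng.uniform(5, 30, n),
            "FS": rng.uniform(0, 30, n),
            "MQ": rng.uniform(50, 60, n),
            "MQRankSum": rng.uniform(-5, 5, n),
            "ReadPosRankSum": rng.uniform(-5, 5, n),
        }
    )
    qual = rng.uniform(100, 1000, n)
    fail_label = np.array([""] * n, dtype=object)
    fail_sites = np.where(rng.random(n) < spec.info_fail_rate)[0]
    criteria = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "QUAL")
    fail_draws = {
        "QD": lambda r: r.uniform(0.0, 1.9),
        "FS": lambda r: r.uniform(60.5, 100.0),
        "MQ": lambda r: r.uniform(10.0, 39.5),
        "MQRankSum": lambda r: r.uniform(-20.0, -13.0),
        "ReadPosRankSum": lambda r: r.uniform(-12.0, -8.5),
        "QUAL": lambda r: r.uniform(0.0, 29.5),
    }
    for s in fail_sites:
        crit = criteria[rng.integers(len(criteria))]
        val = fail_draws[crit](rng)
        if crit == "QUAL":
            qual[s] = val
        else:
            info.loc[s, crit] = val
        fail_label[s] = crit

    vt = VariantTable(
        chrom=np.array([spec.chromosome] * n, dtype=object),
        pos=pos.astype(np.int64),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["C"] * n, dtype=object),
        genotypes=genotypes,
        individuals=individuals,
        qual=qual,
        info=info,
    )
    truth.info_fail_label = list(fail_label)
    truth.alt_allele_totals = [int(t) for t in genotypes.sum(axis=1)]
    return vt, popmap, truth


def simulate_annotations(
    spec: SimulationSpec, truth: GroundTruth | None = None
) -> tuple[list[GeneModel], list[str], dict[str, str]]:
    """Non-overlapping two-exon gene models tiled on one chromosome, the TF
    list, and the pathway map; planted positives sit inside the sweep
    interval by construction."""
    if truth is None:
        truth = plan(spec)
    genes = _gene_ids(spec)
    models = []
    for i, g in enumerate(genes):
        start, end = _gene_span(spec, i)
        exons = tuple(
            (start + s, start + e - 1) for s, e in _EXONS_REL
        )
        models.append(
            GeneModel(gene_id=g, chrom=spec.chromosome, start=start, end=end, strand="+", exons=exons)
        )
    return models, list(truth.tf_ids), dict(truth.pathway_map)


@dataclass
class SyntheticDataset:
    spec: SimulationSpec
    counts: CountMatrix
    samples: SampleSheet
    traits: pd.DataFrame
    models: list[GeneModel]
    tf_ids: list[str]
    pathway_map: dict[str, str]
    variants: VariantTable
    popmap: PopulationMap
    truth: GroundTruth


def generate_dataset(spec: SimulationSpec) -> SyntheticDataset:
    counts, samples, truth = simulate_counts(spec)
    traits = simulate_traits(spec, truth)
    variants, popmap, gtruth = simulate_genotypes(spec)
    truth.info_fail_label = gtruth.info_fail_label
    truth.alt_allele_totals = gtruth.alt_allele_totals
    models, tf_ids, pathway = simulate_annotations(spec, truth)
    return SyntheticDataset(
        spec=spec,
        counts=counts,
        samples=samples,
        traits=traits,
        models=models,
        tf_ids=tf_ids,
        pathway_map=pathway,
        variants=variants,
        popmap=popmap,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | os.PathLike) -> None:
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    io_core.write_counts(ds.counts, os.path.join(outdir, "counts.tsv"))
    io_core.write_sample_sheet(ds.samples, os.path.join(outdir, "samples.csv"))
    io_core.write_traits(ds.traits, os.path.join(outdir, "traits.csv"))
    io_core.write_gff3(ds.models, os.path.join(outdir, "genes.gff3"))
    with open(os.path.join(outdir, "tfs.txt"), "w") as fh:
        fh.write("\n".join(ds.tf_ids) + "\n")
    io_core.write_pathway_map(ds.pathway_map, os.path.join(outdir, "pathway.tsv"))
    io_core.write_population_map(ds.popmap, os.path.join(outdir, "pop.map"))
    io_core.write_vcf(
        ds.variants,
        os.path.join(outdir, "variants.vcf"),
        contig_lengths={ds.spec.chromosome: ds.spec.chromosome_length_bp},
    )
    ds.truth.to_json(os.path.join(outdir, "ground_truth.json"))
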