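"""Readers/writers for the formats the pipeline touches, plus shared domain types.

Coordinate convention: all interval arithmetic inside the package is 0-based
half-open; GFF3 and VCF are 1-based inclusive and are converted at the file
boundary.  Window tables emitted by :mod:`acidpipe.selection_scan` are 1-based
inclusive.
"""

from __future__ import annotations

import dataclasses
import os
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "MetadataMismatchError",
    "VARIETIES",
    "STAGES",
    "STAGE_DAFB",
    "POPULATIONS",
    "SampleMeta",
    "SampleSheet",
    "GeneModel",
    "RunConfig",
    "PopulationMap",
    "CountMatrix",
    "VariantTable",
    "merge_intervals",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_counts",
    "write_counts",
    "read_gff3",
    "write_gff3",
    "read_vcf",
    "write_vcf",
    "read_population_map",
    "write_population_map",
    "read_traits",
    "write_traits",
    "read_gene_list",
    "read_pathway_map",
    "write_pathway_map",
]


class FormatError(ValueError):
    """A file violates its declared format."""


class MetadataMismatchError(ValueError):
    """File contents disagree with the supplied sample/population metadata."""


VARIETIES = ("AMT", "DSHS")
STAGES = ("S1", "S2", "S3", "S4")
STAGE_DAFB = {"S1": 15, "S2": 45, "S3": 90, "S4": 120}
POPULATIONS = ("POP_BRET", "POP_SINK", "WILD")


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing library: variety x developmental stage x replicate."""

    sample_id: str
    variety: str
    stage: str
    replicate: int

    def __post_init__(self) -> None:
        if self.variety not in VARIETIES:
            raise FormatError(f"unknown variety {self.variety!r}")
        if self.stage not in STAGES:
            raise FormatError(f"unknown stage {self.stage!r}")
        if self.replicate < 1:
            raise FormatError("replicate must be >= 1")

    @property
    def dafb(self) -> int:
        return STAGE_DAFB[self.stage]

    @property
    def condition(self) -> tuple[str, str]:
        return (self.variety, self.stage)


class SampleSheet:
    """Ordered collection of :class:`SampleMeta` with uniqueness checks."""

    def __init__(self, samples: Sequence[SampleMeta]):
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sample ids: {dupes}")
        self.samples = list(samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def ids_for(self, variety: str | None = None, stage: str | None = None) -> list[str]:
        out = []
        for s in self.samples:
            if variety is not None and s.variety != variety:
                continue
            if stage is not None and s.stage != stage:
                continue
            out.append(s.sample_id)
        return out

    def conditions(self) -> dict[tuple[str, str], list[str]]:
        cond: dict[tuple[str, str], list[str]] = {}
        for s in self.samples:
            cond.setdefault(s.condition, []).append(s.sample_id)
        return cond

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        keep = set(sample_ids)
        return SampleSheet([s for s in self.samples if s.sample_id in keep])


@dataclass(frozen=True)
class GeneModel:
    """Gene span plus merged exonic length; coordinates 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    exons: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError(f"{self.gene_id}: end < start")
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def exonic_length_bp(self) -> int:
        if not self.exons:
            return self.end - self.start + 1
        half_open = [(s - 1, e) for s, e in self.exons]
        return sum(e - s for s, e in merge_intervals(half_open))

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open gene span."""
        return (self.start - 1, self.end)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/book-ended 0-based half-open intervals."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if e < s:
            raise FormatError("interval end < start")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


@dataclass
class RunConfig:
    """Pipeline constants; defaults follow the study design."""

    fpkm_min_expressed: float = 5.0
    deg_fpkm_min: float = 0.1
    deg_fdr_max: float = 0.05
    deg_abs_lfc_min: float = 2.0
    soft_power: float = 14.0
    tom_type: str = "unsigned"
    min_module_size: int = 40
    merge_cut_height: float = 0.3
    mr_pcc_min: float = 0.3
    mr_rank_max: int = 5
    window_bp: int = 10_000
    step_bp: int = 1_000
    min_snps_per_window: int = 3
    fst_top_fraction: float = 0.05
    xpclr_top_fraction: float = 0.01
    qc_pcc_min: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fst_top_fraction", "xpclr_top_fraction"):
            frac = getattr(self, name)
            if not 0 < frac < 1:
                raise FormatError(f"{name} must be in (0,1)")
        if self.window_bp < self.step_bp:
            raise FormatError("window_bp must be >= step_bp")
        if self.soft_power < 1:
            raise FormatError("soft_power must be >= 1")
        if self.tom_type != "unsigned":
            raise FormatError("only unsigned TOM is supported")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


class PopulationMap:
    """individual -> population label; every analyzed population needs >= 2 members."""

    def __init__(self, assignments: Mapping[str, str]):
        self._map = dict(assignments)
        sizes: dict[str, int] = {}
        for pop in self._map.values():
            sizes[pop] = sizes.get(pop, 0) + 1
        too_small = sorted(p for p, n in sizes.items() if n < 2)
        if too_small:
            raise FormatError(f"populations with <2 individuals: {too_small}")
        self.sizes = sizes

    def __getitem__(self, individual: str) -> str:
        return self._map[individual]

    def __contains__(self, individual: str) -> bool:
        return individual in self._map

    def __len__(self) -> int:
        return len(self._map)

    def individuals(self, pop: str | None = None) -> list[str]:
        if pop is None:
            return list(self._map)
        return [i for i, p in self._map.items() if p == pop]

    @property
    def populations(self) -> list[str]:
        return sorted(self.sizes)

    def items(self):
        return self._map.items()


@dataclass
class CountMatrix:
    """Integer fragment counts (genes x samples) plus per-sample mapped totals."""

    counts: pd.DataFrame
    totals: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative counts")
        if not self.counts.columns.equals(self.totals.index):
            raise MetadataMismatchError("totals index must match count columns")
        colsums = self.counts.sum(axis=0)
        if (self.totals + 1e-9 < colsums).any():
            raise FormatError("totals smaller than column sums")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class VariantTable:
    """Biallelic SNPs with diploid genotype codes (0/1/2; -1 = missing)."""

    chrom: np.ndarray
    pos: np.ndarray  # 1-based positions
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray  # (n_snps, n_individuals) int8
    individuals: list[str]
    qual: np.ndarray
    info: pd.DataFrame  # columns QD, FS, MQ, MQRankSum, ReadPosRankSum (NaN = absent)
    n_dropped_non_biallelic: int = 0

    def __post_init__(self) -> None:
        n = len(self.pos)
        if not (len(self.chrom) == len(self.ref) == len(self.alt) == n):
            raise FormatError("ragged variant table")
        if self.genotypes.shape != (n, len(self.individuals)):
            raise FormatError("genotype matrix shape mismatch")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise FormatError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def subset_sites(self, mask: np.ndarray) -> "VariantTable":
        return VariantTable(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            genotypes=self.genotypes[mask],
            individuals=list(self.individuals),
            qual=self.qual[mask],
            info=self.info.loc[mask].reset_index(drop=True),
            n_dropped_non_biallelic=self.n_dropped_non_biallelic,
        )

    def allele_freq(self, individuals: Sequence[str]) -> np.ndarray:
        """Alt-allele frequency per site over the given individuals.

        Missing genotypes are excluded from the denominator; monomorphic-missing
        sites yield NaN.
        """
        idx = [self.individuals.index(i) for i in individuals]
        g = self.genotypes[:, idx].astype(float)
        g[g < 0] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(g, axis=1) / 2.0


# ---------------------------------------------------------------------------
# sample sheet


def read_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    df = pd.read_csv(path, dtype={"sample_id": str, "variety": str, "stage": str})
    required = {"sample_id", "variety", "stage", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    return SampleSheet(
        [
            SampleMeta(r.sample_id, r.variety, r.stage, int(r.replicate))
            for r in df.itertuples()
        ]
    )


def write_sample_sheet(sheet: SampleSheet, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in sheet],
            "variety": [s.variety for s in sheet],
            "stage": [s.stage for s in sheet],
            "replicate": [s.replicate for s in sheet],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# counts

_TOTALS_PREFIX = "#total_fragments"


def read_counts(path: str | os.PathLike, samples: SampleSheet) -> CountMatrix:
    """Read a genes x samples TSV of integer fragment counts.

    An optional ``#total_fragments`` comment line carries per-sample mapped
    totals; otherwise totals default to the column sums.
    """
    totals_line = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith(_TOTALS_PREFIX):
            totals_line = first.rstrip("\n").split("\t")[1:]
            header_pos = fh.tell()
        else:
            header_pos = 0
        fh.seek(header_pos)
        df = pd.read_csv(fh, sep="\t", index_col=0)

    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise FormatError(f"duplicate gene ids: {dupes}")
    unknown = set(df.columns) - set(samples.sample_ids)
    if unknown:
        raise MetadataMismatchError(f"count columns not in sample sheet: {sorted(unknown)}")
    absent = set(samples.sample_ids) - set(df.columns)
    if absent:
        raise MetadataMismatchError(f"samples missing from counts: {sorted(absent)}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.all(np.isfinite(values)) or np.any(values != np.round(values)):
            raise FormatError("non-integer count cells")
        df = df.astype(np.int64)
    df = df[samples.sample_ids]
    df.index.name = None
    if totals_line is not None:
        if len(totals_line) != df.shape[1]:
            raise FormatError("totals line width does not match sample columns")
        totals = pd.Series([float(x) for x in totals_line], index=df.columns)
        totals = totals[samples.sample_ids]
    else:
        totals = df.sum(axis=0).astype(float)
    return CountMatrix(counts=df, totals=totals)


def write_counts(cm: CountMatrix, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(_TOTALS_PREFIX + "\t" + "\t".join(f"{t:.0f}" for t in cm.totals) + "\n")
        cm.counts.to_csv(fh, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene/exon features; exonic length = union of exon intervals."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if gene.end < gene.start:
            raise FormatError(f"{gene.id}: end < start")
        exons = tuple(
            (e.start, e.end)
            for e in db.children(gene, featuretype="exon", order_by="start")
        )
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand if gene.strand in "+-" else ".",
                exons=exons or None,
            )
        )
    ids = [m.gene_id for m in models]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate gene ids in GFF3")
    return models


def write_gff3(models: Sequence[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{m.chrom}\t.\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons or (), start=1):
                fh.write(
                    f"{m.chrom}\t.\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.gene_id}.exon{i};Parent={m.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# VCF

_INFO_FIELDS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

_GT_CODE = {0: 0, 1: 1, 3: 2, 2: -1}  # cyvcf2 gt_types -> dosage code


def read_vcf(path: str | os.PathLike, popmap: PopulationMap) -> VariantTable:
    """Load biallelic SNPs; non-biallelic/non-SNP records are dropped and counted."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    missing = [i for i in individuals if i not in popmap]
    if missing:
        raise MetadataMismatchError(f"VCF individuals absent from population map: {missing}")

    chrom, pos, ref, alt, qual, gts = [], [], [], [], [], []
    info_rows = []
    dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            dropped += 1
            continue
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        qual.append(v.QUAL if v.QUAL is not None else np.nan)
        gts.append([_GT_CODE[t] for t in v.gt_types])
        row = {}
        for k in _INFO_FIELDS:
            val = v.INFO.get(k)
            row[k] = float(val) if val is not None else np.nan
        info_rows.append(row)
    if not pos:
        raise FormatError("empty VCF (no biallelic SNPs)")
    return VariantTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        genotypes=np.array(gts, dtype=np.int8),
        individuals=individuals,
        qual=np.array(qual, dtype=float),
        info=pd.DataFrame(info_rows, columns=list(_INFO_FIELDS)),
        n_dropped_non_biallelic=dropped,
    )


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(vt: VariantTable, path: str | os.PathLike, contig_lengths: Mapping[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        for k in _INFO_FIELDS:
            fh.write(f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(vt.individuals)
            + "\n"
        )
        for i in range(vt.n_sites):
            info = ";".join(
                f"{k}={vt.info[k].iloc[i]:.4g}"
                for k in _INFO_FIELDS
                if np.isfinite(vt.info[k].iloc[i])
            )
            qual = f"{vt.qual[i]:.4g}" if np.isfinite(vt.qual[i]) else "."
            gts = "\t".join(_GT_STRING[int(g)] for g in vt.genotypes[i])
            fh.write(
                f"{vt.chrom[i]}\t{vt.pos[i]}\t.\t{vt.ref[i]}\t{vt.alt[i]}\t{qual}\t.\t"
                f"{info or '.'}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# small tables


def read_population_map(path: str | os.PathLike) -> PopulationMap:
    df = pd.read_csv(path, sep="\t", header=None, names=["individual", "population"])
    if df["individual"].duplicated().any():
        raise FormatError("duplicate individuals in population map")
    return PopulationMap(dict(zip(df["individual"], df["population"])))


def write_population_map(popmap: PopulationMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for ind, pop in popmap.items():
            fh.write(f"{ind}\t{pop}\n")


def read_traits(path: str | os.PathLike) -> pd.DataFrame:
    """Trait table: rows = samples (index sample_id), columns = acids (mg/g FW)."""
    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates:
        raise FormatError("duplicate sample ids in trait table")
    return df


def write_traits(traits: pd.DataFrame, path: str | os.PathLike) -> None:
    traits.to_csv(path, index_label="sample_id")


def read_gene_list(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_pathway_map(path: str | os.PathLike) -> dict[str, str]:
    """TSV gene_id<TAB>label (e.g. TCA / transporter / TF family)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "label"])
    if df["gene_id"].duplicated().any():
        raise FormatError("duplicate gene ids in pathway map")
    return dict(zip(df["gene_id"], df["label"]))


def write_pathway_map(mapping: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g, label in mapping.items():
            fh.write(f"{g}\t{label}\n")
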