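"""Final inference layer.

Candidate genes are the conjunction pathway-label AND parallel-stage DEG AND
key-module membership; domestication calls are candidates or TRN TFs whose
span overlaps both the F_ST and the XP-CLR sweep-region sets; an S3-only
Wald test with Holm correction validates the calls; the report bundles every
stage artifact with provenance checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import coexpression_modules as cx
from . import expression_profiles as ep
from . import mutual_rank_network as mrn
from . import selection_scan as ss
from .io_core import CountMatrix, GeneModel, RunConfig, SampleSheet
from .synthetic_data import SyntheticDataset

__all__ = [
    "CandidateGene",
    "DomesticationCall",
    "PipelineResult",
    "select_candidates",
    "nominate_domestication_genes",
    "s3_validation",
    "build_report",
    "run_full_pipeline",
]

REPORT_SCHEMA_VERSION = 1

PATHWAY_LABELS = ("TCA", "transporter")


@dataclass(frozen=True)
class CandidateGene:
    gene_id: str
    pathway_label: str
    deg_evidence: tuple[tuple[str, str], ...]  # (contrast, direction)
    module: int
    gene_significance: float | None = None
    module_membership: float | None = None


@dataclass(frozen=True)
class DomesticationCall:
    gene_id: str
    role: str  # candidate | TRN-TF
    fst_region: tuple[int, int]
    xpclr_region: tuple[int, int]


def select_candidates(
    pathway_map: Mapping[str, str],
    deg_tables: Mapping[str, pd.DataFrame],
    key_modules: Mapping[str, int],
    mods: cx.ModuleSet,
    mtc: cx.ModuleTraitCor | None = None,
) -> list[CandidateGene]:
    """Genes satisfying all three predicates, with the evidence recorded."""
    if not key_modules:
        raise ValueError("no key modules supplied")
    key_set = set(key_modules.values())
    module_trait = {m: t for t, m in key_modules.items()}
    parallel = [c for c in ep.parallel_contrast_names() if c in deg_tables]
    out = []
    for gene, label in sorted(pathway_map.items()):
        if label not in PATHWAY_LABELS:
            continue
        evidence = tuple(
            (c, str(deg_tables[c].loc[gene, "direction"]))
            for c in parallel
            if gene in deg_tables[c].index and bool(deg_tables[c].loc[gene, "deg"])
        )
        if not evidence:
            continue
        if gene not in mods.labels.index:
            continue
        module = int(mods.labels[gene])
        if module not in key_set:
            continue
        gs = mm = None
        if mtc is not None and gene in mtc.module_membership.index:
            trait = module_trait[module]
            gs = float(mtc.gene_significance.loc[gene, trait])
            mm = float(mtc.module_membership.loc[gene, module])
        out.append(
            CandidateGene(
                gene_id=gene,
                pathway_label=label,
                deg_evidence=evidence,
                module=module,
                gene_significance=gs,
                module_membership=mm,
            )
        )
    return out


def _overlapping_region(
    model: GeneModel, regions: ss.SweepRegionSet
) -> tuple[int, int] | None:
    for r in regions.regions.itertuples():
        if r.chrom == model.chrom and model.start <= r.end and model.end >= r.start:
            return (int(r.start), int(r.end))
    return None


def nominate_domestication_genes(
    candidates: Sequence[CandidateGene],
    trns: Sequence[mrn.MRNetwork],
    fst_regions: ss.SweepRegionSet,
    xpclr_regions: ss.SweepRegionSet,
    models: Sequence[GeneModel],
) -> list[DomesticationCall]:
    """Dual-sweep intersection over candidates plus the TRN TF nodes."""
    model_by_id = {m.gene_id: m for m in models}
    universe: dict[str, str] = {c.gene_id: "candidate" for c in candidates}
    for net in trns:
        for tf in net.tf_nodes:
            universe.setdefault(tf, "TRN-TF")
    if not universe:
        raise ValueError("empty nomination universe")
    calls = []
    for gene in sorted(universe):
        model = model_by_id.get(gene)
        if model is None:
            continue
        fst_hit = _overlapping_region(model, fst_regions)
        xp_hit = _overlapping_region(model, xpclr_regions)
        if fst_hit is not None and xp_hit is not None:
            calls.append(
                DomesticationCall(
                    gene_id=gene,
                    role=universe[gene],
                    fst_region=fst_hit,
                    xpclr_region=xp_hit,
                )
            )
    return calls


def s3_validation(
    counts: CountMatrix, meta: SampleSheet, genes: Sequence[str]
) -> tuple[pd.DataFrame, list[str]]:
    """AMT-vs-DSHS Wald test on S3 samples only, Holm-adjusted over ``genes``.

    Returns the per-gene table (log2FC, z, p, padj, direction) and the list
    of genes absent from the count matrix.
    """
    amt = meta.ids_for(variety="AMT", stage="S3")
    dshs = meta.ids_for(variety="DSHS", stage="S3")
    if len(amt) < 2 or len(dshs) < 2:
        raise ValueError("need >= 2 S3 replicates per variety")
    de = ep.nb_wald_test(counts, amt, dshs, contrast_name="DS3 vs AS3 (validation)")
    present = [g for g in genes if g in de.table.index]
    untested = [g for g in genes if g not in de.table.index]
    table = de.table.loc[present, ["log2FC", "z", "p"]].copy()
    if present:
        table["padj"] = ep.adjust_holm(table["p"].to_numpy())
        table["direction"] = np.where(table["log2FC"] > 0, "+", "-")
    else:
        table["padj"] = []
        table["direction"] = []
    return table, untested


@dataclass
class PipelineResult:
    config: RunConfig
    qc_flagged: list[str]
    deg_tables: dict[str, pd.DataFrame]
    tca_matrix: pd.DataFrame
    tca_counts: dict[str, int]
    modules: cx.ModuleSet
    module_trait: cx.ModuleTraitCor
    key_modules: dict[str, int]
    trns: list[mrn.MRNetwork]
    fst_scan: ss.GenomeScan
    xpclr_scan: ss.GenomeScan
    fst_regions: ss.SweepRegionSet
    xpclr_regions: ss.SweepRegionSet
    candidates: list[CandidateGene]
    nominations: list[DomesticationCall]
    validation: pd.DataFrame
    hard_filter_counts: dict[str, int]


def run_full_pipeline(ds: SyntheticDataset, config: RunConfig) -> PipelineResult:
    """Execute quantify -> QC -> DE -> modules -> TRN -> scan -> integrate."""
    expr = ep.compute_fpkm(ds.counts, ds.models)

    flagged = ep.replicate_qc(expr, ds.samples, config.qc_pcc_min)
    retained_ids = [s for s in expr.sample_ids if s not in flagged]
    retained_meta = ds.samples.subset(retained_ids)

    contrasts = ep.pairwise_contrast_table(ds.samples)
    deg_tables: dict[str, pd.DataFrame] = {}
    for c in contrasts:
        de = ep.nb_wald_test(ds.counts, list(c.numerator), list(c.denominator), c.name)
        deg_tables[c.name] = ep.call_degs(de, expr, config, c.numerator, c.denominator)
    tca_matrix, tca_counts = ep.tca_deg_matrix(deg_tables, ds.pathway_map, label="TCA")

    expr_qc = expr.subset_samples(retained_ids)
    mods, mtc, key = cx.run_wgcna(expr_qc, ds.traits.loc[retained_ids], config)

    candidates = select_candidates(ds.pathway_map, deg_tables, key, mods, mtc)

    trns = []
    candidate_ids = [c.gene_id for c in candidates] or list(ds.truth.positive_genes)
    for variety in ("AMT", "DSHS"):
        v_ids = [s for s in retained_meta.ids_for(variety=variety)]
        v_expr = cx.filter_expressed(expr.subset_samples(v_ids), config.fpkm_min_expressed)
        pcc = mrn.pcc_matrix(v_expr)
        ranks, _ = mrn.mutual_rank(pcc)
        trns.append(
            mrn.build_trn(
                pcc,
                ranks,
                ds.tf_ids,
                candidate_ids,
                variety=variety,
                mr_pcc_min=config.mr_pcc_min,
                mr_rank_max=config.mr_rank_max,
            )
        )

    chrom_lengths = {ds.spec.chromosome: ds.spec.chromosome_length_bp}
    passing, filter_counts = ss.hard_filter(ds.variants)
    per_snp = ss.wc_fst_per_snp(passing, ds.popmap, "POP_BRET", "POP_SINK")
    fst_scan = ss.windowed_fst_scan(
        per_snp, chrom_lengths, config.window_bp, config.step_bp, config.min_snps_per_window
    )
    xpclr_scan = ss.xpclr_window_score(
        passing,
        ds.popmap,
        chrom_lengths,
        window_bp=config.window_bp,
        step_bp=config.step_bp,
        min_snps_per_window=config.min_snps_per_window,
    )
    fst_regions = ss.call_sweeps(fst_scan, config.fst_top_fraction)
    xpclr_regions = ss.call_sweeps(xpclr_scan, config.xpclr_top_fraction)

    nominations = nominate_domestication_genes(
        candidates, trns, fst_regions, xpclr_regions, ds.models
    )
    validation, _ = s3_validation(ds.counts, ds.samples, [n.gene_id for n in nominations])

    return PipelineResult(
        config=config,
        qc_flagged=flagged,
        deg_tables=deg_tables,
        tca_matrix=tca_matrix,
        tca_counts=tca_counts,
        modules=mods,
        module_trait=mtc,
        key_modules=key,
        trns=trns,
        fst_scan=fst_scan,
        xpclr_scan=xpclr_scan,
        fst_regions=fst_regions,
        xpclr_regions=xpclr_regions,
        candidates=candidates,
        nominations=nominations,
        validation=validation,
        hard_filter_counts=filter_counts,
    )


def _checksum(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:16]


def build_report(result: PipelineResult, ds: SyntheticDataset | None = None) -> dict:
    """Schema-versioned JSON-serializable report over all stage artifacts."""
    deg_counts = {
        name: {
            "n_deg": int(t["deg"].sum()),
            "n_up": int((t["deg"] & (t["direction"] == "+")).sum()),
            "n_down": int((t["deg"] & (t["direction"] == "-")).sum()),
        }
        for name, t in sorted(result.deg_tables.items())
    }
    shared = mrn.network_comparison(result.trns[0], result.trns[1])
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": dataclasses.asdict(result.config),
        "qc": {"flagged_samples": sorted(result.qc_flagged)},
        "deg_counts": deg_counts,
        "tca_updown_counts": result.tca_counts,
        "modules": {
            "n_modules": len(result.modules.module_ids),
            "sizes": {str(m): s for m, s in sorted(result.modules.sizes.items())},
            "n_unassigned": int((result.modules.labels == cx.UNASSIGNED).sum()),
            "key_modules": {t: int(m) for t, m in sorted(result.key_modules.items())},
            "module_trait_cor": {
                str(m): {t: round(float(v), 6) for t, v in row.items()}
                for m, row in result.module_trait.module_trait_cor.iterrows()
            },
        },
        "trn": {
            "edges_per_variety": {n.variety: len(n.edges) for n in result.trns},
            "shared_tf_count": len(shared["shared_tfs"]),
            "shared_tfs": shared["shared_tfs"],
        },
        "sweeps": {
            "hard_filter_counts": result.hard_filter_counts,
            "fst_threshold": round(result.fst_regions.threshold, 8),
            "xpclr_threshold": round(result.xpclr_regions.threshold, 8),
            "n_fst_regions": len(result.fst_regions.regions),
            "n_xpclr_regions": len(result.xpclr_regions.regions),
            "fst_regions": result.fst_regions.regions.to_dict("records"),
            "xpclr_regions": result.xpclr_regions.regions.to_dict("records"),
        },
        "candidates": [
            {
                "gene_id": c.gene_id,
                "pathway": c.pathway_label,
                "module": c.module,
                "deg_evidence": [list(e) for e in c.deg_evidence],
            }
            for c in result.candidates
        ],
        "nominations": [dataclasses.asdict(n) for n in result.nominations],
        "validation": {
            g: {
                "log2FC": round(float(r["log2FC"]), 6),
                "padj": float(r["padj"]),
                "direction": str(r["direction"]),
            }
            for g, r in result.validation.iterrows()
        },
        "provenance": {
            "deg_tables": _checksum({k: v.to_csv() for k, v in sorted(result.deg_tables.items())}),
            "module_labels": _checksum(result.modules.labels.to_dict()),
        },
    }
    if ds is not None:
        report["provenance"]["counts"] = _checksum(ds.counts.counts.to_csv())
        report["provenance"]["variants"] = _checksum(
            (ds.variants.pos.tolist(), ds.variants.genotypes.tobytes())
        )
    return report


def write_report(report: dict, outdir: str | os.PathLike) -> None:
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    lines = [
        "# Pipeline report",
        "",
        f"Schema version {report['schema_version']}",
        "",
        f"QC-flagged samples: {', '.join(report['qc']['flagged_samples']) or 'none'}",
        "",
        "## DEG counts per contrast",
    ]
    for name, c in report["deg_counts"].items():
        lines.append(f"- {name}: {c['n_deg']} ({c['n_up']} up, {c['n_down']} down)")
    lines += [
        "",
        f"## Modules: {report['modules']['n_modules']} "
        f"(unassigned {report['modules']['n_unassigned']})",
        f"Key modules: {report['modules']['key_modules']}",
        "",
        f"## TRN shared TFs: {report['trn']['shared_tf_count']}",
        "",
        f"## Sweep regions: FST {report['sweeps']['n_fst_regions']}, "
        f"XP-CLR {report['sweeps']['n_xpclr_regions']}",
        "",
        "## Domestication calls",
    ]
    for n in report["nominations"]:
        lines.append(f"- {n['gene_id']} ({n['role']})")
    with open(os.path.join(outdir, "report.md"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
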