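"""End-to-end orchestration of the analysis stages, in study order:

normalize -> call total-p53 peaks per condition -> classify common vs
preferential / RPP / R^2 -> phospho restriction + quintile fractions ->
region annotation -> motif scan -> expression integration -> differential
pS46 candidates, with optional scoring against a simulation truth table.

``run_stages`` works on in-memory objects (what the tests, drivers and the
acceptance script use); ``run_all`` is the file-level wrapper that loads a
:class:`PipelineConfig`'s paths, runs the stages and writes TSV/JSON
reports plus a parameter log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coverage, expression, motif, occupancy, peaks, regions
from .core import (
    Genome,
    GenomicInterval,
    overlap_fraction,
    read_chrom_sizes,
    read_genes,
    read_tags,
)
from .coverage import TagLibrary
from .expression import ExpressionTable
from .simulate import Bundle, recovery_report

logger = logging.getLogger("phosphobind")

__all__ = ["PipelineParams", "PipelineConfig", "run_stages", "run_all"]


@dataclass
class PipelineParams:
    """Tunable analysis parameters with their study defaults."""

    extension_bp: int = 133
    window_bp: int = 10
    pvalue: float = 1e-7
    min_height: int = 1
    flank: int = 25000
    fold: float = 1.7
    diff_fold: float = 1.2
    ptm_fold: float = 2.0
    n_bins: int = 5
    k: int = 10
    n_background_regions: int = 2000
    background_region_bp: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("extension_bp", "window_bp", "flank", "n_bins", "k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.pvalue <= 1:
            raise ValueError("pvalue must be in (0, 1]")


@dataclass
class PipelineConfig:
    """File-level configuration: input paths plus parameters."""

    genome_sizes: str
    tags: dict[str, str]  # sample_id ("total_A", "pS46_B", ...) -> BED path
    genes: str | None = None
    genome_fasta: str | None = None
    expression: str | None = None
    samples: str | None = None
    blacklist: str | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = PipelineParams(**raw.pop("params", {}))
        return cls(params=params, **raw)


def run_stages(
    genome: Genome,
    libraries: dict[tuple[str, str], TagLibrary],
    genes=None,
    sequences=None,
    expr_table: ExpressionTable | None = None,
    blacklist: list[GenomicInterval] | None = None,
    params: PipelineParams | None = None,
    bundle: Bundle | None = None,
) -> dict:
    """Run every stage on in-memory inputs; returns a results dict.

    ``libraries`` maps (antibody, condition) with antibodies ``total``,
    ``pS15``, ``pS46`` and conditions ``A``, ``B``; phospho libraries and
    downstream stages are skipped gracefully when their inputs are absent.
    When ``bundle`` carries the generating truth, recovery metrics are
    appended.
    """
    params = params or PipelineParams()
    ext, window = params.extension_bp, params.window_bp
    results: dict = {"params": asdict(params)}

    # --- normalization -----------------------------------------------------
    keys = sorted(libraries)
    norm_list = coverage.normalize_libraries(
        [libraries[k] for k in keys], seed=params.seed
    )
    norm = dict(zip(keys, norm_list))
    results["normalized_depth"] = norm_list[0].depth
    logger.info("normalized %d libraries to depth %d", len(norm), norm_list[0].depth)

    # --- total-p53 peak calling -------------------------------------------
    total_peaks: dict[str, list[peaks.Peak]] = {}
    for cond in ("A", "B"):
        called = peaks.call_peaks(
            norm[("total", cond)],
            genome,
            p_threshold=params.pvalue,
            ext=ext,
            window_bp=window,
            min_height=params.min_height,
            name_prefix=f"total{cond}",
        )
        total_peaks[cond] = peaks.filter_artifacts(called, blacklist or [])
        results[f"n_peaks_total_{cond}"] = len(total_peaks[cond])

    # --- occupancy comparison ----------------------------------------------
    cls = occupancy.classify_common_preferential(total_peaks["A"], total_peaks["B"])
    results["n_common_A"] = cls.n_common_a
    results["n_common_B"] = cls.n_common_b
    if total_peaks["A"]:
        results["overlap_percent_A_in_B"] = overlap_fraction(
            len(total_peaks["A"]), cls.n_common_a
        )

    union = peaks.merge_peak_sets(total_peaks["A"], total_peaks["B"])
    results["n_union_sites"] = len(union)
    rpp = occupancy.rpp_matrix(union, list(norm.values()), genome, ext)
    results["rpp_matrix"] = rpp
    if len(union) >= 2:
        try:
            results["rsq_total"] = occupancy.rsq(rpp["total_A"], rpp["total_B"])
        except ValueError:
            results["rsq_total"] = None

    rpp_a = occupancy.reads_per_peak(total_peaks["A"], norm[("total", "A")], genome, ext)
    rpp_b = occupancy.reads_per_peak(total_peaks["B"], norm[("total", "B")], genome, ext)
    results["median_rpp"] = occupancy.median_rpp_report(cls, rpp_a, rpp_b)

    bg = occupancy.background_rpp(
        norm[("total", "A")],
        params.n_background_regions,
        params.background_region_bp,
        genome,
        seed=params.seed,
        ext=ext,
    )
    pref_a = [p for p, c in zip(total_peaks["A"], cls.common_mask_a) if not c]
    if pref_a:
        pref_rpp = occupancy.reads_per_peak(pref_a, norm[("total", "A")], genome, ext)
        d, p = occupancy.ks_two_sample(pref_rpp, bg)
        results["preferential_vs_background"] = {"ks_D": d, "ks_p": p}

    # --- phospho-specific peaks and quintile fractions ----------------------
    mean_total_rpp = (
        rpp["total_A"].to_numpy() + rpp["total_B"].to_numpy()
    ) / 2.0
    results["bin_fractions"] = {}
    phospho_peaks: dict[tuple[str, str], list[peaks.Peak]] = {}
    for antibody in ("pS15", "pS46"):
        for cond in ("A", "B"):
            if (antibody, cond) not in norm:
                continue
            called = peaks.call_peaks(
                norm[(antibody, cond)],
                genome,
                p_threshold=params.pvalue,
                ext=ext,
                window_bp=window,
                min_height=params.min_height,
                name_prefix=f"{antibody}{cond}",
            )
            restricted = peaks.restrict_to_reference(called, union)
            phospho_peaks[(antibody, cond)] = restricted
            results[f"n_peaks_{antibody}_{cond}"] = len(restricted)
            if len(union) >= params.n_bins:
                results["bin_fractions"][f"{antibody}_{cond}"] = (
                    occupancy.binned_modification_fraction(
                        union, mean_total_rpp, restricted, params.n_bins
                    ).tolist()
                )
    for antibody in ("pS15", "pS46"):
        cols = (f"{antibody}_A", f"{antibody}_B")
        if all(c in rpp.columns for c in cols) and len(union) >= 2:
            try:
                results[f"rsq_{antibody}"] = occupancy.rsq(rpp[cols[0]], rpp[cols[1]])
            except ValueError:
                results[f"rsq_{antibody}"] = None

    # --- region annotation ---------------------------------------------------
    if genes is not None:
        region_map = regions.build_region_map(genes, genome)
        dist = regions.genomic_distribution(region_map)
        results["genomic_distribution"] = dist
        _, counts = regions.annotate_peaks(union, region_map)
        results["peak_categories"] = counts
        results["enrichment"] = regions.enrichment_test(counts, len(union), dist)
        gene_table = regions.assign_peaks_to_genes(union, genes, params.flank)
        results["gene_peak_table"] = gene_table
        results["n_bound_genes"] = gene_table["gene_id"].nunique()

    # --- motif scan ----------------------------------------------------------
    if sequences is not None and union:
        model = motif.default_p53_model()
        results["motif_fraction_union"] = motif.fraction_with_motif(
            union, sequences, model
        )

    # --- expression integration ---------------------------------------------
    if expr_table is not None and genes is not None:
        ratios = expression.compute_ratios(expr_table)
        results["ratios"] = ratios
        results["expression_correlation"] = expression.treatment_correlation(
            ratios, "A", "B"
        )
        bound_genes = sorted(set(results["gene_peak_table"]["gene_id"]))
        for cond in ("A", "B"):
            n_bound, n_changed, pct = expression.select_bound_changed(
                bound_genes, ratios, cond, params.fold
            )
            results[f"bound_changed_{cond}"] = {
                "n_bound": n_bound,
                "n_changed": n_changed,
                "percent": pct,
            }
        bound_in_ratios = [g for g in bound_genes if g in ratios.index]
        if len(bound_in_ratios) >= params.k:
            X = ratios.loc[bound_in_ratios, ["A", "B"]].to_numpy()
            labels, _, objective = expression.kmeans_uncentered(
                X, k=params.k, seed=params.seed
            )
            results["clusters"] = pd.DataFrame(
                {"gene_id": bound_in_ratios, "cluster": labels}
            )
            results["kmeans_objective"] = objective

        if ("pS46", "A") in norm and ("pS46", "B") in norm:
            cand = expression.select_differential_ptm_candidates(
                [p.name for p in union],
                rpp["pS46_A"].to_numpy(),
                rpp["pS46_B"].to_numpy(),
                results["gene_peak_table"],
                ratios,
                "A",
                "B",
                ptm_fold=params.ptm_fold,
                expr_fold=params.diff_fold,
            )
            results["candidate_table"] = cand
            selected = cand[cand["candidate"]]
            results["n_candidate_pairs"] = int(len(selected))
            results["n_candidate_genes"] = int(selected["gene_id"].nunique())

    # --- recovery vs simulation truth ---------------------------------------
    if bundle is not None:
        cand_genes = None
        if "candidate_table" in results:
            sel = results["candidate_table"]
            cand_genes = sorted(set(sel.loc[sel["candidate"], "gene_id"]))
        results["recovery"] = recovery_report(
            bundle.truth_sites,
            union,
            peak_rpp=mean_total_rpp,
            candidate_genes=cand_genes,
            truth_genes=bundle.truth_genes,
        )
    return results


def run_bundle(bundle: Bundle, params: PipelineParams | None = None) -> dict:
    """Convenience: run every stage directly on a generated bundle."""
    expr_table = ExpressionTable(bundle.expression, bundle.sample_sheet)
    return run_stages(
        bundle.genome,
        bundle.libraries,
        genes=bundle.genes,
        sequences=bundle.sequences,
        expr_table=expr_table,
        params=params,
        bundle=bundle,
    )


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """File-level pipeline: load inputs, run stages, write reports.

    Writes ``rpp_matrix.tsv``, ``classification-level`` summaries,
    ``bin_fractions.tsv``, annotation/enrichment/cluster/candidate tables
    and ``summary.json`` (which embeds the exact parameter set used).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = read_chrom_sizes(config.genome_sizes)
    libraries = {}
    for sample_id, path in config.tags.items():
        antibody, cond = sample_id.rsplit("_", 1)
        libraries[(antibody, cond)] = TagLibrary(
            sample_id, antibody, cond, read_tags(path)
        )
    genes = read_genes(config.genes) if config.genes else None
    sequences = None
    if config.genome_fasta:
        import pyfaidx

        sequences = pyfaidx.Fasta(config.genome_fasta)
    expr_table = None
    if config.expression and config.samples:
        expr_table = ExpressionTable.from_files(config.expression, config.samples)
    blacklist = None
    if config.blacklist:
        blacklist = []
        with open(config.blacklist) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                blacklist.append(GenomicInterval(chrom, int(start), int(end)))

    results = run_stages(
        genome,
        libraries,
        genes=genes,
        sequences=sequences,
        expr_table=expr_table,
        blacklist=blacklist,
        params=config.params,
    )
    _write_reports(results, outdir)
    return results


def _write_reports(results: dict, outdir: Path) -> None:
    summary = {}
    for key, value in results.items():
        if isinstance(value, pd.DataFrame):
            value.to_csv(outdir / f"{key}.tsv", sep="\t")
        elif isinstance(value, np.ndarray):
            np.savetxt(outdir / f"{key}.tsv", value, delimiter="\t")
        else:
            summary[key] = value
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")
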