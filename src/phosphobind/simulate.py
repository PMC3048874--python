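"""Truth-annotated miniature study generator.

Emulates the full experimental design the pipeline assumes: two treatments
(generic conditions ``A`` and ``B``) x three antibodies (total p53, pS15,
pS46) sharing one set of genomic binding sites, plus a replicated
expression matrix in which a subset of site-proximal genes responds to
condition B only.

Generative model
----------------
* Background tags are a homogeneous Poisson process per library.
* Each binding site emits ``Poisson(strength)`` sequencing fragments per
  total-p53 library; fragment centers fall uniformly within +/-66 bp of
  the site center, fragments are 133 bp, and the recorded tag is the
  fragment's 5' end on a random strand (so directional extension by 133 bp
  recovers the fragment).
* Phospho-specific libraries are *thinned* subsets of the total fragment
  process: a site-bound protein is phosphorylated with probability ``f``
  (pS15: condition-independent; pS46: higher in condition B at the
  designated responsive sites, which are the strongest sites).  Background
  rates are topped up per library so expected depths match across
  antibodies, as library preparations are sequenced to similar depth.
* Responsive sites sit inside designated genes, which receive a true log2
  expression change in condition B; all other genes are null.  Replicates
  add Gaussian noise.

Every random draw flows from one seed; a config + seed pair yields a
byte-identical output bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    GeneModel,
    Genome,
    Tag,
    write_chrom_sizes,
    write_fasta,
    write_genes,
    write_tags,
)
from .coverage import TagLibrary
from .peaks import Peak

__all__ = ["SimulationConfig", "Bundle", "generate", "recovery_report"]

ANTIBODIES = ("total", "pS15", "pS46")
CONDITIONS = ("A", "B")
CONSENSUS_SITE = "GGGCATGTCC" * 2  # planted response element (two half-sites)


@dataclass
class SimulationConfig:
    """Study conditions for the miniature dataset.

    Site strengths are expected fragment counts per total-p53 library and
    follow a shifted log-normal, ``strength_min * (1 + LogNormal(mu,
    sigma))``, so every site clears the minimum evidence the peak caller
    is specified to recover (>= 30 expected fragments at >= ~20x local
    enrichment over background).
    """

    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 500_000, "chr2": 500_000}
    )
    n_genes: int = 60
    n_sites: int = 120
    strength_min: float = 30.0
    strength_lognorm_mu: float = 0.0
    strength_lognorm_sigma: float = 0.8
    background_rate: float = 0.01  # tags per bp per library (total antibody)
    f15: float = 0.5  # pS15 fraction, condition-independent
    f46_base: float = 0.1  # pS46 fraction at non-responsive sites (both conditions)
    f46_responsive_B: float = 0.5  # pS46 fraction at responsive sites, condition B
    responsive_fraction: float = 0.25  # strongest sites, B-preferential
    expression_effect: float = 1.0  # true log2 change in B for responsive genes
    expression_noise_sd: float = 0.05  # technical-duplicate noise, log2 scale
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    gc: float = 0.41
    fragment_len: int = 133
    implant_motif: bool = True
    min_site_spacing: int = 3000
    target_depth: int | None = None  # optional post-hoc per-library downsample

    def __post_init__(self) -> None:
        for name in ("f15", "f46_base", "f46_responsive_B", "responsive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.background_rate <= 0 or self.strength_min <= 0:
            raise ValueError("rates and strengths must be positive")
        if any(s <= 0 for s in self.chrom_sizes.values()):
            raise ValueError("chromosome sizes must be positive")


@dataclass
class Bundle:
    """In-memory view of a generated study plus the paths written."""

    config: SimulationConfig
    genome: Genome
    sequences: dict[str, str]
    genes: list[GeneModel]
    libraries: dict[tuple[str, str], TagLibrary]  # (antibody, condition)
    expression: pd.DataFrame
    sample_sheet: pd.DataFrame
    truth_sites: pd.DataFrame
    truth_genes: pd.DataFrame
    paths: dict[str, str] = field(default_factory=dict)


def generate(config: SimulationConfig, outdir: str | Path | None = None) -> Bundle:
    """Generate the full file bundle and truth tables.

    With ``outdir`` set, writes genome FASTA, chrom.sizes, genes TSV, six
    tag BED files, expression + sample-sheet TSVs, truth TSVs and a
    MANIFEST.json; identical config and seed give byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    genome = Genome.from_sizes(config.chrom_sizes)

    sequences = _draw_sequences(rng, genome, config.gc)
    genes = _place_genes(rng, genome, config.n_genes)
    truth_sites = _place_sites(rng, genome, genes, config)

    if config.implant_motif:
        _implant_motifs(sequences, truth_sites)

    libraries = _draw_libraries(rng, genome, truth_sites, config)

    truth_genes, expression, sample_sheet = _draw_expression(
        rng, genes, truth_sites, config
    )

    bundle = Bundle(
        config=config,
        genome=genome,
        sequences=sequences,
        genes=genes,
        libraries=libraries,
        expression=expression,
        sample_sheet=sample_sheet,
        truth_sites=truth_sites,
        truth_genes=truth_genes,
    )
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


# ---------------------------------------------------------------------------
# generation steps


def _draw_sequences(rng, genome: Genome, gc: float) -> dict[str, str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = {}
    for chrom in genome.chrom_names:
        codes = rng.choice(4, size=genome.size(chrom), p=p)
        out[chrom] = "".join(np.array(list("ACGT"))[codes])
    return out


def _place_genes(rng, genome: Genome, n_genes: int) -> list[GeneModel]:
    """Evenly slotted non-overlapping genes with 2-5 exons each."""
    genes: list[GeneModel] = []
    sizes = np.array([genome.size(c) for c in genome.chrom_names], dtype=float)
    per_chrom = np.maximum(1, np.round(n_genes * sizes / sizes.sum()).astype(int))
    # adjust rounding drift
    while per_chrom.sum() > n_genes:
        per_chrom[np.argmax(per_chrom)] -= 1
    while per_chrom.sum() < n_genes:
        per_chrom[np.argmin(per_chrom)] += 1
    gid = 0
    for chrom, n_c in zip(genome.chrom_names, per_chrom):
        size = genome.size(chrom)
        slot = size // n_c
        for i in range(n_c):
            tx_len = int(rng.integers(3000, min(8000, max(3001, slot - 2000))))
            lo = i * slot + 1000
            hi = min((i + 1) * slot, size) - tx_len - 1000
            tx_start = int(rng.integers(lo, max(lo + 1, hi)))
            tx_end = tx_start + tx_len
            n_ex = int(rng.integers(2, 6))
            breaks = np.sort(
                rng.choice(
                    np.arange(tx_start + 200, tx_end - 200),
                    size=2 * (n_ex - 1),
                    replace=False,
                )
            )
            exon_starts = (tx_start,) + tuple(int(b) for b in breaks[1::2])
            exon_ends = tuple(int(b) for b in breaks[0::2]) + (tx_end,)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    f"gene{gid:03d}", chrom, strand, tx_start, tx_end,
                    exon_starts, exon_ends,
                )
            )
            gid += 1
    return genes


def _place_sites(
    rng, genome: Genome, genes: list[GeneModel], config: SimulationConfig
) -> pd.DataFrame:
    """Draw strengths, designate the strongest sites responsive, place them.

    Responsive sites sit inside distinct host genes (guaranteeing a
    peak-to-gene assignment); the rest are scattered with a minimum
    spacing so neighbouring peaks never merge.
    """
    n = config.n_sites
    strengths = config.strength_min * (
        1.0
        + rng.lognormal(
            config.strength_lognorm_mu, config.strength_lognorm_sigma, size=n
        )
    )
    n_resp = int(round(config.responsive_fraction * n))
    order = np.argsort(-strengths)  # strongest first
    responsive = np.zeros(n, dtype=bool)
    responsive[order[:n_resp]] = True

    host_genes = rng.choice(len(genes), size=n_resp, replace=False)
    placements: list[tuple[str, int]] = []
    taken: dict[str, list[int]] = {c: [] for c in genome.chrom_names}

    def _far_enough(chrom: str, pos: int) -> bool:
        return all(abs(pos - q) >= config.min_site_spacing for q in taken[chrom])

    chroms = np.empty(n, dtype=object)
    centers = np.zeros(n, dtype=np.int64)
    host = np.empty(n, dtype=object)
    resp_iter = iter(host_genes)
    # responsive sites first: their positions are constrained to host genes
    site_order = [i for i in range(n) if responsive[i]] + [
        i for i in range(n) if not responsive[i]
    ]
    for i in site_order:
        if responsive[i]:
            g = genes[int(next(resp_iter))]
            for _ in range(1000):
                pos = int(rng.integers(g.tx_start + 200, g.tx_end - 200))
                if _far_enough(g.chrom, pos):
                    break
            else:
                raise RuntimeError("could not place a responsive site")
            chroms[i], centers[i], host[i] = g.chrom, pos, g.gene_id
        else:
            for _ in range(1000):
                ci = int(rng.integers(0, len(genome.chrom_names)))
                chrom = genome.chrom_names[ci]
                pos = int(rng.integers(1000, genome.size(chrom) - 1000))
                if _far_enough(chrom, pos):
                    break
            else:
                raise RuntimeError("could not place a background site")
            chroms[i], centers[i], host[i] = chrom, pos, ""
        taken[chroms[i]].append(int(centers[i]))

    f46_a = np.full(n, config.f46_base)
    f46_b = np.where(responsive, config.f46_responsive_B, config.f46_base)
    return pd.DataFrame(
        {
            "site_id": [f"site{i:03d}" for i in range(n)],
            "chrom": chroms,
            "center": centers,
            "strength": strengths,
            "responsive": responsive,
            "host_gene": host,
            "f15": config.f15,
            "f46_A": f46_a,
            "f46_B": f46_b,
            "motif_pos": centers - len(CONSENSUS_SITE) // 2,
        }
    )


def _implant_motifs(sequences: dict[str, str], truth_sites: pd.DataFrame) -> None:
    for _, site in truth_sites.iterrows():
        seq = sequences[site["chrom"]]
        pos = int(site["motif_pos"])
        sequences[site["chrom"]] = (
            seq[:pos] + CONSENSUS_SITE + seq[pos + len(CONSENSUS_SITE) :]
        )


def _antibody_fraction(site: pd.Series, antibody: str, condition: str) -> float:
    if antibody == "total":
        return 1.0
    if antibody == "pS15":
        return float(site["f15"])
    return float(site[f"f46_{condition}"])


def _draw_libraries(
    rng, genome: Genome, truth_sites: pd.DataFrame, config: SimulationConfig
) -> dict[tuple[str, str], TagLibrary]:
    frag = config.fragment_len
    half = (frag - 1) // 2  # 66 for 133 bp fragments
    total_site_expect = float(truth_sites["strength"].sum())
    libraries: dict[tuple[str, str], TagLibrary] = {}
    for antibody in ANTIBODIES:
        for condition in CONDITIONS:
            site_expect = sum(
                site["strength"] * _antibody_fraction(site, antibody, condition)
                for _, site in truth_sites.iterrows()
            )
            # top up background so expected depths match across antibodies
            bg_rate = config.background_rate + (
                total_site_expect - site_expect
            ) / genome.total_size
            tags: list[Tag] = []
            for _, site in truth_sites.iterrows():
                lam = site["strength"] * _antibody_fraction(site, antibody, condition)
                n_frag = int(rng.poisson(lam))
                if n_frag == 0:
                    continue
                centers = rng.integers(
                    int(site["center"]) - half,
                    int(site["center"]) + half + 1,
                    size=n_frag,
                )
                strands = rng.random(n_frag) < 0.5
                size = genome.size(site["chrom"])
                for c, plus in zip(centers, strands):
                    start = int(c) - half
                    end = start + frag
                    pos = start if plus else end - 1
                    pos = min(max(pos, 0), size - 1)
                    tags.append(Tag(site["chrom"], pos, "+" if plus else "-"))
            for chrom in genome.chrom_names:
                size = genome.size(chrom)
                n_bg = int(rng.poisson(bg_rate * size))
                positions = rng.integers(0, size, size=n_bg)
                strands = rng.random(n_bg) < 0.5
                tags.extend(
                    Tag(chrom, int(p), "+" if s else "-")
                    for p, s in zip(positions, strands)
                )
            sample_id = f"{antibody}_{condition}"
            lib = TagLibrary(sample_id, antibody, condition, tags)
            if config.target_depth is not None:
                from .coverage import downsample

                lib = downsample(
                    lib, min(config.target_depth, lib.depth),
                    int(rng.integers(0, 2**31 - 1)),
                )
            libraries[(antibody, condition)] = lib
    return libraries


def _draw_expression(
    rng, genes: list[GeneModel], truth_sites: pd.DataFrame, config: SimulationConfig
):
    responsive_hosts = set(
        truth_sites.loc[truth_sites["responsive"], "host_gene"]
    )
    gene_ids = [g.gene_id for g in genes]
    true_da = np.zeros(len(genes))
    true_db = np.array(
        [
            config.expression_effect if gid in responsive_hosts else 0.0
            for gid in gene_ids
        ]
    )
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=len(genes))

    columns, data = [], {}
    sheet = []
    for cond, true_d in (("A", true_da), ("B", true_db)):
        for tp, shift in (("0h", 0.0), ("24h", 1.0)):
            for rep in (1, 2):
                sample = f"{cond}_{tp}_r{rep}"
                noise = rng.normal(0.0, config.expression_noise_sd, size=len(genes))
                data[sample] = baseline + shift * true_d + noise
                columns.append(sample)
                sheet.append(
                    {
                        "sample_id": sample,
                        "condition": cond,
                        "timepoint": tp,
                        "replicate": str(rep),
                    }
                )
    expression = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    sample_sheet = pd.DataFrame(sheet)
    truth_genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_dlog2_A": true_da,
            "true_dlog2_B": true_db,
            "candidate": [
                gid in responsive_hosts
                and abs(db - da) >= np.log2(1.2)
                for gid, da, db in zip(gene_ids, true_da, true_db)
            ],
        }
    )
    return truth_genes, expression, sample_sheet


def _write_bundle(bundle: Bundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome_fasta": outdir / "genome.fa",
        "chrom_sizes": outdir / "genome.chrom.sizes",
        "genes": outdir / "genes.tsv",
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "truth_sites": outdir / "truth_sites.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
    }
    write_fasta(bundle.sequences, paths["genome_fasta"])
    write_chrom_sizes(bundle.genome, paths["chrom_sizes"])
    write_genes(bundle.genes, paths["genes"])
    bundle.expression.round(6).to_csv(paths["expression"], sep="\t")
    bundle.sample_sheet.to_csv(paths["samples"], sep="\t", index=False)
    bundle.truth_sites.round(6).to_csv(paths["truth_sites"], sep="\t", index=False)
    bundle.truth_genes.round(6).to_csv(paths["truth_genes"], sep="\t", index=False)
    for (antibody, condition), lib in bundle.libraries.items():
        key = f"tags_{antibody}_{condition}"
        paths[key] = outdir / f"{key}.bed"
        write_tags(lib.tags, paths[key])
    manifest = {
        "files": {k: p.name for k, p in sorted(paths.items())},
        "config": {
            k: (v if not isinstance(v, dict) else dict(v))
            for k, v in asdict(bundle.config).items()
        },
    }
    manifest_path = outdir / "MANIFEST.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = manifest_path
    bundle.paths = {k: str(p) for k, p in paths.items()}


# ---------------------------------------------------------------------------
# recovery metrics


def recovery_report(
    truth_sites: pd.DataFrame,
    called_peaks: list[Peak],
    peak_rpp=None,
    candidate_genes=None,
    truth_genes: pd.DataFrame | None = None,
    match_bp: int = 200,
) -> dict:
    """Score pipeline output against the generator's truth.

    A true site is recovered iff some called peak summit lies within
    ``match_bp`` of its center (same chromosome); a called peak is a false
    discovery iff it matches no site.  With ``peak_rpp`` (aligned to
    ``called_peaks``) the Spearman correlation between matched-peak RPP and
    true strength is added; with ``candidate_genes`` and ``truth_genes``
    the candidate precision/recall are added.
    """
    site_matched = np.zeros(len(truth_sites), dtype=bool)
    peak_matched = np.zeros(len(called_peaks), dtype=bool)
    site_best_rpp = np.full(len(truth_sites), np.nan)
    for j, p in enumerate(called_peaks):
        for i, (_, site) in enumerate(truth_sites.iterrows()):
            if p.interval.chrom != site["chrom"]:
                continue
            if abs(p.summit - int(site["center"])) <= match_bp:
                site_matched[i] = True
                peak_matched[j] = True
                if peak_rpp is not None:
                    r = float(np.asarray(peak_rpp)[j])
                    if np.isnan(site_best_rpp[i]) or r > site_best_rpp[i]:
                        site_best_rpp[i] = r
    report = {
        "n_sites": int(len(truth_sites)),
        "n_peaks": int(len(called_peaks)),
        "sensitivity": float(site_matched.mean()) if len(truth_sites) else 0.0,
        "fdr": float((~peak_matched).mean()) if called_peaks else 0.0,
    }
    if peak_rpp is not None and site_matched.sum() >= 3:
        strengths = truth_sites["strength"].to_numpy()[site_matched]
        rpps = site_best_rpp[site_matched]
        rho = stats.spearmanr(rpps, strengths).statistic
        report["spearman_rpp_strength"] = float(rho)
    if candidate_genes is not None and truth_genes is not None:
        truth_set = set(truth_genes.loc[truth_genes["candidate"], "gene_id"])
        called_set = set(candidate_genes)
        tp = len(truth_set & called_set)
        report["candidate_precision"] = tp / len(called_set) if called_set else 1.0
        report["candidate_recall"] = tp / len(truth_set) if truth_set else 1.0
        report["n_candidate_genes"] = len(called_set)
        report["n_true_candidate_genes"] = len(truth_set)
    return report
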