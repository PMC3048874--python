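"""Integrate binding with expression changes and select pS46 candidates.

Computes per-condition log2 expression changes, their between-treatment
correlation, the bound-and-changed gene counts at the 1.7-fold threshold,
k-means clusters of bound genes' change profiles (uncentered correlation,
k = 10), and the differential-pS46 candidate list (2-fold pS46 RPP ratio,
1.2-fold expression difference).  Tables go to results/expression/.
"""

import json

import pandas as pd

from common import PEAKS_DIR, RESULTS, SIM_DIR, load_genome, load_libraries, seed_argument

from phosphobind.coverage import normalize_libraries
from phosphobind.expression import (
    ExpressionTable,
    compute_ratios,
    kmeans_uncentered,
    select_bound_changed,
    select_differential_ptm_candidates,
    treatment_correlation,
)
from phosphobind.occupancy import reads_per_peak
from phosphobind.peaks import read_peaks_bed


def main():
    args = seed_argument(__doc__).parse_args()
    outdir = RESULTS / "expression"
    outdir.mkdir(parents=True, exist_ok=True)
    genome = load_genome()
    libraries = load_libraries()
    keys = sorted(libraries)
    norm = dict(zip(keys, normalize_libraries([libraries[k] for k in keys], args.seed)))

    table = ExpressionTable.from_files(
        SIM_DIR / "expression.tsv", SIM_DIR / "samples.tsv"
    )
    ratios = compute_ratios(table)
    ratios.to_csv(outdir / "ratios.tsv", sep="\t")
    r = treatment_correlation(ratios, "A", "B")
    print(f"between-treatment correlation of expression changes: r = {r:.2f}")

    gene_peak = pd.read_csv(
        RESULTS / "annotation" / "gene_peak_table.tsv", sep="\t"
    )
    bound_genes = sorted(set(gene_peak["gene_id"]))
    summary = {"expression_correlation": r}
    for cond in ("A", "B"):
        n_bound, n_changed, pct = select_bound_changed(bound_genes, ratios, cond)
        summary[f"bound_changed_{cond}"] = {
            "n_bound": n_bound, "n_changed": n_changed, "percent": pct,
        }
        print(f"condition {cond}: {n_changed}/{n_bound} bound genes "
              f"changed >= 1.7-fold ({pct}%)")

    in_ratios = [g for g in bound_genes if g in ratios.index]
    labels, _, objective = kmeans_uncentered(
        ratios.loc[in_ratios, ["A", "B"]].to_numpy(), k=10, seed=args.seed
    )
    pd.DataFrame({"gene_id": in_ratios, "cluster": labels}).to_csv(
        outdir / "clusters.tsv", sep="\t", index=False
    )
    print(f"k-means (k=10, uncentered correlation): objective {objective:.3f}")

    union = read_peaks_bed(PEAKS_DIR / "peaks_union.bed")
    rpp46_a = reads_per_peak(union, norm[("pS46", "A")], genome)
    rpp46_b = reads_per_peak(union, norm[("pS46", "B")], genome)
    cand = select_differential_ptm_candidates(
        [p.name for p in union], rpp46_a, rpp46_b, gene_peak, ratios, "A", "B"
    )
    cand.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    selected = cand[cand["candidate"]]
    summary["n_candidate_pairs"] = int(len(selected))
    summary["n_candidate_genes"] = int(selected["gene_id"].nunique())
    print(f"{len(selected)} binding sites close to "
          f"{selected['gene_id'].nunique()} unique genes show B-preferential "
          f"pS46 binding plus a >= 1.2-fold expression difference")

    with open(outdir / "expression_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")


if __name__ == "__main__":
    main()
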