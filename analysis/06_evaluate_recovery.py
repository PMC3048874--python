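"""Score the pipeline's output against the generator's truth tables.

Reports peak sensitivity and FDR, the Spearman correlation between RPP and
true site strength, and candidate precision/recall.  Goes to
results/recovery.json.
"""

import json

import numpy as np
import pandas as pd

from common import PEAKS_DIR, RESULTS, SIM_DIR, seed_argument

from phosphobind.peaks import read_peaks_bed
from phosphobind.simulate import recovery_report


def main():
    seed_argument(__doc__).parse_args()
    truth_sites = pd.read_csv(SIM_DIR / "truth_sites.tsv", sep="\t")
    truth_genes = pd.read_csv(SIM_DIR / "truth_genes.tsv", sep="\t")
    union = read_peaks_bed(PEAKS_DIR / "peaks_union.bed")
    rpp = pd.read_csv(RESULTS / "occupancy" / "rpp_matrix.tsv", sep="\t", index_col=0)
    mean_rpp = np.array(
        [(rpp.at[p.name, "total_A"] + rpp.at[p.name, "total_B"]) / 2 for p in union]
    )
    cand = pd.read_csv(RESULTS / "expression" / "candidates.tsv", sep="\t")
    cand_genes = sorted(set(cand.loc[cand["candidate"], "gene_id"]))

    report = recovery_report(
        truth_sites, union, peak_rpp=mean_rpp,
        candidate_genes=cand_genes, truth_genes=truth_genes,
    )
    with open(RESULTS / "recovery.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    print(f"sensitivity {report['sensitivity']:.3f}, FDR {report['fdr']:.3f}")
    print(f"Spearman(RPP, true strength) = {report['spearman_rpp_strength']:.2f}")
    print(f"candidate precision {report['candidate_precision']:.2f}, "
          f"recall {report['candidate_recall']:.2f}")


if __name__ == "__main__":
    main()
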