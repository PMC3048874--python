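"""Compare binding occupancy between treatments and antibodies.

Computes the RPP matrix over the union sites, squared correlations between
conditions, the common/preferential classification with median RPP and KS
tests, random-region background, and the quintile-binned phospho
fractions.  Tables go to results/occupancy/.
"""

import json

import numpy as np

from common import PEAKS_DIR, RESULTS, load_genome, load_libraries, seed_argument

from phosphobind.core import overlap_fraction
from phosphobind.coverage import normalize_libraries
from phosphobind.occupancy import (
    background_rpp,
    binned_modification_fraction,
    classify_common_preferential,
    ks_two_sample,
    median_rpp_report,
    reads_per_peak,
    rpp_matrix,
    rsq,
)
from phosphobind.peaks import read_peaks_bed


def main():
    args = seed_argument(__doc__).parse_args()
    outdir = RESULTS / "occupancy"
    outdir.mkdir(parents=True, exist_ok=True)
    genome = load_genome()
    libraries = load_libraries()
    keys = sorted(libraries)
    norm = dict(zip(keys, normalize_libraries([libraries[k] for k in keys], args.seed)))

    total_a = read_peaks_bed(PEAKS_DIR / "peaks_total_A.bed")
    total_b = read_peaks_bed(PEAKS_DIR / "peaks_total_B.bed")
    union = read_peaks_bed(PEAKS_DIR / "peaks_union.bed")

    summary = {}
    cls = classify_common_preferential(total_a, total_b)
    summary["overlap_percent_A_in_B"] = overlap_fraction(len(total_a), cls.n_common_a)
    summary["overlap_percent_B_in_A"] = overlap_fraction(len(total_b), cls.n_common_b)
    print(f"{cls.n_common_a}/{len(total_a)} condition-A peaks common "
          f"({summary['overlap_percent_A_in_B']}%)")

    rpp = rpp_matrix(union, list(norm.values()), genome)
    rpp.to_csv(outdir / "rpp_matrix.tsv", sep="\t")
    for ab in ("total", "pS15", "pS46"):
        summary[f"rsq_{ab}"] = rsq(rpp[f"{ab}_A"], rpp[f"{ab}_B"])
        print(f"R^2 {ab} A vs B: {summary[f'rsq_{ab}']:.2f}")

    rpp_a = reads_per_peak(total_a, norm[("total", "A")], genome)
    rpp_b = reads_per_peak(total_b, norm[("total", "B")], genome)
    summary["median_rpp"] = median_rpp_report(cls, rpp_a, rpp_b)

    bg = background_rpp(norm[("total", "A")], 2000, 200, genome, seed=args.seed)
    pref = cls.preferential_a
    if pref:
        pref_rpp = reads_per_peak(pref, norm[("total", "A")], genome)
        d, p = ks_two_sample(pref_rpp, bg)
        summary["preferential_vs_background"] = {"ks_D": d, "ks_p": p}
        print(f"preferential-A RPP vs background: D={d:.2f}, p={p:.2e}")

    mean_rpp = (rpp["total_A"].to_numpy() + rpp["total_B"].to_numpy()) / 2
    bins = {}
    for ab in ("pS15", "pS46"):
        for cond in ("A", "B"):
            mod = read_peaks_bed(PEAKS_DIR / f"peaks_{ab}_{cond}.bed")
            bins[f"{ab}_{cond}"] = binned_modification_fraction(
                union, mean_rpp, mod
            ).tolist()
    summary["bin_fractions"] = bins
    print("top-quintile pS46 fraction: A=%.2f  B=%.2f"
          % (bins["pS46_A"][-1], bins["pS46_B"][-1]))

    with open(outdir / "occupancy_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")


if __name__ == "__main__":
    main()
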