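"""Depth-normalize the six libraries and call binding sites.

Total-p53 peaks are called per condition; phospho-specific peaks are
restricted to sites bound by total p53 in either condition.  Peak BEDs and
a count table go to results/peaks/.
"""

import json

from common import PEAKS_DIR, load_genome, load_libraries, seed_argument

from phosphobind.coverage import normalize_libraries
from phosphobind.peaks import call_peaks, merge_peak_sets, restrict_to_reference, write_peaks_bed


def main():
    args = seed_argument(__doc__).parse_args()
    genome = load_genome()
    libraries = load_libraries()
    PEAKS_DIR.mkdir(parents=True, exist_ok=True)

    keys = sorted(libraries)
    norm = dict(zip(keys, normalize_libraries([libraries[k] for k in keys], args.seed)))
    depth = norm[keys[0]].depth
    print(f"normalized all libraries to {depth} tags")

    counts = {"normalized_depth": depth}
    total = {}
    for cond in ("A", "B"):
        total[cond] = call_peaks(norm[("total", cond)], genome, name_prefix=f"total{cond}")
        write_peaks_bed(total[cond], PEAKS_DIR / f"peaks_total_{cond}.bed")
        counts[f"total_{cond}"] = len(total[cond])
        print(f"total p53, condition {cond}: {len(total[cond])} peaks")

    union = merge_peak_sets(total["A"], total["B"])
    write_peaks_bed(union, PEAKS_DIR / "peaks_union.bed")
    counts["union_sites"] = len(union)
    print(f"site-level union: {len(union)} binding sites")

    for ab in ("pS15", "pS46"):
        for cond in ("A", "B"):
            called = call_peaks(norm[(ab, cond)], genome, name_prefix=f"{ab}{cond}")
            kept = restrict_to_reference(called, union)
            write_peaks_bed(kept, PEAKS_DIR / f"peaks_{ab}_{cond}.bed")
            counts[f"{ab}_{cond}"] = len(kept)
            print(f"{ab}, condition {cond}: {len(kept)} peaks at total-p53 sites")

    with open(PEAKS_DIR / "peak_counts.json", "w") as fh:
        json.dump(counts, fh, indent=1, sort_keys=True)
        fh.write("\n")


if __name__ == "__main__":
    main()
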