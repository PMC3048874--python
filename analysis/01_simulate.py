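"""Generate the miniature two-treatment, three-antibody study.

Writes the genome, gene models, six tag libraries, the replicated
expression matrix and the truth tables under results/sim/.
"""

from common import SIM_DIR, seed_argument

from phosphobind.simulate import SimulationConfig, generate


def main():
    args = seed_argument(__doc__).parse_args()
    config = SimulationConfig(seed=args.seed)
    bundle = generate(config, SIM_DIR)
    print(f"wrote {len(bundle.paths)} files to {SIM_DIR}")
    print(f"  chromosomes: {dict(config.chrom_sizes)}")
    print(f"  sites: {config.n_sites} ({int(bundle.truth_sites['responsive'].sum())} responsive)")
    for key, lib in sorted(bundle.libraries.items()):
        print(f"  {key[0]}_{key[1]}: {lib.depth} tags")


if __name__ == "__main__":
    main()
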