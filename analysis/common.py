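"""Shared paths and loaders for the numbered analysis drivers."""

import argparse
from pathlib import Path

from phosphobind.core import read_chrom_sizes, read_genes, read_tags
from phosphobind.coverage import TagLibrary

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SIM_DIR = RESULTS / "sim"
PEAKS_DIR = RESULTS / "peaks"

ANTIBODIES = ("total", "pS15", "pS46")
CONDITIONS = ("A", "B")


def seed_argument(description):
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=0)
    return parser


def load_genome():
    return read_chrom_sizes(SIM_DIR / "genome.chrom.sizes")


def load_genes():
    return read_genes(SIM_DIR / "genes.tsv")


def load_libraries():
    libs = {}
    for ab in ANTIBODIES:
        for cond in CONDITIONS:
            tags = read_tags(SIM_DIR / f"tags_{ab}_{cond}.bed")
            libs[(ab, cond)] = TagLibrary(f"{ab}_{cond}", ab, cond, tags)
    return libs
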