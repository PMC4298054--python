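"""Simulate the study-shaped dataset: genotypes, truth, traits and tree.

Emulates the sampling design of the wasp paternity study: five species of
ten colonies each, ~20 genotyped workers per colony on a 6-locus
microsatellite panel with 2% missing calls, plus a 22-species trait table
and matching ultrametric phylogeny for the comparative stage.

Writes results/simulated/{genotypes.csv, truth.tsv, traits.csv, tree.nwk}.
"""

import argparse
from pathlib import Path

import numpy as np

from vespine.synthetic_data import (
    ColonySimConfig,
    default_locus_panel,
    simulate_comparative_dataset,
    simulate_species_dataset,
)

SPECIES = ["acadica", "atropilosa", "consobrina", "vidua", "flavopilosa"]
# observed mean paternity numbers per species range ~2-4; colony sizes differ
K_TRUE = {"acadica": 2, "atropilosa": 2, "consobrina": 3, "vidua": 3, "flavopilosa": 4}


def simulate_all(seed: int, out: Path):
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    configs = {}
    for sp in SPECIES:
        panel = default_locus_panel(n_loci=6, n_alleles=8, rng=rng)
        configs[sp] = (
            ColonySimConfig(
                loci=panel, k_true=K_TRUE[sp], shares=2.0, n_workers=20,
                missing_prob=0.02,
            ),
            10,
        )
    colonies, truth = simulate_species_dataset(
        configs,
        seed=seed,
        genotype_table_path=out / "genotypes.csv",
        truth_table_path=out / "truth.tsv",
    )
    traits, phylo = simulate_comparative_dataset(seed=seed)
    traits.to_csv(out / "traits.csv")
    phylo.tree.write(path=str(out / "tree.nwk"), schema="newick")
    return colonies, truth, traits, phylo


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20140277)
    ap.add_argument("--out", type=Path, default=Path("results/simulated"))
    args = ap.parse_args()
    colonies, truth, traits, phylo = simulate_all(args.seed, args.out)
    n_workers = sum(len(c.workers) for c in colonies)
    print(f"simulated {len(colonies)} colonies, {n_workers} workers "
          f"({len(SPECIES)} species); trait table for {len(traits)} taxa")
    print(f"wrote {args.out}/genotypes.csv, truth.tsv, traits.csv, tree.nwk")
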