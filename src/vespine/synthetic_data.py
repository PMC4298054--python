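"""Known-truth simulators for colony genotypes and comparative trait data.

Two generators mirror the statistical structure the analysis assumes:

* :func:`simulate_colony` draws a single-queen haplodiploid colony — a
  diploid queen sampled in Hardy-Weinberg proportions from per-locus allele
  frequency vectors, ``k_true`` haploid fathers, and ``n`` workers each built
  from one uniformly chosen maternal allele plus the paternal allele of a
  father drawn from the paternity-share vector.  Missingness is applied per
  worker-locus.  The true patriline partition is returned alongside.
* :func:`simulate_traits` draws species trait vectors under the PGLS
  generative model ``y = X beta + eps`` with ``eps`` multivariate normal with
  covariance ``sigma^2 * lambda_transform(phylo_vcv(tree), lambda_true)``.

Defaults emulate the study's sampling design: ~20 genotyped workers per
colony, 10 colonies per species, 4-6 microsatellite loci of roughly 5-10
alleles, and a 22-taxon ultrametric tree for trait simulations.  All
simulators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd

from .comparative import Phylogeny, lambda_transform, phylo_vcv
from .patrilines import (
    ColonyGenotypes,
    Genotype,
    PatrilinePartition,
    write_genotype_table,
)

__all__ = [
    "ColonySimConfig",
    "TraitSimConfig",
    "default_locus_panel",
    "simulate_colony",
    "simulate_species_dataset",
    "simulate_traits",
    "simulate_comparative_dataset",
    "simulate_balanced_tree",
    "simulate_predictors",
]


def default_locus_panel(
    n_loci: int = 6, n_alleles: int = 8, rng: Optional[np.random.Generator] = None
) -> dict[str, dict[int, float]]:
    """A microsatellite panel with flat Dirichlet allele-frequency spectra.

    Allele codes mimic dinucleotide fragment lengths (100, 102, ...).
    With 8 near-equifrequent alleles per locus the probability that two
    fathers share a multilocus genotype is ~(1/8)^6 per pair, negligible.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    panel = {}
    for i in range(n_loci):
        freqs = rng.dirichlet(np.full(n_alleles, 5.0))
        alleles = [100 + 2 * j for j in range(n_alleles)]
        panel[f"L{i + 1}"] = dict(zip(alleles, freqs.tolist()))
    return panel


@dataclass
class ColonySimConfig:
    """Generative settings for one colony."""

    loci: dict[str, dict[int, float]]
    k_true: int = 3
    shares: Union[Sequence[float], float, None] = None  # vector, Dirichlet alpha, or even
    n_workers: int = 20
    missing_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        for locus, fmap in self.loci.items():
            total = sum(fmap.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {locus} sum to {total}, not 1")
        if isinstance(self.shares, Sequence):
            if len(self.shares) != self.k_true:
                raise ValueError("share vector length must equal k_true")
            if abs(sum(self.shares) - 1.0) > 1e-9:
                raise ValueError("shares must sum to 1")


def _draw_haploid(
    loci: dict[str, dict[int, float]], rng: np.random.Generator
) -> dict[str, int]:
    out = {}
    for locus, fmap in loci.items():
        alleles = list(fmap)
        probs = np.array([fmap[a] for a in alleles])
        out[locus] = int(rng.choice(alleles, p=probs / probs.sum()))
    return out


def simulate_colony(
    config: ColonySimConfig,
    colony_id: str = "C1",
    species: str = "synthetic",
    rng: Optional[np.random.Generator] = None,
    genotype_queen: bool = True,
) -> tuple[ColonyGenotypes, PatrilinePartition]:
    """Draw one colony and its true patriline partition.

    Draw order (stable across versions): queen's two haploid genomes, then
    each father's haploid genome, then the paternity share vector if
    Dirichlet, then per worker its father index, maternal allele choices and
    missingness mask.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    loci = config.loci
    queen_a = _draw_haploid(loci, rng)
    queen_b = _draw_haploid(loci, rng)
    fathers = [_draw_haploid(loci, rng) for _ in range(config.k_true)]

    if config.shares is None:
        shares = np.full(config.k_true, 1.0 / config.k_true)
    elif isinstance(config.shares, (int, float)):
        shares = rng.dirichlet(np.full(config.k_true, float(config.shares)))
    else:
        shares = np.asarray(config.shares, dtype=float)

    workers: list[tuple[str, Genotype]] = []
    father_of: dict[str, int] = {}
    width = len(str(config.n_workers))
    for w in range(config.n_workers):
        wid = f"{colony_id}-W{w + 1:0{width}d}"
        fidx = int(rng.choice(config.k_true, p=shares))
        father_of[wid] = fidx
        calls = {}
        for locus in loci:
            maternal = queen_a[locus] if rng.random() < 0.5 else queen_b[locus]
            pair = (maternal, fathers[fidx][locus])
            if config.missing_prob > 0 and rng.random() < config.missing_prob:
                pair = (None, None)
            calls[locus] = pair
        workers.append((wid, Genotype(calls)))

    queen_geno = Genotype({loc: (queen_a[loc], queen_b[loc]) for loc in loci})
    colony = ColonyGenotypes(
        colony_id=colony_id,
        species=species,
        workers=workers,
        queen=queen_geno if genotype_queen else None,
        queenright=genotype_queen,
    )
    # truth partition: only fathers with sampled offspring appear
    sampled = sorted({f for f in father_of.values()})
    members = [
        sorted(w for w, f in father_of.items() if f == fidx) for fidx in sampled
    ]
    haplos = [
        {loc: frozenset({fathers[fidx][loc]}) for loc in loci} for fidx in sampled
    ]
    truth = PatrilinePartition(
        colony_id=colony_id, members=members, haplotypes=haplos
    )
    return colony, truth


def simulate_species_dataset(
    species_configs: dict[str, tuple[ColonySimConfig, int]],
    seed: int = 0,
    genotype_table_path=None,
    truth_table_path=None,
) -> tuple[list[ColonyGenotypes], pd.DataFrame]:
    """Concatenated multi-species colony dataset with a truth table.

    ``species_configs`` maps species name to ``(config, n_colonies)``.  One
    seeded stream drives all colonies in species order, so the whole dataset
    is a pure function of (configs, seed).  Optionally writes the genotype
    table dialect read by ``patrilines.read_genotype_table`` and a
    tab-separated truth table (colony_id, individual_id, true_patriline).
    """
    rng = np.random.default_rng(seed)
    colonies: list[ColonyGenotypes] = []
    truth_rows = []
    for species in sorted(species_configs):
        cfg, n_colonies = species_configs[species]
        tag = species.replace(" ", "_")
        for c in range(n_colonies):
            cid = f"{tag}-{c + 1:02d}"
            colony, truth = simulate_colony(
                cfg, colony_id=cid, species=species, rng=rng
            )
            colonies.append(colony)
            for g, mem in enumerate(truth.members):
                for wid in mem:
                    truth_rows.append(
                        {
                            "colony_id": cid,
                            "individual_id": wid,
                            "true_patriline": g,
                        }
                    )
    truth_df = pd.DataFrame(
        truth_rows, columns=["colony_id", "individual_id", "true_patriline"]
    )
    if genotype_table_path is not None:
        write_genotype_table(colonies, genotype_table_path)
    if truth_table_path is not None:
        truth_df.to_csv(truth_table_path, sep="\t", index=False)
    return colonies, truth_df


# ---------------------------------------------------------------------------
# comparative-trait simulation


def simulate_balanced_tree(
    n_tips: int = 22, depth: float = 1.0, seed: int = 0
) -> Phylogeny:
    """Random ultrametric tree via seeded sequential coalescent-style joins.

    Tips are merged pairwise at increasing node heights drawn from a seeded
    stream, then depths are rescaled so every root-to-tip path equals
    ``depth`` — a lightweight stand-in for the rate-smoothed species tree.
    """
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"sp{i + 1:02d}" for i in range(n_tips)])
    nodes = []
    for taxon in taxa:
        leaf = dendropy.Node(taxon=taxon)
        leaf.height = 0.0
        nodes.append(leaf)
    height = 0.0
    while len(nodes) > 1:
        height += float(rng.exponential(1.0 / len(nodes)))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.height = height
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = height - child.height
        nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    scale = depth / root.height
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return Phylogeny(tree=tree)


def simulate_predictors(
    taxa: Sequence[str], seed: int = 0
) -> pd.DataFrame:
    """Colony-size and nest-site predictors with realistic spreads.

    Colony sizes are log-normal spanning roughly 10^2-10^4 workers, the range
    across vespine species; nest-site fractions are Beta(0.5, 0.5) draws,
    reflecting the bimodal (mostly-enclosed vs mostly-aerial) habit.
    """
    rng = np.random.default_rng(seed)
    n = len(taxa)
    size = 10 ** rng.normal(3.0, 0.6, size=n)
    nest = rng.beta(0.5, 0.5, size=n)
    return pd.DataFrame({"size": size, "nest_site": nest}, index=list(taxa))


def simulate_comparative_dataset(
    seed: int = 0,
    n_tips: int = 22,
    beta: Sequence[float] = (0.75, -0.09, -0.03),
    lambda_true: float = 0.5,
    sigma2: float = 0.004,
) -> tuple[pd.DataFrame, "Phylogeny"]:
    """A species trait table plus matching tree for comparative analyses.

    Intracolony relatedness is generated under the PGLS model
    ``r = b0 + b1 log10(size) + b2 nest_site + eps`` with lambda-scaled
    phylogenetic noise; paternity frequency follows from relatedness through
    ``r = 1/4 + 1/(2 k_e)``, and skew declines with paternity frequency, the
    qualitative pattern seen across social insects.  Columns: r, k, B,
    mean_size, max_size, nest_site.
    """
    phylo = simulate_balanced_tree(n_tips=n_tips, seed=seed)
    pred = simulate_predictors(phylo.taxa, seed=seed + 1)
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "logsize": np.log10(pred["size"]),
            "nest_site": pred["nest_site"],
        },
        index=pred.index,
    )
    reps = simulate_traits(
        TraitSimConfig(
            phylo=phylo, X=X, beta=list(beta), lambda_true=lambda_true,
            sigma2=sigma2, n_replicates=1, seed=seed + 2, response_name="r",
        )
    )
    traits = reps[0][["r"]].copy()
    traits["r"] = traits["r"].clip(0.26, 0.75)
    traits["k"] = (1.0 / (2.0 * (traits["r"] - 0.25))).clip(1.0, None)
    traits["B"] = (0.25 / traits["k"] - 0.02).clip(0.005, None)
    traits["mean_size"] = pred["size"]
    traits["max_size"] = pred["size"] * 3.0
    traits["nest_site"] = pred["nest_site"]
    traits.index.name = "species"
    return traits, phylo


@dataclass
class TraitSimConfig:
    """Generative settings for PGLS trait replicates."""

    phylo: Phylogeny
    X: pd.DataFrame  # design incl. intercept column, indexed by species
    beta: Sequence[float]
    lambda_true: float = 0.5
    sigma2: float = 1.0
    n_replicates: int = 1
    seed: int = 0
    response_name: str = "y"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must be in [0, 1]")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        if len(self.beta) != self.X.shape[1]:
            raise ValueError("beta length must match design columns")


def simulate_traits(config: TraitSimConfig) -> list[pd.DataFrame]:
    """Trait replicates under ``y = X beta + eps``, ``eps ~ MVN(0, s2 C_lam)``.

    Returns one trait DataFrame per replicate (columns: the response plus the
    non-intercept design columns), indexed by species and ready for
    :func:`vespine.comparative.build_design`.
    """
    taxa = list(config.X.index)
    C = phylo_vcv(config.phylo, taxa)
    V = lambda_transform(C, config.lambda_true) * config.sigma2
    X = config.X.to_numpy(dtype=float)
    mean = X @ np.asarray(config.beta, dtype=float)
    rng = np.random.default_rng(config.seed)
    if config.sigma2 == 0:
        draws = np.tile(mean, (config.n_replicates, 1))
    else:
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"trait covariance is not positive definite: {exc}"
            ) from exc
        z = rng.standard_normal((config.n_replicates, len(taxa)))
        draws = mean + z @ L.T
    out = []
    predictors = config.X.drop(
        columns=[c for c in config.X.columns if c == "intercept"]
    )
    for rep in range(config.n_replicates):
        df = predictors.copy()
        df.insert(0, config.response_name, draws[rep])
        out.append(df)
    return out
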