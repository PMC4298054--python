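"""Genotype I/O, queen inference and minimum-father partitioning."""

import numpy as np
import pytest

from vespine.patrilines import (
    ColonyStructureError,
    Genotype,
    GenotypeTableError,
    estimate_allele_frequencies,
    filter_workers,
    infer_queen_genotype,
    partition_patrilines,
    paternal_alleles,
    read_genotype_table,
    write_genotype_table,
)
from vespine.synthetic_data import ColonySimConfig, simulate_colony

from .conftest import random_colony_config
from .oracles import min_fathers_bruteforce


# ---------------------------------------------------------------------------
# table I/O


def _colony_key(col):
    return (
        col.colony_id,
        col.species,
        col.queen.calls if col.queen else None,
        [(wid, g.calls) for wid, g in col.workers],
    )


def test_genotype_table_round_trip(tmp_path, panel):
    cfg = ColonySimConfig(loci=panel, k_true=2, n_workers=4, missing_prob=0.2, seed=5)
    cols = [
        simulate_colony(cfg, colony_id=f"C{i}", species="sp", rng=rng, genotype_queen=(i == 1))[0]
        for i, rng in [(1, np.random.default_rng(1)), (2, np.random.default_rng(2))]
    ]
    path = tmp_path / "geno.csv"
    write_genotype_table(cols, path)
    back = read_genotype_table(path)
    assert len(back) == 2
    assert sorted(map(_colony_key, back)) == sorted(map(_colony_key, cols))
    # colony 2 was written without a queen row
    by_id = {c.colony_id: c for c in back}
    assert by_id["C2"].queen is None
    assert by_id["C1"].queen is not None


def test_blank_allele_reads_as_missing_locus(tmp_path):
    path = tmp_path / "g.csv"
    path.write_text(
        "colony_id,individual_id,role,L1_1,L1_2,L2_1,L2_2\n"
        "A,w1,worker,100,,200,202\n"
        "A,w2,worker,100,104,200,202\n"
    )
    (colony,) = read_genotype_table(path)
    assert colony.workers[0][1].is_missing("L1")
    assert not colony.workers[0][1].is_missing("L2")


def test_malformed_rows_raise_naming_problem(tmp_path):
    bad_allele = tmp_path / "bad.csv"
    bad_allele.write_text(
        "colony_id,individual_id,role,L1_1,L1_2\nA,w1,worker,abc,104\n"
    )
    with pytest.raises(GenotypeTableError, match="L1_1"):
        read_genotype_table(bad_allele)
    dup = tmp_path / "dup.csv"
    dup.write_text(
        "colony_id,individual_id,role,L1_1,L1_2\n"
        "A,w1,worker,100,104\nA,w1,worker,100,104\n"
    )
    with pytest.raises(GenotypeTableError, match="duplicate"):
        read_genotype_table(dup)


# ---------------------------------------------------------------------------
# filtering


@pytest.mark.parametrize(
    "n_missing,expected_excluded", [(3, True), (2, False), (0, False)]
)
def test_filter_workers_boundary(n_missing, expected_excluded):
    loci = [f"L{i}" for i in range(5)]
    calls = {
        loc: ((None, None) if i < n_missing else (100, 102))
        for i, loc in enumerate(loci)
    }
    from vespine.patrilines import ColonyGenotypes

    colony = ColonyGenotypes(
        colony_id="F",
        species="sp",
        workers=[("w1", Genotype(calls)), ("w2", Genotype({loc: (100, 102) for loc in loci}))],
    )
    kept, excluded = filter_workers(colony, max_failed_loci=2)
    assert (("w1", "amplification failure") in excluded) == expected_excluded
    assert [wid for wid, _ in kept.workers][-1] == "w2"  # order preserved


# ---------------------------------------------------------------------------
# queen inference


def test_genotyped_queen_is_echoed(toy_colony):
    inf = infer_queen_genotype(toy_colony)
    assert inf.from_genotyped_queen
    assert inf.genotype.calls == toy_colony.queen.calls
    assert inf.n_ambiguous == 0


def test_queen_inference_matches_exhaustive_enumeration(toy_colony):
    """On a toy colony the most-compatible candidate is unique per locus."""
    toy_colony.queen = None
    toy_colony.queenright = False
    inf = infer_queen_genotype(toy_colony)
    # independent check: enumerate all pairs at L1, count compatible workers
    observed = [100, 108, 104, 108, 100, 112, 104, 112]
    best = {}
    for a in set(observed):
        for b in set(observed):
            if a > b:
                continue
            score = sum(
                1
                for w, g in toy_colony.workers
                if {a, b} & set(g.alleles_at("L1"))
            )
            best.setdefault(score, []).append((a, b))
    top = best[max(best)]
    assert tuple(inf.genotype.calls["L1"]) in top
    # (100, 104) is compatible with all four workers and maximises frequency
    assert inf.genotype.calls["L1"] == (100, 104)


def test_queen_ambiguity_flag_when_two_candidates_tie():
    # every worker carries both queen alleles -> homozygous candidates tie too
    workers = [
        (f"w{i}", Genotype({"L1": (100, 104), "L2": (200, 210 + 2 * i)}))
        for i in range(6)
    ]
    from vespine.patrilines import ColonyGenotypes

    colony = ColonyGenotypes(colony_id="A", species="sp", workers=workers)
    inf = infer_queen_genotype(colony)
    assert inf.ambiguous["L1"]


def test_colony_structure_violation_detected():
    # two matrilines mixed: no single queen works at either locus
    from vespine.patrilines import ColonyGenotypes

    workers = [
        ("w1", Genotype({"L1": (100, 102), "L2": (200, 202)})),
        ("w2", Genotype({"L1": (104, 106), "L2": (204, 206)})),
        ("w3", Genotype({"L1": (108, 110), "L2": (208, 210)})),
    ]
    colony = ColonyGenotypes(colony_id="X", species="sp", workers=workers)
    with pytest.raises(ColonyStructureError):
        infer_queen_genotype(colony)


# ---------------------------------------------------------------------------
# paternal alleles


def test_paternal_allele_cases(toy_colony):
    queen = infer_queen_genotype(toy_colony)
    forced, _ = paternal_alleles(Genotype({"L1": (100, 108), "L2": (200, 202)}), queen)
    assert forced["L1"] == frozenset({108})
    assert forced["L2"] == frozenset({200, 202})  # both maternal -> ambiguous
    wild, _ = paternal_alleles(Genotype({"L1": (None, None), "L2": (200, 202)}), queen)
    assert wild["L1"] is None
    _, incompat = paternal_alleles(
        Genotype({"L1": (108, 112), "L2": (200, 202)}), queen
    )
    assert incompat == ["L1"]


# ---------------------------------------------------------------------------
# partitioning


def test_two_distinct_fathers_recovered(toy_colony):
    queen = infer_queen_genotype(toy_colony)
    part = partition_patrilines(toy_colony, queen)
    assert part.k == 2
    assert sorted(sorted(m) for m in part.members) == [["w1", "w2"], ["w3", "w4"]]
    assert part.provably_minimal


def test_identical_paternal_alleles_single_patriline(toy_colony):
    queen = infer_queen_genotype(toy_colony)
    toy_colony.workers = [
        (f"w{i}", Genotype({"L1": (100, 108), "L2": (200, 210)})) for i in range(5)
    ]
    part = partition_patrilines(toy_colony, queen)
    assert part.k == 1
    assert part.counts == [5]


def test_foreign_matriline_worker_excluded_single_mismatch_flagged(toy_colony):
    queen = infer_queen_genotype(toy_colony)
    toy_colony.workers = toy_colony.workers + [
        ("zz-foreign", Genotype({"L1": (130, 132), "L2": (230, 232)})),
        ("zz-mut", Genotype({"L1": (130, 132), "L2": (200, 210)})),
    ]
    part = partition_patrilines(toy_colony, queen)
    assert ("zz-foreign", "foreign matriline") in part.excluded_workers
    assert "zz-mut" in part.flagged_workers  # one mismatching locus: retained
    assert any("zz-mut" in m for m in part.members)


def test_partition_matches_bruteforce_minimum_on_random_colonies(panel):
    """Parsimony partition size equals the exhaustive-search minimum."""
    rng = np.random.default_rng(99)
    for _ in range(60):
        cfg = random_colony_config(rng, panel)
        colony, _ = simulate_colony(cfg, rng=np.random.default_rng(cfg.seed))
        queen = infer_queen_genotype(colony)
        psets = [paternal_alleles(g, queen)[0] for _, g in colony.workers]
        part = partition_patrilines(colony, queen)
        assert part.k == min_fathers_bruteforce(psets)


def test_partition_recovers_simulated_truth(panel):
    """With informative loci the partition equals the simulated memberships."""
    rng = np.random.default_rng(123)
    for seed in range(30):
        cfg = ColonySimConfig(
            loci=panel, k_true=3, shares=[0.5, 0.3, 0.2], n_workers=20, seed=seed
        )
        colony, truth = simulate_colony(cfg, genotype_queen=False)
        # only keep draws where fathers differ from each other and the queen
        haplos = [tuple(sorted(h.items())) for h in truth.haplotypes]
        if len(set(haplos)) < len(haplos):
            continue
        queen = infer_queen_genotype(colony)
        part = partition_patrilines(colony, queen)
        assert sorted(map(sorted, part.members)) == sorted(map(sorted, truth.members))


def test_dropping_a_locus_never_splits_patrilines(panel):
    """Partition size is non-increasing when loci are removed."""
    rng = np.random.default_rng(7)
    for seed in range(10):
        cfg = ColonySimConfig(loci=panel, k_true=3, n_workers=12, seed=seed)
        colony, _ = simulate_colony(cfg)
        queen = infer_queen_genotype(colony)
        k_full = partition_patrilines(colony, queen).k
        drop = colony.panel[0]
        for _, g in colony.workers:
            g.calls[drop] = (None, None)
        queen2 = infer_queen_genotype(colony)
        k_less = partition_patrilines(colony, queen2).k
        assert k_less <= k_full


# ---------------------------------------------------------------------------
# allele frequencies


def test_allele_frequencies_hand_count(toy_colony):
    """Queen (100/104) + fathers {108},{112}: four parental copies at L1."""
    queen = infer_queen_genotype(toy_colony)
    part = partition_patrilines(toy_colony, queen)
    freqs, het = estimate_allele_frequencies([(queen, part)])
    assert freqs["L1"] == {100: 0.25, 104: 0.25, 108: 0.25, 112: 0.25}
    assert het["L1"] == pytest.approx(0.75)


def test_heterozygosity_limits():
    from vespine.patrilines import PatrilinePartition, QueenInference

    queen = QueenInference(
        genotype=Genotype({"L1": (100, 100), "L2": (100, 102)}),
        ambiguous={"L1": False, "L2": False},
        from_genotyped_queen=True,
    )
    part = PatrilinePartition(colony_id="c", members=[], haplotypes=[])
    freqs, het = estimate_allele_frequencies([(queen, part)])
    assert het["L1"] == 0.0  # single allele
    assert het["L2"] == pytest.approx(0.5)  # two equifrequent alleles
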