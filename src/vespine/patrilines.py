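"""Patriline reconstruction from colony microsatellite genotypes.

Workers of a single-queen haplodiploid colony inherit one allele per locus
from their diploid mother and the other from a haploid father, so all members
of a patriline (offspring of one father) share a single paternal allele at
every locus.  Given multilocus genotypes of ~20 workers per colony (and the
queen where she was genotyped), this module

1. filters workers with excessive amplification failure,
2. infers the queen genotype from worker genotypes when she is unknown,
3. derives the candidate paternal allele set of each worker, and
4. partitions workers into the minimum number of patrilines consistent with
   haplodiploid inheritance (minimum-father parsimony), deterministically.

Allele codes are integers (microsatellite fragment lengths).  A locus with
any uncalled allele is treated as missing for that individual.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "Locus",
    "Genotype",
    "ColonyGenotypes",
    "QueenInference",
    "PatrilinePartition",
    "ColonyStructureError",
    "GenotypeTableError",
    "read_genotype_table",
    "write_genotype_table",
    "filter_workers",
    "infer_queen_genotype",
    "paternal_alleles",
    "partition_patrilines",
    "estimate_allele_frequencies",
    "write_partition_table",
]

MISSING: tuple[None, None] = (None, None)

# reasons recorded for excluded workers
REASON_AMPLIFICATION = "amplification failure"
REASON_FOREIGN = "foreign matriline"


class ColonyStructureError(ValueError):
    """Raised when worker genotypes are incompatible with a single queen."""


class GenotypeTableError(ValueError):
    """Raised on malformed genotype table input."""


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus: a label and the set of known allele codes."""

    name: str
    alleles: frozenset[int]

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError(f"locus {self.name!r} has an empty allele set")


@dataclass
class Genotype:
    """Per-locus unordered diploid genotype; (None, None) marks a missing locus."""

    calls: dict[str, tuple[Optional[int], Optional[int]]]

    def __post_init__(self) -> None:
        # normalise: unordered storage, any half-missing call -> fully missing
        norm = {}
        for locus, pair in self.calls.items():
            a, b = pair
            if a is None or b is None:
                norm[locus] = MISSING
            else:
                norm[locus] = (min(a, b), max(a, b))
        self.calls = norm

    def is_missing(self, locus: str) -> bool:
        return self.calls.get(locus, MISSING) == MISSING

    def alleles_at(self, locus: str) -> tuple[int, int]:
        pair = self.calls[locus]
        if pair == MISSING:
            raise KeyError(f"locus {locus} is missing")
        return pair  # type: ignore[return-value]

    @property
    def loci(self) -> list[str]:
        return list(self.calls)

    def n_missing(self) -> int:
        return sum(1 for p in self.calls.values() if p == MISSING)


@dataclass
class ColonyGenotypes:
    """All genotyped individuals of one colony."""

    colony_id: str
    species: str
    workers: list[tuple[str, Genotype]]
    queen: Optional[Genotype] = None
    queenright: bool = False

    def __post_init__(self) -> None:
        ids = [wid for wid, _ in self.workers]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise GenotypeTableError(
                f"colony {self.colony_id}: duplicate individual id(s) {dup}"
            )

    @property
    def panel(self) -> list[str]:
        if self.workers:
            return self.workers[0][1].loci
        if self.queen is not None:
            return self.queen.loci
        return []


@dataclass
class QueenInference:
    """Queen diploid genotype, observed or reconstructed from workers.

    ``candidates`` holds, per locus, the genotypes tied on worker
    compatibility (frequency-ranked, best first); loci with more than one
    candidate are flagged ambiguous and may be refined jointly against the
    patriline partition (see :func:`partition_patrilines`).
    """

    genotype: Genotype
    ambiguous: dict[str, bool]
    from_genotyped_queen: bool
    candidates: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def n_ambiguous(self) -> int:
        return sum(self.ambiguous.values())


@dataclass
class PatrilinePartition:
    """Workers assigned to patrilines with reconstructed paternal haplotypes.

    ``haplotypes[i]`` maps locus -> frozenset of paternal allele candidates
    (``None`` = fully unconstrained at that locus).
    """

    colony_id: str
    members: list[list[str]]
    haplotypes: list[dict[str, Optional[frozenset[int]]]]
    excluded_workers: list[tuple[str, str]] = field(default_factory=list)
    flagged_workers: dict[str, list[str]] = field(default_factory=dict)
    provably_minimal: bool = True

    @property
    def counts(self) -> list[int]:
        return [len(m) for m in self.members]

    @property
    def n(self) -> int:
        return sum(self.counts)

    @property
    def k(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# genotype table I/O

_ROLES = {"queen", "worker", "gyne"}
_META_COLS = ("colony_id", "individual_id", "role")


def _panel_from_header(columns: Sequence[str]) -> list[str]:
    loci: list[str] = []
    rest = [c for c in columns if c not in _META_COLS and c != "species"]
    for col in rest:
        if col.endswith("_1"):
            name = col[:-2]
            if f"{name}_2" not in rest:
                raise GenotypeTableError(f"column {col} has no matching {name}_2")
            loci.append(name)
        elif not col.endswith("_2"):
            raise GenotypeTableError(f"unrecognised column {col!r}")
    if not loci:
        raise GenotypeTableError("no locus columns found in header")
    return loci


def _parse_allele(value, column: str, line: int) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return int(value)
    except (TypeError, ValueError):
        raise GenotypeTableError(
            f"line {line}: allele {value!r} in column {column} is not an integer"
        ) from None


def read_genotype_table(
    path, panel: Optional[Sequence[Locus]] = None
) -> list[ColonyGenotypes]:
    """Read a delimited genotype table into one ``ColonyGenotypes`` per colony.

    Expected columns: ``colony_id, individual_id, role`` (queen/worker/gyne),
    optionally ``species``, then ``<locus>_1, <locus>_2`` integer pairs; an
    empty cell marks a missing allele.  Comma or tab delimited; ``#`` lines
    are comments.  Gynes (unmated reproductive females) are offspring of the
    queen like workers and are treated as such downstream.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#", dtype=str)
    df.columns = [c.strip() for c in df.columns]
    for col in _META_COLS:
        if col not in df.columns:
            raise GenotypeTableError(f"missing required column {col!r}")
    locus_names = _panel_from_header(df.columns)
    if panel is not None:
        supplied = [loc.name for loc in panel]
        if set(supplied) != set(locus_names):
            raise GenotypeTableError(
                f"supplied panel {supplied} does not match header loci {locus_names}"
            )
        locus_names = supplied

    colonies: dict[str, dict] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        cid = row["colony_id"]
        role = str(row["role"]).strip().lower()
        if pd.isna(cid) or role not in _ROLES:
            raise GenotypeTableError(
                f"line {line}: role {row['role']!r} not in {sorted(_ROLES)}"
            )
        cid = str(cid).strip()
        calls = {}
        for locus in locus_names:
            a = _parse_allele(row.get(f"{locus}_1"), f"{locus}_1", line)
            b = _parse_allele(row.get(f"{locus}_2"), f"{locus}_2", line)
            calls[locus] = (a, b)
        geno = Genotype(calls)
        entry = colonies.setdefault(
            cid,
            {
                "species": str(row.get("species", "")).strip() or "unknown",
                "queen": None,
                "workers": [],
            },
        )
        if role == "queen":
            if entry["queen"] is not None:
                raise GenotypeTableError(f"line {line}: second queen in colony {cid}")
            entry["queen"] = geno
        else:
            entry["workers"].append((str(row["individual_id"]).strip(), geno))

    out = []
    for cid, entry in colonies.items():
        if not entry["workers"]:
            raise GenotypeTableError(f"colony {cid}: no worker rows")
        out.append(
            ColonyGenotypes(
                colony_id=cid,
                species=entry["species"],
                workers=entry["workers"],
                queen=entry["queen"],
                queenright=entry["queen"] is not None,
            )
        )
    return out


def write_genotype_table(colonies: Iterable[ColonyGenotypes], path, sep=",") -> None:
    """Write colonies in the dialect that :func:`read_genotype_table` reads."""
    rows = []
    for col in colonies:
        panel = col.panel
        def _row(ind_id, role, geno):
            rec = {
                "colony_id": col.colony_id,
                "individual_id": ind_id,
                "role": role,
                "species": col.species,
            }
            for locus in panel:
                a, b = geno.calls[locus]
                rec[f"{locus}_1"] = "" if a is None else a
                rec[f"{locus}_2"] = "" if b is None else b
            return rec

        if col.queen is not None:
            rows.append(_row(f"{col.colony_id}-Q", "queen", col.queen))
        for wid, geno in col.workers:
            rows.append(_row(wid, "worker", geno))
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# filtering and queen inference


def filter_workers(
    colony: ColonyGenotypes, max_failed_loci: int = 2
) -> tuple[ColonyGenotypes, list[tuple[str, str]]]:
    """Drop workers that failed to amplify at more than ``max_failed_loci`` loci.

    Returns the retained colony (worker order preserved) and the exclusion
    list of ``(individual_id, reason)`` pairs.
    """
    retained, excluded = [], []
    for wid, geno in colony.workers:
        if geno.n_missing() > max_failed_loci:
            excluded.append((wid, REASON_AMPLIFICATION))
        else:
            retained.append((wid, geno))
    kept = ColonyGenotypes(
        colony_id=colony.colony_id,
        species=colony.species,
        workers=retained,
        queen=colony.queen,
        queenright=colony.queenright,
    )
    return kept, excluded


def _candidate_pairs(alleles: Sequence[int]) -> list[tuple[int, int]]:
    """All unordered diploid genotypes (incl. homozygotes) over ``alleles``."""
    uniq = sorted(set(alleles))
    return [(a, b) for i, a in enumerate(uniq) for b in uniq[i:]]




def infer_queen_genotype(
    colony: ColonyGenotypes,
    allele_frequencies: Optional[Mapping[str, Mapping[int, float]]] = None,
) -> QueenInference:
    """Infer the queen's diploid genotype from worker genotypes.

    If the queen was genotyped her genotype is echoed unchanged.  Otherwise,
    per locus, every diploid genotype over observed worker alleles is scored
    by the number of compatible workers (a worker is compatible if it carries
    at least one candidate allele or is missing at the locus); candidates
    compatible with the maximum number of workers are retained.  Ties are
    broken by the product of population allele frequencies (observed worker
    allele frequencies when none are supplied), then numeric order, and the
    locus is flagged ambiguous.

    Raises :class:`ColonyStructureError` when at two or more loci no single
    candidate is compatible with every worker — the signature of a
    multi-queen or mixed colony.
    """
    if len(colony.workers) < 2:
        raise ValueError("queen inference requires at least 2 workers")
    panel = colony.panel
    if colony.queen is not None:
        return QueenInference(
            genotype=colony.queen,
            ambiguous={locus: False for locus in panel},
            from_genotyped_queen=True,
        )

    calls: dict[str, tuple[Optional[int], Optional[int]]] = {}
    ambiguous: dict[str, bool] = {}
    cand_lists: dict[str, list[tuple[int, int]]] = {}
    violated_loci = 0
    for locus in panel:
        observed: list[int] = []
        present_workers = []
        for _, geno in colony.workers:
            if not geno.is_missing(locus):
                observed.extend(geno.alleles_at(locus))
                present_workers.append(geno)
        if not observed:
            calls[locus] = MISSING
            ambiguous[locus] = False
            cand_lists[locus] = []
            continue
        if allele_frequencies and locus in allele_frequencies:
            freqs = allele_frequencies[locus]
        else:
            freqs = {a: observed.count(a) / len(observed) for a in set(observed)}
        best_score = -1
        best: list[tuple[int, int]] = []
        for cand in _candidate_pairs(observed):
            cset = set(cand)
            score = sum(
                1
                for geno in present_workers
                if cset & set(geno.alleles_at(locus))
            )
            if score > best_score:
                best_score, best = score, [cand]
            elif score == best_score:
                best.append(cand)
        if best_score < len(present_workers):
            violated_loci += 1
        ambiguous[locus] = len(best) > 1
        best.sort(
            key=lambda c: (-(freqs.get(c[0], 0.0) * freqs.get(c[1], 0.0)), c)
        )
        calls[locus] = best[0]
        cand_lists[locus] = best
    if violated_loci >= 2:
        raise ColonyStructureError(
            f"colony {colony.colony_id}: no queen genotype compatible with all "
            f"workers at {violated_loci} loci (possible multi-queen or mixed colony)"
        )
    return QueenInference(
        genotype=Genotype(calls),
        ambiguous=ambiguous,
        from_genotyped_queen=False,
        candidates=cand_lists,
    )


# ---------------------------------------------------------------------------
# paternal allele deduction and minimum-father partitioning


def paternal_alleles(
    worker: Genotype, queen: QueenInference
) -> tuple[dict[str, Optional[frozenset[int]]], list[str]]:
    """Per-locus candidate paternal alleles of a worker.

    A worker inherits one maternal and one paternal allele per locus.  If
    exactly one worker allele is non-maternal it must be paternal; if both are
    maternal either could be; a missing locus (worker or queen) is a wildcard
    (``None``).  Loci where neither worker allele is maternal are returned in
    the incompatibility list.
    """
    sets: dict[str, Optional[frozenset[int]]] = {}
    incompatible: list[str] = []
    for locus in worker.loci:
        if worker.is_missing(locus) or queen.genotype.is_missing(locus):
            sets[locus] = None
            continue
        w = worker.alleles_at(locus)
        q = set(queen.genotype.alleles_at(locus))
        maternal = [a in q for a in w]
        if not any(maternal):
            incompatible.append(locus)
            sets[locus] = None
        elif all(maternal):
            sets[locus] = frozenset(w)
        else:
            sets[locus] = frozenset(a for a, m in zip(w, maternal) if not m)
    return sets, incompatible


def _intersect(
    group: dict[str, Optional[frozenset[int]]],
    pat: dict[str, Optional[frozenset[int]]],
) -> Optional[dict[str, Optional[frozenset[int]]]]:
    """Intersect two per-locus ambiguity-set maps; None = universal set."""
    out: dict[str, Optional[frozenset[int]]] = {}
    for locus in group:
        a, b = group[locus], pat[locus]
        if a is None:
            out[locus] = b
        elif b is None:
            out[locus] = a
        else:
            inter = a & b
            if not inter:
                return None
            out[locus] = inter
    return out


def _dfs_exact(psets: list[dict], limit: int) -> Optional[list[int]]:
    """First assignment (workers in given order) using at most ``limit`` fathers.

    Trying existing groups in creation order before opening a new one makes
    the first solution found the lexicographically smallest assignment
    sequence, hence deterministic.
    """
    n = len(psets)
    assignment = [0] * n
    groups: list[dict] = []

    def rec(i: int) -> bool:
        if i == n:
            return True
        for g in range(len(groups)):
            merged = _intersect(groups[g], psets[i])
            if merged is not None:
                saved = groups[g]
                groups[g] = merged
                assignment[i] = g
                if rec(i + 1):
                    return True
                groups[g] = saved
        if len(groups) < limit:
            groups.append(dict(psets[i]))
            assignment[i] = len(groups) - 1
            if rec(i + 1):
                return True
            groups.pop()
        return False

    return assignment if rec(0) else None


def _greedy(psets: list[dict]) -> list[int]:
    """First-fit assignment followed by pairwise group-merge refinement."""
    groups: list[dict] = []
    assignment: list[int] = []
    for pat in psets:
        for g, grp in enumerate(groups):
            merged = _intersect(grp, pat)
            if merged is not None:
                groups[g] = merged
                assignment.append(g)
                break
        else:
            groups.append(dict(pat))
            assignment.append(len(groups) - 1)
    # pairwise merges until a fixed point
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(len(groups)), 2):
            merged = _intersect(groups[i], groups[j])
            if merged is not None:
                groups[i] = merged
                del groups[j]
                assignment = [
                    i if a == j else (a - 1 if a > j else a) for a in assignment
                ]
                changed = True
                break
    return assignment


EXACT_SEARCH_MAX_WORKERS = 25


def _partition_given_queen(
    colony: ColonyGenotypes, queen: QueenInference
) -> PatrilinePartition:
    workers = sorted(colony.workers, key=lambda item: item[0])
    excluded: list[tuple[str, str]] = []
    flagged: dict[str, list[str]] = {}
    ids: list[str] = []
    psets: list[dict] = []
    for wid, geno in workers:
        sets, incompat = paternal_alleles(geno, queen)
        if len(incompat) >= 2:
            excluded.append((wid, REASON_FOREIGN))
            continue
        if len(incompat) == 1:
            flagged[wid] = incompat
        ids.append(wid)
        psets.append(sets)

    if not psets:
        return PatrilinePartition(
            colony_id=colony.colony_id,
            members=[],
            haplotypes=[],
            excluded_workers=excluded,
            flagged_workers=flagged,
        )

    if len(psets) <= EXACT_SEARCH_MAX_WORKERS:
        upper = max(_greedy(psets)) + 1
        assignment = None
        for limit in range(1, upper + 1):
            assignment = _dfs_exact(psets, limit)
            if assignment is not None:
                break
        assert assignment is not None
        minimal = True
    else:
        assignment = _greedy(psets)
        minimal = max(assignment) + 1 == 1

    k = max(assignment) + 1
    members: list[list[str]] = [[] for _ in range(k)]
    haplos: list[dict] = [dict.fromkeys(psets[0], None) for _ in range(k)]
    for wid, pat, g in zip(ids, psets, assignment):
        members[g].append(wid)
        merged = _intersect(haplos[g], pat)
        assert merged is not None
        haplos[g] = merged
    return PatrilinePartition(
        colony_id=colony.colony_id,
        members=members,
        haplotypes=haplos,
        excluded_workers=excluded,
        flagged_workers=flagged,
        provably_minimal=minimal,
    )


MAX_REFINE_CANDIDATES = 15


def partition_patrilines(
    colony: ColonyGenotypes, queen: QueenInference
) -> PatrilinePartition:
    """Partition workers into the minimum number of patrilines.

    Workers maternally incompatible at two or more loci are excluded as
    foreign-matriline intruders; a single mismatching locus (possible
    mutation, null allele or scoring error) is treated as missing for that
    worker, which is flagged but retained.  The partition minimises the
    number of fathers such that each patriline's per-locus paternal
    candidate sets intersect; among minimal solutions the lexicographically
    first by sorted worker id is returned.  Exact branch-and-bound search is
    used up to 25 workers; above that a greedy-plus-merge heuristic is used
    and ``provably_minimal`` is set accordingly.

    When the queen was reconstructed and some loci have several equally
    compatible genotypes, those loci are refined jointly against the
    partition itself: per ambiguous locus the candidate yielding the fewest
    fathers (then fewest exclusions and flags, then the frequency ranking)
    is kept, by deterministic coordinate descent.  Per-locus worker
    compatibility alone cannot separate such candidates — a wrong choice
    reads maternal alleles as paternal and splinters true patrilines — so
    the queen genotype and the sibship structure are inferred jointly, as in
    likelihood-based sibship reconstruction.  ``queen`` is updated in place
    with the refined genotype.
    """
    amb_loci = [
        locus
        for locus, cands in queen.candidates.items()
        if 1 < len(cands) <= MAX_REFINE_CANDIDATES
    ]
    if queen.from_genotyped_queen or not amb_loci:
        return _partition_given_queen(colony, queen)

    choices = dict(queen.genotype.calls)

    def cost(calls: dict) -> tuple[int, int, int]:
        trial = QueenInference(
            genotype=Genotype(dict(calls)),
            ambiguous=queen.ambiguous,
            from_genotyped_queen=False,
        )
        part = _partition_given_queen(colony, trial)
        return (part.k, len(part.excluded_workers), len(part.flagged_workers))

    for _ in range(2):  # two coordinate passes reach a fixed point in practice
        changed = False
        for locus in amb_loci:
            scored = []
            for rank, cand in enumerate(queen.candidates[locus]):
                trial_calls = dict(choices)
                trial_calls[locus] = cand
                scored.append((cost(trial_calls), rank, cand))
            scored.sort(key=lambda item: (item[0], item[1]))
            winner = scored[0][2]
            if choices[locus] != tuple(sorted(winner)):
                choices[locus] = winner
                changed = True
        if not changed:
            break
    queen.genotype = Genotype(choices)
    return _partition_given_queen(colony, queen)


# ---------------------------------------------------------------------------
# allele frequencies from inferred parental genomes


def estimate_allele_frequencies(
    parents: Iterable[tuple[QueenInference, PatrilinePartition]],
) -> tuple[dict[str, dict[int, float]], dict[str, float]]:
    """Per-locus allele frequencies and expected heterozygosity from parents.

    Each queen contributes two allele copies per locus and each patriline's
    father one; paternal loci still ambiguous (candidate set size != 1) and
    missing queen loci are skipped.  Returns ``(frequencies, H)`` where
    ``H = 1 - sum(f**2)`` per locus.  Loci with no parental observations are
    omitted.
    """
    counts: dict[str, dict[int, int]] = {}
    for queen, part in parents:
        for locus in queen.genotype.loci:
            if queen.genotype.is_missing(locus):
                continue
            bucket = counts.setdefault(locus, {})
            for a in queen.genotype.alleles_at(locus):
                bucket[a] = bucket.get(a, 0) + 1
        for haplo in part.haplotypes:
            for locus, aset in haplo.items():
                if aset is not None and len(aset) == 1:
                    (a,) = aset
                    bucket = counts.setdefault(locus, {})
                    bucket[a] = bucket.get(a, 0) + 1
    freqs: dict[str, dict[int, float]] = {}
    het: dict[str, float] = {}
    for locus, bucket in counts.items():
        total = sum(bucket.values())
        freqs[locus] = {a: c / total for a, c in sorted(bucket.items())}
        het[locus] = 1.0 - sum(f * f for f in freqs[locus].values())
    return freqs, het


def write_partition_table(partitions: Iterable[PatrilinePartition], path) -> None:
    """Long-format patriline assignment table (tab-separated)."""
    rows = []
    for part in partitions:
        for g, mem in enumerate(part.members):
            for wid in mem:
                rows.append(
                    {
                        "colony_id": part.colony_id,
                        "individual_id": wid,
                        "patriline_index": g,
                        "excluded_reason": "",
                    }
                )
        for wid, reason in part.excluded_workers:
            rows.append(
                {
                    "colony_id": part.colony_id,
                    "individual_id": wid,
                    "patriline_index": -1,
                    "excluded_reason": reason,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
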