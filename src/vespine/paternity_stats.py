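"""Colony- and species-level paternity statistics with error corrections.

Given patriline counts ``n_i`` for a colony of ``n = sum(n_i)`` sampled
offspring with paternity proportions ``p_i = n_i / n``:

* observed paternity ``k`` — number of detected patrilines,
* effective paternity ``k_e = 1 / sum(p_i**2)`` — the number of equally
  contributing fathers giving the same genetic diversity,
* sample-size-corrected effective paternity
  ``k_e3 = (n-1)**2 / ((sum p_i**2)(n+1)(n-2) + 3 - n)``,
* intracolony relatedness ``r = 1/4 + 1/(2 k_e3)`` for a singly mated,
  singly queened haplodiploid colony,
* paternity skew ``B = sum((p_i - 1/k)**2) - (1 - 1/k)/n`` — deviation of
  shares from evenness minus the sampling variance expected under equal
  contributions, so E[B] = 0 under even sperm use (B may be negative).

Two sampling corrections: the non-detection error is the probability two
fathers share a multilocus genotype (product over loci of the probability of
identity of haploid males, ``sum_a f_a**2``); the non-sampling correction
inverts ``E[k_obs | k, n] = k (1 - (1 - 1/k)**n)`` to recover the expected
true father number from the observed one under zero skew.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ColonyPaternity",
    "SpeciesPaternitySummary",
    "effective_paternity",
    "corrected_effective_paternity",
    "relatedness",
    "skew_B",
    "nondetection_error",
    "expected_true_paternity",
    "expected_observed_paternity",
    "colony_paternity",
    "species_summary",
    "species_table",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def _validate_counts(counts: Sequence[int]) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError("counts must be non-empty")
    if np.any(arr < 1) or np.any(arr != np.round(arr)):
        raise ValueError("counts must be positive integers")
    return arr


def effective_paternity(counts: Sequence[int]) -> float:
    """Effective paternity k_e = 1 / sum(p_i^2), uncorrected."""
    arr = _validate_counts(counts)
    p = arr / arr.sum()
    return float(1.0 / np.sum(p * p))


def corrected_effective_paternity(counts: Sequence[int]) -> float:
    """Sample-size-corrected effective paternity k_e3 (requires n >= 3).

    k_e3 = (n-1)^2 / [ (sum p_i^2)(n+1)(n-2) + 3 - n ]; equals 1 exactly for
    a single-father colony and converges to k_e as n grows.
    """
    arr = _validate_counts(counts)
    n = arr.sum()
    if n < 3:
        raise ValueError(f"k_e3 requires n >= 3 offspring, got n={int(n)}")
    p = arr / n
    denom = np.sum(p * p) * (n + 1) * (n - 2) + 3 - n
    if denom <= 0:
        raise ValueError(
            f"k_e3 denominator nonpositive ({denom:.6g}) for counts {list(counts)}"
        )
    return float((n - 1) ** 2 / denom)


def relatedness(k_e3: float) -> float:
    """Intracolony worker-worker relatedness r = 1/4 + 1/(2 k_e3)."""
    if k_e3 < 1:
        raise ValueError(f"k_e3 must be >= 1, got {k_e3}")
    return 0.25 + 1.0 / (2.0 * k_e3)


def skew_B(counts: Sequence[int]) -> Optional[float]:
    """Nonacs B skew index; ``None`` for single-paternity colonies (k < 2)."""
    arr = _validate_counts(counts)
    k = arr.size
    if k < 2:
        return None
    n = arr.sum()
    p = arr / n
    return float(np.sum((p - 1.0 / k) ** 2) - (1.0 - 1.0 / k) / n)


def nondetection_error(
    freqs: Mapping[str, Mapping[int, float]],
    problematic_loci: Optional[Sequence[str]] = None,
    drop_most_variable: int = 0,
) -> float:
    """Probability that two fathers share the same multilocus genotype.

    For haploid males the per-locus probability of identity is
    ``sum_a f_a**2``; independence across loci gives the product.  The
    conservative upper-bound variant removes the ``drop_most_variable`` most
    variable loci (lowest ``sum f**2``) among ``problematic_loci`` — the loci
    whose queen genotypes were ambiguous — before taking the product.
    """
    per_locus: dict[str, float] = {}
    for locus, fmap in freqs.items():
        total = sum(fmap.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"allele frequencies at locus {locus} sum to {total:.12g}, not 1"
            )
        per_locus[locus] = sum(f * f for f in fmap.values())
    dropped: set[str] = set()
    if drop_most_variable:
        pool = list(problematic_loci) if problematic_loci else []
        if len(pool) < drop_most_variable:
            raise ValueError(
                "fewer problematic loci supplied than requested to drop"
            )
        pool.sort(key=lambda loc: (per_locus[loc], loc))
        dropped = set(pool[:drop_most_variable])
    prob = 1.0
    for locus, pid in per_locus.items():
        if locus not in dropped:
            prob *= pid
    return prob


def expected_observed_paternity(k: float, n: int) -> float:
    """Forward map: expected number of detected patrilines among n offspring
    from k equally used fathers, E[k_obs] = k (1 - (1 - 1/k)^n)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return k * (1.0 - (1.0 - 1.0 / k) ** n)


def expected_true_paternity(k_obs: float, n: int, tol: float = 1e-8) -> float:
    """Expected true paternity given observed paternity, assuming no skew.

    Inverts ``E[k_obs | k, n] = k (1 - (1 - 1/k)**n)`` by bisection.  The
    forward map is increasing in k with supremum n, so ``k_obs = n`` is
    unidentifiable and returns ``inf``.
    """
    if not 1 <= k_obs <= n:
        raise ValueError(f"need 1 <= k_obs <= n, got k_obs={k_obs}, n={n}")
    if k_obs == 1:
        return 1.0
    if k_obs == n:
        return math.inf
    lo, hi = float(k_obs), float(k_obs)
    while expected_observed_paternity(hi, n) < k_obs:
        hi *= 2.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if expected_observed_paternity(mid, n) < k_obs:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# per-colony and per-species aggregation


@dataclass
class ColonyPaternity:
    """All paternity statistics for one colony."""

    colony_id: str
    species: str
    counts: list[int]
    n: int
    k: int
    k_e: float
    k_e3: float
    r: float
    B: Optional[float]
    k_true_expected: float

    @property
    def p(self) -> list[float]:
        return [c / self.n for c in self.counts]


def colony_paternity(
    colony_id: str, species: str, counts: Sequence[int]
) -> ColonyPaternity:
    """Compute the full statistic set from one colony's patriline counts."""
    arr = _validate_counts(counts)
    n = int(arr.sum())
    k_e = effective_paternity(counts)
    k_e3 = corrected_effective_paternity(counts)
    return ColonyPaternity(
        colony_id=colony_id,
        species=species,
        counts=[int(c) for c in counts],
        n=n,
        k=len(counts),
        k_e=k_e,
        k_e3=k_e3,
        r=relatedness(k_e3),
        B=skew_B(counts),
        k_true_expected=expected_true_paternity(len(counts), n),
    )


@dataclass
class SpeciesPaternitySummary:
    species: str
    n_colonies: int
    n_workers_mean: float
    n_workers_range: tuple[int, int]
    k_mean: float
    k_ci: tuple[float, float]
    k_e_harmonic: float
    k_e_ci: tuple[float, float]
    k_e3_harmonic: float
    k_e3_ci: tuple[float, float]
    r_mean: float
    B_mean: Optional[float]
    n_multiple_paternity: int
    k_true_mean: float
    nondetection: Optional[float] = None
    nondetection_upper: Optional[float] = None


def _mean_ci(values: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Arithmetic mean with a normal-approximation 95% CI (+/- 1.96 SE)."""
    mean = float(values.mean())
    if values.size < 2:
        return mean, (math.nan, math.nan)
    se = float(values.std(ddof=1) / math.sqrt(values.size))
    return mean, (mean - Z95 * se, mean + Z95 * se)


def _harmonic_ci(values: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Harmonic mean with a CI from inverting the normal CI of reciprocals."""
    recip = 1.0 / values
    m, (lo, hi) = _mean_ci(recip)
    harm = 1.0 / m
    if math.isnan(lo):
        return harm, (math.nan, math.nan)
    # reciprocal-scale upper bound maps to the harmonic-scale lower bound
    return harm, (1.0 / hi, 1.0 / lo)


def species_summary(
    colonies: Sequence[ColonyPaternity],
    nondetection: Optional[float] = None,
    nondetection_upper: Optional[float] = None,
) -> SpeciesPaternitySummary:
    """Aggregate colony statistics into a species summary.

    Observed paternity k is summarised by an arithmetic mean with a normal
    95% CI; k_e and k_e3 by harmonic means whose CIs are the inverted normal
    CIs of the mean reciprocal; skew B is averaged over multiple-paternity
    colonies only.
    """
    if not colonies:
        raise ValueError("need at least one colony")
    species = colonies[0].species
    ns = np.array([c.n for c in colonies], dtype=float)
    ks = np.array([c.k for c in colonies], dtype=float)
    k_mean, k_ci = _mean_ci(ks)
    k_e_h, k_e_ci = _harmonic_ci(np.array([c.k_e for c in colonies]))
    k_e3_h, k_e3_ci = _harmonic_ci(np.array([c.k_e3 for c in colonies]))
    bs = [c.B for c in colonies if c.B is not None]
    finite_ktrue = [c.k_true_expected for c in colonies if math.isfinite(c.k_true_expected)]
    return SpeciesPaternitySummary(
        species=species,
        n_colonies=len(colonies),
        n_workers_mean=float(ns.mean()),
        n_workers_range=(int(ns.min()), int(ns.max())),
        k_mean=k_mean,
        k_ci=k_ci,
        k_e_harmonic=k_e_h,
        k_e_ci=k_e_ci,
        k_e3_harmonic=k_e3_h,
        k_e3_ci=k_e3_ci,
        r_mean=relatedness(k_e3_h),
        B_mean=float(np.mean(bs)) if bs else None,
        n_multiple_paternity=len(bs),
        k_true_mean=float(np.mean(finite_ktrue)) if finite_ktrue else math.nan,
        nondetection=nondetection,
        nondetection_upper=nondetection_upper,
    )


def species_table(summaries: Iterable[SpeciesPaternitySummary]) -> pd.DataFrame:
    """Species summaries as a tidy table (one row per species)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "species": s.species,
                "n_c": s.n_colonies,
                "n_w_mean": s.n_workers_mean,
                "n_w_min": s.n_workers_range[0],
                "n_w_max": s.n_workers_range[1],
                "k_mean": s.k_mean,
                "k_ci_lo": s.k_ci[0],
                "k_ci_hi": s.k_ci[1],
                "k_e": s.k_e_harmonic,
                "k_e_ci_lo": s.k_e_ci[0],
                "k_e_ci_hi": s.k_e_ci[1],
                "k_e3": s.k_e3_harmonic,
                "k_e3_ci_lo": s.k_e3_ci[0],
                "k_e3_ci_hi": s.k_e3_ci[1],
                "r": s.r_mean,
                "B_mean": s.B_mean,
                "n_multi": s.n_multiple_paternity,
                "k_true_expected": s.k_true_mean,
                "nondetection": s.nondetection,
                "nondetection_upper": s.nondetection_upper,
            }
        )
    return pd.DataFrame(rows)
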