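"""Ratiometric feature transform and ratio-combination selection.

Raw input for one hand placement is ten finger-pair magnitude spectra on a
25-point frequency grid (250 values).  The ratiometric transform divides
one pair's spectrum element-wise by another pair's spectrum from the same
placement at the same frequency; any multiplicative factor common to all
pairs — session drift, temperature — cancels exactly.

Ten of the 45 possible pair-over-pair combinations are used, constrained
so that every pair appears exactly once as a numerator and exactly once as
a denominator.  The denominator assignment is therefore a fixed-point-free
permutation (derangement) of the ten pairs.  A consequence worth knowing:
the product of the ten ratio features at any fixed frequency telescopes
to 1, so the mean log-feature across combinations is always 0.

`select_combinations` chooses the derangement that balances feature
scales: writing ``M_p`` for the training-set mean of ``log |Z_p(f)|`` of
pair ``p``, it minimises ``sum_p (M_p - M_sigma(p))^2`` — the squared
log-scale of each ratio feature about the (zero) derangement mean.  This
is a linear assignment problem with the diagonal forbidden and is solved
exactly; ties are broken toward the lexicographically smallest assignment
list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cohort import ALL_PAIRS, FingerPair, MeasurementRecord, SpectraDataset

__all__ = [
    "RatioCombinationSet",
    "FeatureVector",
    "published_combination",
    "ratiometric_transform",
    "raw_features",
    "select_combinations",
    "select_combinations_from_means",
    "balanced_derangement",
]


@dataclass(frozen=True)
class RatioCombinationSet:
    """Ten (numerator, denominator) finger-pair assignments.

    Valid sets are derangements: each pair appears exactly once on each
    side and never divides by itself.
    """

    assignments: tuple[tuple[FingerPair, FingerPair], ...]

    def __post_init__(self) -> None:
        nums = [a for a, _ in self.assignments]
        dens = [b for _, b in self.assignments]
        if sorted(nums) != sorted(set(nums)) or set(nums) != set(ALL_PAIRS):
            raise ValueError("each pair must appear exactly once as numerator")
        if set(dens) != set(ALL_PAIRS) or len(dens) != len(set(dens)):
            raise ValueError("each pair must appear exactly once as denominator")
        if any(a == b for a, b in self.assignments):
            raise ValueError("numerator and denominator must differ (derangement)")

    def __len__(self) -> int:
        return len(self.assignments)

    def permutation(self) -> dict[FingerPair, FingerPair]:
        """numerator -> denominator map."""
        return dict(self.assignments)

    def cycle_lengths(self) -> tuple[int, ...]:
        """Lengths of the cycles of the numerator -> denominator permutation."""
        perm = self.permutation()
        seen: set[FingerPair] = set()
        lengths = []
        for start in ALL_PAIRS:
            if start in seen:
                continue
            n, p = 0, start
            while p not in seen:
                seen.add(p)
                p = perm[p]
                n += 1
            lengths.append(n)
        return tuple(sorted(lengths, reverse=True))


def published_combination() -> RatioCombinationSet:
    """The fixed ten-ratio set used for identification, in its printed order.

    (1,2)/(4,5), (1,3)/(1,2), (1,5)/(1,3), (1,4)/(1,5), (2,3)/(1,4),
    (2,5)/(2,3), (2,4)/(2,5), (3,5)/(2,4), (3,4)/(3,5), (4,5)/(3,4).
    """
    raw = [
        ((1, 2), (4, 5)),
        ((1, 3), (1, 2)),
        ((1, 5), (1, 3)),
        ((1, 4), (1, 5)),
        ((2, 3), (1, 4)),
        ((2, 5), (2, 3)),
        ((2, 4), (2, 5)),
        ((3, 5), (2, 4)),
        ((3, 4), (3, 5)),
        ((4, 5), (3, 4)),
    ]
    return RatioCombinationSet(
        tuple((FingerPair(*n), FingerPair(*d)) for n, d in raw)
    )


@dataclass(frozen=True)
class FeatureVector:
    """A 250-element feature vector, either raw magnitudes or ratios."""

    values: tuple[float, ...]
    kind: str  # "raw" | "ratiometric"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if self.kind not in ("raw", "ratiometric"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must be finite")
        if self.kind == "ratiometric" and np.any(v <= 0):
            raise ValueError("ratiometric features must be > 0")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def ratiometric_transform(
    record: MeasurementRecord, combos: RatioCombinationSet
) -> FeatureVector:
    """Ratio features: for each combination, numerator spectrum / denominator.

    Element order is combinations in ``combos`` order, frequencies
    ascending within each combination; 10 x 25 = 250 values.
    """
    values: list[float] = []
    for num, den in combos.assignments:
        zn = record.spectra[num].as_array()
        zd = record.spectra[den].as_array()
        if np.any(zd <= 0):
            raise ValueError(f"non-positive denominator magnitude in pair {den}")
        values.extend(zn / zd)
    return FeatureVector(values=tuple(values), kind="ratiometric")


def raw_features(record: MeasurementRecord) -> FeatureVector:
    """Raw features: the ten spectra concatenated in canonical pair order.

    Pairs in lexicographic (a, b) order, frequencies ascending within each
    pair; 10 x 25 = 250 values.
    """
    values: list[float] = []
    for p in ALL_PAIRS:
        if p not in record.spectra:
            raise ValueError(f"record is missing pair {p}")
        values.extend(record.spectra[p].as_array())
    return FeatureVector(values=tuple(values), kind="raw")


def balanced_derangement(mean_logs, rtol: float = 1e-9) -> tuple[int, ...]:
    """Derangement sigma minimising ``sum_i (m_i - m_sigma(i))^2``.

    Works for any number of items >= 2 (the full problem has 10).  Ties
    are broken toward the lexicographically smallest sigma.
    """
    m = np.asarray(mean_logs, dtype=float)
    if m.ndim != 1 or m.size < 2:
        raise ValueError("need at least two mean log-magnitudes")
    cost = (m[:, None] - m[None, :]) ** 2
    np.fill_diagonal(cost, np.inf)
    return tuple(_lex_min_optimal_derangement(cost, rtol=rtol))


def _lex_min_optimal_derangement(cost: np.ndarray, rtol: float = 1e-9) -> list[int]:
    """Lexicographically smallest assignment among the optimal derangements.

    ``cost`` is n x n with +inf on the diagonal.  Solved by repeated exact
    assignment: fix positions one at a time, keeping only denominator
    choices that still admit a completion of optimal total cost.
    """
    n = cost.shape[0]

    def opt(c: np.ndarray) -> float:
        # infinite if the forbidden entries leave no complete assignment
        try:
            rows, cols = linear_sum_assignment(c)
        except ValueError:
            return np.inf
        return float(c[rows, cols].sum())

    best = opt(cost)
    tol = rtol * max(1.0, abs(best))
    chosen: list[int] = []
    work = cost.copy()
    for i in range(n):
        for j in range(n):
            if j in chosen or not np.isfinite(work[i, j]):
                continue
            trial = work.copy()
            trial[i, :] = np.inf
            trial[:, j] = np.inf
            trial[i, j] = work[i, j]
            if opt(trial) <= best + tol:
                chosen.append(j)
                work = trial
                break
        else:  # pragma: no cover - a completion always exists for n >= 2
            raise RuntimeError("no feasible derangement completion")
    return chosen


def select_combinations_from_means(
    mean_logs: np.ndarray, pairs: tuple[FingerPair, ...] = ALL_PAIRS
) -> RatioCombinationSet:
    """Balanced-scale derangement for given per-pair mean log-magnitudes."""
    m = np.asarray(mean_logs, dtype=float)
    if m.shape != (len(pairs),):
        raise ValueError("one mean log-magnitude per pair required")
    sigma = balanced_derangement(m)
    return RatioCombinationSet(
        tuple((pairs[i], pairs[j]) for i, j in enumerate(sigma))
    )


def select_combinations(training: SpectraDataset) -> RatioCombinationSet:
    """Data-driven combination choice minimising feature log-scale imbalance.

    For each pair ``p`` compute ``M_p``, the mean over all training records
    and frequencies of ``log |Z_p(f)|``; return the derangement minimising
    ``sum_p (M_p - M_sigma(p))^2``, ties broken lexicographically.
    """
    if len(training) == 0:
        raise ValueError("training dataset is empty")
    mean_logs = np.array(
        [
            np.mean(
                [np.log(r.spectra[p].as_array()) for r in training.records]
            )
            for p in ALL_PAIRS
        ]
    )
    return select_combinations_from_means(mean_logs)
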