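"""Bootstrap test for population-scale acclimatization.

For each coral population (one taxon at one site) the per-genet change in
bleaching category between the two heat-stress events — an integer in
[-4, 4], computed over genets present in both events — is resampled with
replacement to build a null distribution of the population median change.
The one-sided p-value is the proportion of resample medians that are >= 0
(inclusive, so ties at zero count against acclimatization); populations
with fewer than ``min_survivors`` genets are ineligible and report no p.

``enumerate_exact_p`` performs the same computation exactly by enumerating
all n^n equally likely resamples (via multiset counts, so it is feasible up
to n = 8) and serves as an independent oracle for the Monte-Carlo routine.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np


@dataclass(frozen=True)
class BootstrapResult:
    n: int
    n_resamples: int
    seed: int
    observed_median: float | None
    p: float | None
    eligible: bool
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.eligible and self.p is not None and self.p < self.alpha


def eligibility(n: int, min_survivors: int = 10) -> bool:
    """A population is testable with >= ``min_survivors`` surviving genets."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return n >= min_survivors


def _check_deltas(deltas) -> np.ndarray:
    arr = np.asarray(deltas, dtype=float)
    if arr.size and (arr.min() < -4 or arr.max() > 4):
        raise ValueError("bleaching-score changes must lie in [-4, 4]")
    return arr


def acclim_test(
    deltas,
    n_resamples: int = 100_000,
    seed: int = 0,
    min_survivors: int = 10,
    alpha: float = 0.05,
) -> BootstrapResult:
    """Bootstrap p-value for a population-wide decrease in bleaching score.

    Each resample draws ``n`` values with replacement from ``deltas``; the
    median of an even-length resample is the mean of the middle two order
    statistics.  ``p`` is the fraction of resamples whose median is >= 0.
    """
    arr = _check_deltas(deltas)
    n = arr.size
    if not eligibility(n, min_survivors):
        return BootstrapResult(
            n=n,
            n_resamples=n_resamples,
            seed=seed,
            observed_median=float(np.median(arr)) if n else None,
            p=None,
            eligible=False,
            alpha=alpha,
        )
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(n_resamples, 20_000_000 // max(n, 1)))
    done = 0
    while done < n_resamples:
        m = min(chunk, n_resamples - done)
        idx = rng.integers(0, n, size=(m, n))
        medians = np.median(arr[idx], axis=1)
        hits += int(np.count_nonzero(medians >= 0))
        done += m
    return BootstrapResult(
        n=n,
        n_resamples=n_resamples,
        seed=seed,
        observed_median=float(np.median(arr)),
        p=hits / n_resamples,
        eligible=True,
        alpha=alpha,
    )


def enumerate_exact_p(deltas) -> float:
    """Exact P(resample median >= 0) over all n^n equally likely resamples.

    Resamples are counted by the multiset of drawn items: a count vector
    (k_1..k_n) with sum n occurs in multinomial(n; k) of the n^n draws.
    Refuses n > 8, where even the multiset enumeration stops being instant.
    """
    arr = _check_deltas(deltas)
    n = arr.size
    if n == 0:
        raise ValueError("empty delta sample")
    if n > 8:
        raise ValueError("exact enumeration restricted to n <= 8")
    total = n**n
    hits = 0
    for picks in combinations_with_replacement(range(n), n):
        counts = np.bincount(picks, minlength=n)
        weight = math.factorial(n)
        for k in counts:
            weight //= math.factorial(int(k))
        if np.median(arr[list(picks)]) >= 0:
            hits += weight
    return hits / total


def population_seed(master_seed: int, site: str, taxon: str) -> int:
    """Stable per-population RNG seed independent of test execution order."""
    tag = zlib.crc32(f"{site}|{taxon}".encode("utf-8"))
    return int(np.random.SeedSequence([master_seed, tag]).generate_state(1)[0] % (2**31))
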