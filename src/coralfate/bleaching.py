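"""Bleaching scoring: patch rubric, area-weighted genet scores, responses.

Every patch carries a bleaching *extent* (percent of its area showing some
paling, 0-100) and a *severity* (ordinal 0-3 scored on the bleached tissue
only: 0 practically no pigmentation loss, 1 slight paling, 2 significant
loss, 3 almost or completely stark white).  A rubric maps the pair to one of
five ordered bleaching categories:

    1  no bleaching or very minor paling
    2  minor bleaching
    3  moderate bleaching
    4  severe bleaching
    5  extreme bleaching

The default rubric thresholds a bleaching index I = extent x severity
(range 0-300): category 1 when I = 0 or extent < 5 %, category 2 for
0 < I <= 25, 3 for I <= 100, 4 for I <= 200 and 5 above.  It anchors the
two labelled corners — (0 %, any) is category 1 and (100 %, 3) is category
5 — is monotone in both inputs, and can be replaced by any threshold table
loaded from CSV.

Genet-level scores are area-weighted.  Two methods are exposed because the
field protocol admits both readings: ``modal`` (default) assigns the patch
category holding the largest summed patch area, ties broken toward the
worse category; ``aggregate`` first pools extent (area-weighted mean) and
severity (bleached-area-weighted mean) across patches and then applies the
rubric to the pooled pair.

The change statistic between the two bleaching events is simply
``category(event 2) - category(event 1)`` (an integer in [-4, 4]); genets
that moved two or more steps are classed as decreased/increased responders,
and stable genets split into thermally tolerant vs. highly susceptible at
moderate bleaching in either event.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORY_LABELS = {
    1: "no bleaching or very minor paling",
    2: "minor bleaching",
    3: "moderate bleaching",
    4: "severe bleaching",
    5: "extreme bleaching",
}


class ResponseClass(str, enum.Enum):
    """Four-way classification of a genet's bleaching trajectory."""

    thermally_tolerant = "thermally_tolerant"
    decreased = "decreased"
    increased = "increased"
    high_susceptibility = "high_susceptibility"


RESPONSE_ORDER = [
    ResponseClass.thermally_tolerant,
    ResponseClass.decreased,
    ResponseClass.increased,
    ResponseClass.high_susceptibility,
]


@dataclass(frozen=True)
class Rubric:
    """Threshold table on the bleaching index I = extent(%) x severity.

    ``bounds`` maps category -> (index_min, index_max]; ``min_extent`` is the
    paling floor below which a patch is always category 1 regardless of
    severity.
    """

    bounds: tuple[tuple[int, float, float], ...] = (
        (2, 0.0, 25.0),
        (3, 25.0, 100.0),
        (4, 100.0, 200.0),
        (5, 200.0, 300.0),
    )
    min_extent: float = 5.0

    def score(self, extent: float, severity: int) -> int:
        if not 0.0 <= extent <= 100.0:
            raise ValueError(f"extent {extent} outside [0, 100]")
        if severity not in (0, 1, 2, 3):
            raise ValueError(f"severity {severity} not in {{0, 1, 2, 3}}")
        index = extent * severity
        if index == 0.0 or extent < self.min_extent:
            return 1
        for category, lo, hi in self.bounds:
            if lo < index <= hi:
                return category
        return self.bounds[-1][0]

    def check_monotone(self) -> None:
        """Assert monotonicity over the full integer extent/severity grid."""
        grid = np.array(
            [[self.score(e, s) for s in range(4)] for e in range(101)], dtype=int
        )
        if (np.diff(grid, axis=0) < 0).any() or (np.diff(grid, axis=1) < 0).any():
            raise ValueError("rubric is not monotone in extent/severity")
        if self.score(0.0, 3) != 1 or self.score(100.0, 3) != 5:
            raise ValueError("rubric must anchor (0, *) -> 1 and (100, 3) -> 5")

    @classmethod
    def from_csv(cls, path) -> "Rubric":
        table = pd.read_csv(path)
        bounds = tuple(
            (int(r.category), float(r.index_min), float(r.index_max))
            for r in table.itertuples()
            if int(r.category) != 1
        )
        rubric = cls(bounds=tuple(sorted(bounds, key=lambda b: b[0])))
        rubric.check_monotone()
        return rubric

    def to_frame(self) -> pd.DataFrame:
        rows = [{"category": 1, "index_min": 0.0, "index_max": 0.0}]
        rows += [
            {"category": c, "index_min": lo, "index_max": hi} for c, lo, hi in self.bounds
        ]
        return pd.DataFrame(rows)


DEFAULT_RUBRIC = Rubric()


def score_patch(extent: float, severity: int, rubric: Rubric = DEFAULT_RUBRIC) -> int:
    """Bleaching category (1-5) of a single patch."""
    return rubric.score(extent, severity)


def genet_weighted_extent(areas, extents) -> float:
    """Area-weighted mean bleaching extent across a genet's patches."""
    areas = np.asarray(areas, dtype=float)
    extents = np.asarray(extents, dtype=float)
    if areas.size == 0:
        raise ValueError("genet has no patches at this timepoint")
    return float(np.average(extents, weights=areas))


def genet_weighted_severity(areas, extents, severities) -> float:
    """Bleached-area-weighted mean severity (0 when nothing is bleached).

    Severity describes only the bleached fraction of each patch, so weights
    are bleached areas ``area * extent / 100`` rather than whole-patch areas.
    """
    areas = np.asarray(areas, dtype=float)
    extents = np.asarray(extents, dtype=float)
    severities = np.asarray(severities, dtype=float)
    bleached = areas * extents / 100.0
    total = bleached.sum()
    if total == 0.0:
        return 0.0
    return float(np.sum(bleached * severities) / total)


@dataclass(frozen=True)
class GenetBleaching:
    genet_id: int
    timepoint: int
    weighted_extent: float
    weighted_severity: float
    category: int
    method: str


def score_genet(
    genet_id: int,
    timepoint: int,
    member_patches: pd.DataFrame,
    method: str = "modal",
    rubric: Rubric = DEFAULT_RUBRIC,
) -> GenetBleaching:
    """Genet-level bleaching score at one timepoint.

    ``member_patches`` holds the genet's patches at ``timepoint`` (columns
    ``area_cm2, extent_pct, severity``).  ``modal`` picks the per-patch
    category with the largest summed area (ties toward the higher category);
    ``aggregate`` applies the rubric to the pooled extent and the pooled
    severity rounded half-up to the nearest ordinal level.
    """
    if len(member_patches) == 0:
        raise ValueError(f"genet {genet_id} has no patches at {timepoint}")
    areas = member_patches["area_cm2"].to_numpy(dtype=float)
    extents = member_patches["extent_pct"].to_numpy(dtype=float)
    severities = member_patches["severity"].to_numpy(dtype=int)

    wext = genet_weighted_extent(areas, extents)
    wsev = genet_weighted_severity(areas, extents, severities)

    if method == "modal":
        weight: dict[int, float] = {}
        for a, e, s in zip(areas, extents, severities):
            c = rubric.score(e, int(s))
            weight[c] = weight.get(c, 0.0) + a
        best = max(weight.items(), key=lambda kv: (kv[1], kv[0]))[0]
        category = best
    elif method == "aggregate":
        category = rubric.score(wext, int(math.floor(wsev + 0.5)))
    else:
        raise ValueError(f"unknown genet scoring method {method!r}")
    return GenetBleaching(genet_id, timepoint, wext, wsev, category, method)


def _check_category(c: int) -> None:
    if c not in (1, 2, 3, 4, 5):
        raise ValueError(f"bleaching category {c} not in 1..5")


def change_statistic(c_event1: int, c_event2: int) -> int:
    """Change in bleaching category between the two events (in [-4, 4]).

    -4 means extreme bleaching in the first event and none in the second
    (the strongest acclimatization signal), +4 the reverse, 0 no change.
    """
    _check_category(c_event1)
    _check_category(c_event2)
    return c_event2 - c_event1


def classify_response(c_event1: int, c_event2: int) -> ResponseClass:
    """Four-way response class from the two event-year categories.

    A shift of two or more steps is a decreased (negative) or increased
    (positive) bleaching response; stable genets (|change| <= 1) are highly
    susceptible when they reached moderate bleaching or worse in either
    event, otherwise thermally tolerant.
    """
    delta = change_statistic(c_event1, c_event2)
    if delta <= -2:
        return ResponseClass.decreased
    if delta >= 2:
        return ResponseClass.increased
    if max(c_event1, c_event2) >= 3:
        return ResponseClass.high_susceptibility
    return ResponseClass.thermally_tolerant


def binarize(category: int) -> int:
    """1 for moderate/severe/extreme bleaching (category >= 3), else 0."""
    _check_category(category)
    return int(category >= 3)
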