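"""Genet assembly from temporally linked coral tissue patches.

A *patch* is one contiguous region of live coral tissue in one survey year.
Patches are linked between consecutive surveys when they belong to the same
colony; many-to-one links encode fusion and one-to-many links encode fission.
A *genet* is a connected component of this temporal link graph and is the
unit of all downstream analysis: its planar area in a year is the summed
area of its member patches, and it survives the timeseries if it holds at
least one patch in both the first and the final survey.

Patch tables are plain :class:`pandas.DataFrame` objects with columns
``patch_id, site, survey_year, taxon, area_cm2, extent_pct, severity`` and
optional centroid columns ``x_m, y_m`` (site-local metres).  Link tables
carry ``site, from_year, from_patch, to_year, to_patch``.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

PATCH_COLUMNS = [
    "patch_id",
    "site",
    "survey_year",
    "taxon",
    "area_cm2",
    "extent_pct",
    "severity",
]
LINK_COLUMNS = ["site", "from_year", "from_patch", "to_year", "to_patch"]


class GenetAssemblyError(ValueError):
    """Raised when patch/link tables violate the temporal-graph contract."""


@dataclass(frozen=True)
class Genet:
    """A network of tissue patches interconnected through time.

    ``members`` is a frozenset of ``(survey_year, patch_id)`` pairs forming
    one connected component of the link graph; singleton patches with no
    links are singleton genets.
    """

    genet_id: int
    site: str
    taxon: str
    members: frozenset[tuple[int, str]]

    def years(self) -> list[int]:
        return sorted({y for y, _ in self.members})

    @property
    def first_year(self) -> int:
        return min(y for y, _ in self.members)

    @property
    def last_year(self) -> int:
        return max(y for y, _ in self.members)


@dataclass(frozen=True)
class Quadrat:
    """A square sampling frame in site-local metres (default 0.5 m^2)."""

    site: str
    x: float
    y: float
    side: float = math.sqrt(0.5)

    def contains(self, x: float, y: float) -> bool:
        return self.x <= x < self.x + self.side and self.y <= y < self.y + self.side

    def overlaps(self, other: "Quadrat") -> bool:
        if self.site != other.site:
            return False
        return (
            self.x < other.x + other.side
            and other.x < self.x + self.side
            and self.y < other.y + other.side
            and other.y < self.y + self.side
        )


@dataclass(frozen=True)
class SamplingConfig:
    """Quadrat sampling rules used to select genets for tracing.

    Genets qualify through a patch with equivalent-circle diameter above
    ``min_diameter_cm`` whose centroid falls inside a quadrat in the first
    survey; quadrats are consumed in order until ``target_genets`` genets are
    reached or ``max_quadrats`` quadrats have been used; any taxon exceeding
    ``genet_cap`` selected genets is subsampled to the cap.
    """

    min_diameter_cm: float = 5.0
    target_genets: int = 40
    max_quadrats: int = 25
    genet_cap: int = 100
    seed: int = 0


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GenetAssemblyError(f"{what} table missing columns: {missing}")


def equivalent_diameter_cm(area_cm2: float) -> float:
    """Diameter of the circle with the same planar area, in cm."""
    return 2.0 * math.sqrt(area_cm2 / math.pi)


def assemble_genets(
    patches: pd.DataFrame,
    links: pd.DataFrame,
    surveys: list[int] | None = None,
    strict: bool = True,
) -> list[Genet]:
    """Partition patches into genets (connected components of the link graph).

    Parameters
    ----------
    patches, links
        Patch and temporal-link tables (see module docstring for schemas).
    surveys
        Ordered list of survey years.  Defaults to the sorted distinct years
        in ``patches``.  Links must join consecutive surveys of this list.
    strict
        When True (default), links joining non-consecutive surveys and
        genets missing all patches at an interior survey between their
        first and last year are rejected as data errors; the annotation
        workflow never produces such gaps, so they indicate a broken link
        table.  With ``strict=False`` a non-consecutive link is accepted as
        an explicit skip over the gap it spans (with a warning), and any
        remaining uncovered gap warns instead of raising.

    Returns
    -------
    list of :class:`Genet`, ordered by deterministic ``genet_id`` (sorted by
    site, then first year of appearance, then lexicographically smallest
    member patch id), starting at 1.
    """
    _require_columns(patches, PATCH_COLUMNS, "patch")
    _require_columns(links, LINK_COLUMNS, "link")
    if surveys is None:
        surveys = sorted(patches["survey_year"].unique().tolist())
    survey_pos = {int(y): i for i, y in enumerate(surveys)}

    dup = patches.duplicated(subset=["site", "survey_year", "patch_id"])
    if dup.any():
        rows = patches.loc[dup, ["site", "survey_year", "patch_id"]].head(5)
        raise GenetAssemblyError(f"duplicate patch keys, e.g.:\n{rows}")

    # node key: (site, year, patch_id)
    graph: nx.Graph = nx.Graph()
    node_index: dict[tuple[str, int, str], int] = {}
    for row in patches.itertuples(index=True):
        year = int(row.survey_year)
        if year not in survey_pos:
            raise GenetAssemblyError(
                f"patch {row.patch_id!r} at year {year} not in survey list {surveys}"
            )
        key = (row.site, year, str(row.patch_id))
        node_index[key] = row.Index
        graph.add_node(key)

    for row in links.itertuples():
        fy, ty = int(row.from_year), int(row.to_year)
        src = (row.site, fy, str(row.from_patch))
        dst = (row.site, ty, str(row.to_patch))
        for end, label in ((src, row.from_patch), (dst, row.to_patch)):
            if end not in node_index:
                raise GenetAssemblyError(
                    f"link endpoint {label!r} (site {row.site}, year {end[1]}) "
                    "has no matching patch"
                )
        if fy not in survey_pos or ty not in survey_pos:
            raise GenetAssemblyError(f"link years ({fy}, {ty}) not in survey list")
        if abs(survey_pos[ty] - survey_pos[fy]) != 1:
            msg = (
                f"link {row.from_patch!r}->{row.to_patch!r} joins non-consecutive "
                f"surveys {fy} and {ty}"
            )
            if strict:
                raise GenetAssemblyError(msg + "; pass strict=False to allow skips")
            warnings.warn(msg + "; treated as an explicit skip", stacklevel=2)
        graph.add_edge(src, dst)

    taxa = patches["taxon"].to_numpy()
    components = []
    for comp in nx.connected_components(graph):
        members = frozenset((year, pid) for (_site, year, pid) in comp)
        sites = {site for (site, _y, _p) in comp}
        if len(sites) != 1:
            raise GenetAssemblyError(f"component spans multiple sites: {sorted(sites)}")
        site = next(iter(sites))
        member_taxa = Counter(taxa[node_index[key]] for key in comp)
        if len(member_taxa) > 1:
            warnings.warn(
                f"mixed-taxon genet at site {site} ({dict(member_taxa)}); "
                "using modal taxon",
                stacklevel=2,
            )
        # modal taxon, alphabetical tie-break for determinism
        taxon = min(member_taxa, key=lambda t: (-member_taxa[t], t))
        components.append((site, members, taxon))

    components.sort(key=lambda c: (c[0], min(y for y, _ in c[1]), min(p for _, p in c[1])))
    genets = [
        Genet(genet_id=i, site=site, taxon=taxon, members=members)
        for i, (site, members, taxon) in enumerate(components, start=1)
    ]

    # spans of explicit skip links, per genet, in survey positions
    member_to_genet: dict[tuple[str, int, str], int] = {}
    for g in genets:
        for y, p in g.members:
            member_to_genet[(g.site, y, p)] = g.genet_id
    skip_spans: dict[int, list[tuple[int, int]]] = {}
    for row in links.itertuples():
        a, b = survey_pos[int(row.from_year)], survey_pos[int(row.to_year)]
        if abs(b - a) > 1:
            gid = member_to_genet[(row.site, int(row.from_year), str(row.from_patch))]
            skip_spans.setdefault(gid, []).append((min(a, b), max(a, b)))

    for g in genets:
        years = set(g.years())
        lo, hi = survey_pos[g.first_year], survey_pos[g.last_year]
        spans = skip_spans.get(g.genet_id, [])
        gaps = [
            surveys[i]
            for i in range(lo, hi + 1)
            if surveys[i] not in years and not any(a < i < b for a, b in spans)
        ]
        if gaps:
            msg = (
                f"genet {g.genet_id} (site {g.site}) has no patch at interior "
                f"survey(s) {gaps} between {g.first_year} and {g.last_year}"
            )
            if strict:
                raise GenetAssemblyError(msg + "; pass strict=False to allow")
            warnings.warn(msg, stacklevel=2)
    return genets


def genet_area_series(
    genet: Genet, patches: pd.DataFrame, surveys: list[int] | None = None
) -> dict[int, float]:
    """Total planar area (cm^2) of a genet in each survey year.

    The value at a year is the sum of member-patch areas; years in which the
    genet holds no patch report 0.
    """
    if surveys is None:
        surveys = sorted(patches["survey_year"].unique().tolist())
    sub = member_patches(genet, patches)
    by_year = sub.groupby("survey_year")["area_cm2"].sum()
    return {int(y): float(by_year.get(y, 0.0)) for y in surveys}


def member_patches(genet: Genet, patches: pd.DataFrame) -> pd.DataFrame:
    """Rows of ``patches`` belonging to ``genet``."""
    keys = {(y, p) for y, p in genet.members}
    mask = [
        (int(y), str(p)) in keys and s == genet.site
        for y, p, s in zip(patches["survey_year"], patches["patch_id"], patches["site"])
    ]
    return patches.loc[mask]


def assign_genet_ids(genets: list[Genet], patches: pd.DataFrame) -> pd.Series:
    """``genet_id`` for every patch row (NaN for rows in no listed genet).

    One dict lookup per row, so downstream per-genet operations can group
    by this column instead of rescanning the patch table per genet.
    """
    lookup: dict[tuple[str, int, str], int] = {}
    for g in genets:
        for y, p in g.members:
            lookup[(g.site, y, p)] = g.genet_id
    ids = [
        lookup.get((s, int(y), str(p)))
        for s, y, p in zip(patches["site"], patches["survey_year"], patches["patch_id"])
    ]
    return pd.Series(ids, index=patches.index, dtype="Int64", name="genet_id")


def survived(genet: Genet, t_first: int, t_last: int, surveys: list[int]) -> bool:
    """True iff the genet holds >= 1 patch in both endpoint surveys."""
    for t in (t_first, t_last):
        if t not in surveys:
            raise ValueError(f"unknown survey year {t}; surveys are {surveys}")
    years = set(g for g, _ in genet.members)
    return t_first in years and t_last in years


def cohort_filter(genets: list[Genet], t_first: int) -> list[Genet]:
    """Restrict to the cohort alive at the first survey (recruits excluded)."""
    return [g for g in genets if t_first in {y for y, _ in g.members}]


def select_quadrat_genets(
    patches: pd.DataFrame,
    links: pd.DataFrame,
    quadrats: list[Quadrat],
    config: SamplingConfig,
    surveys: list[int] | None = None,
) -> set[int]:
    """Apply the quadrat sampling rules and return selected ``genet_id`` s.

    A genet qualifies when, at the first survey, it has at least one patch
    with equivalent-circle diameter above ``config.min_diameter_cm`` whose
    centroid lies inside a quadrat in use.  Quadrats are consumed in the
    given order until ``target_genets`` genets are selected or
    ``max_quadrats`` quadrats are used; patches outside quadrats or below
    the diameter threshold ride along via their genet membership.  If any
    taxon exceeds ``genet_cap`` selected genets it is subsampled to the cap
    with the configured seed.
    """
    for i, qa in enumerate(quadrats):
        for qb in quadrats[i + 1 :]:
            if qa.overlaps(qb):
                raise ValueError(f"overlapping quadrats at site {qa.site}: {qa}, {qb}")

    if surveys is None:
        surveys = sorted(patches["survey_year"].unique().tolist())
    t_first = surveys[0]
    genets = assemble_genets(patches, links, surveys)

    first = patches[patches["survey_year"] == t_first]
    missing_centroids = (
        first[first[["x_m", "y_m"]].isna().any(axis=1)]["patch_id"].tolist()
        if {"x_m", "y_m"} <= set(first.columns)
        else first["patch_id"].tolist()
    )
    if missing_centroids:
        raise ValueError(f"patches without centroids: {missing_centroids}")

    patch_to_genet: dict[tuple[str, int, str], Genet] = {}
    for g in genets:
        for y, p in g.members:
            patch_to_genet[(g.site, y, p)] = g

    selected: set[int] = set()
    used = 0
    for quad in quadrats:
        if used >= config.max_quadrats or len(selected) >= config.target_genets:
            break
        used += 1
        inside = first[
            (first["site"] == quad.site)
            & first.apply(lambda r: quad.contains(r["x_m"], r["y_m"]), axis=1)
        ]
        for row in inside.itertuples():
            if equivalent_diameter_cm(row.area_cm2) > config.min_diameter_cm:
                g = patch_to_genet[(row.site, int(row.survey_year), str(row.patch_id))]
                selected.add(g.genet_id)

    by_taxon: dict[str, list[int]] = {}
    lookup = {g.genet_id: g for g in genets}
    for gid in sorted(selected):
        by_taxon.setdefault(lookup[gid].taxon, []).append(gid)

    rng = np.random.default_rng(config.seed)
    out: set[int] = set()
    for taxon in sorted(by_taxon):
        gids = by_taxon[taxon]
        if len(gids) > config.genet_cap:
            gids = sorted(rng.choice(gids, size=config.genet_cap, replace=False).tolist())
        out.update(gids)
    return out


def genets_to_frame(
    genets: list[Genet],
    patches: pd.DataFrame,
    surveys: list[int],
    t_first: int,
    t_last: int,
) -> pd.DataFrame:
    """Summary table: one row per genet with per-survey areas and survival."""
    ids = assign_genet_ids(genets, patches)
    areas = (
        patches.assign(genet_id=ids)
        .dropna(subset=["genet_id"])
        .pivot_table(
            index="genet_id", columns="survey_year", values="area_cm2", aggfunc="sum"
        )
        .reindex(columns=surveys)
        .fillna(0.0)
    )
    rows = []
    for g in genets:
        per_year = areas.loc[g.genet_id] if g.genet_id in areas.index else None
        rows.append(
            {
                "genet_id": g.genet_id,
                "site": g.site,
                "taxon": g.taxon,
                "first_year": g.first_year,
                "last_year": g.last_year,
                "survived": survived(g, t_first, t_last, surveys),
                **{
                    f"area_{y}": float(per_year[y]) if per_year is not None else 0.0
                    for y in surveys
                },
            }
        )
    return pd.DataFrame(rows)
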