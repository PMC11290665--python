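"""Validated file I/O and the end-to-end analysis pipeline.

The pipeline chains the stages in analysis order: read and validate the
patch and link tables, assemble genets, restrict to the cohort alive at the
first survey, score genet-level bleaching in every survey year, classify
2015 -> 2019 responses, run the per-population bootstrap acclimatization
test and the population statistics, and write a deterministic report
bundle (``genets.csv``, ``bleaching_scores.csv``, ``responses.csv``,
``acclim_results.csv``, ``popstats.json``, ``letters.csv``, ``run_log.txt``).

Given identical inputs, configuration and master seed the bundle is
byte-identical across runs (the run log records wall-clock timestamps and
is the only exception).
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from coralfate.acclim import acclim_test, population_seed
from coralfate.bleaching import (
    DEFAULT_RUBRIC,
    Rubric,
    binarize,
    change_statistic,
    classify_response,
    score_genet,
)
from coralfate.genet_graph import (
    LINK_COLUMNS,
    PATCH_COLUMNS,
    Genet,
    assemble_genets,
    assign_genet_ids,
    cohort_filter,
    genets_to_frame,
)
from coralfate.popstats import (
    ancova,
    build_response_table,
    compact_letters,
    diagnostics,
    logistic_fit,
    pairwise_fisher,
    pairwise_site_contrasts,
    survivorship_design,
)

PATCH_CSV_COLUMNS = [
    "patch_id",
    "site",
    "survey_year",
    "taxon",
    "area_cm2",
    "extent_pct",
    "severity",
    "x_m",
    "y_m",
]


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    n_rows_read: int = 0
    n_rows_kept: int = 0

    @property
    def ok(self) -> bool:
        return not self.errors


def read_patch_table(path) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a patch table; invalid rows are excluded and listed.

    Row numbers in the report refer to the CSV line (header = line 1).
    A missing required column is a hard error; out-of-range area, extent or
    severity values and duplicate (site, year, patch) keys are row-level
    errors that drop the offending row.
    """
    df = pd.read_csv(path)
    report = ValidationReport(n_rows_read=len(df))
    missing = [c for c in PATCH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for c in ("x_m", "y_m"):
        if c not in df.columns:
            df[c] = np.nan

    keep = np.ones(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        problems = []
        if not row.area_cm2 > 0:
            problems.append(f"area_cm2={row.area_cm2} (must be > 0)")
        if not 0.0 <= row.extent_pct <= 100.0:
            problems.append(f"extent_pct={row.extent_pct} (must be in [0, 100])")
        if row.severity not in (0, 1, 2, 3):
            problems.append(f"severity={row.severity} (must be in 0..3)")
        if problems:
            report.errors.append(f"row {line}: " + "; ".join(problems))
            keep[i] = False
    dup = df.duplicated(subset=["site", "survey_year", "patch_id"], keep="first")
    for i in np.flatnonzero(dup.to_numpy()):
        report.errors.append(f"row {i + 2}: duplicate (site, survey_year, patch_id) key")
        keep[i] = False
    out = df.loc[keep].reset_index(drop=True)
    report.n_rows_kept = len(out)
    return out, report


def read_link_table(path) -> tuple[pd.DataFrame, ValidationReport]:
    """Read a temporal-link table; endpoint existence is checked at assembly."""
    df = pd.read_csv(path)
    report = ValidationReport(n_rows_read=len(df), n_rows_kept=len(df))
    missing = [c for c in LINK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df, report


@dataclass
class RunConfig:
    """Fixed constants and paths for one pipeline run.

    Defaults carry the study design: five surveys 2014-2021, bleaching
    events in 2015 and 2019, alpha = 0.05, 100,000 bootstrap resamples and
    a minimum of 10 surviving genets per testable population.
    """

    patches_path: str | Path | None = None
    links_path: str | Path | None = None
    out_dir: str | Path = "coralfate_out"
    surveys: tuple[int, ...] = (2014, 2015, 2017, 2019, 2021)
    event_years: tuple[int, int] = (2015, 2019)
    t_first: int | None = None
    t_last: int | None = None
    alpha: float = 0.05
    n_resamples: int = 100_000
    min_survivors: int = 10
    rubric_path: str | Path | None = None
    method: str = "modal"
    strict: bool = True
    seed: int = 0
    ancova_interaction: bool = False

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not set(self.event_years) <= set(self.surveys):
            raise ValueError("event years must be surveys")
        if self.t_first is None:
            self.t_first = self.surveys[0]
        if self.t_last is None:
            self.t_last = self.surveys[-1]
        if not self.t_first < self.t_last:
            raise ValueError("t_first must precede t_last")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("surveys", "event_years"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _fmt(value) -> object:
    if isinstance(value, (np.floating, float)):
        return float(f"{float(value):.10g}")
    if isinstance(value, (np.integer, int)):
        return int(value)
    return value


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_pipeline(
    config: RunConfig,
    patches: pd.DataFrame | None = None,
    links: pd.DataFrame | None = None,
) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``.

    ``patches``/``links`` may be passed directly (already validated) or read
    from ``config.patches_path``/``links_path``.  Returns a dict with the
    in-memory results keyed by output name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        stamp = datetime.datetime.now(datetime.timezone.utc).strftime(
            "%Y-%m-%dT%H:%M:%SZ"
        )
        log_lines.append(f"{stamp} {msg}")

    from coralfate import __version__ as _version

    log(f"coralfate {_version} pipeline start")
    log(f"config: {config}")

    if patches is None:
        patches, report = _stage("read_patches", read_patch_table, config.patches_path)
        if not report.ok:
            for err in report.errors:
                log(f"patch validation: {err}")
            raise RuntimeError(
                f"pipeline stage 'read_patches' failed: {len(report.errors)} invalid rows; "
                + "; ".join(report.errors[:5])
            )
    if links is None:
        links, _ = _stage("read_links", read_link_table, config.links_path)

    rubric = (
        Rubric.from_csv(config.rubric_path) if config.rubric_path else DEFAULT_RUBRIC
    )
    surveys = list(config.surveys)
    e1, e2 = config.event_years

    genets = _stage(
        "assemble", assemble_genets, patches, links, surveys, strict=config.strict
    )
    cohort = _stage("cohort", cohort_filter, genets, config.t_first)
    log(f"assembled {len(genets)} genets; cohort at {config.t_first}: {len(cohort)}")

    genets_df = genets_to_frame(cohort, patches, surveys, config.t_first, config.t_last)

    # genet-level bleaching scores in every year with live tissue
    annotated = patches.assign(genet_id=assign_genet_ids(cohort, patches)).dropna(
        subset=["genet_id"]
    )
    grouped = {
        (int(gid), int(year)): sub
        for (gid, year), sub in annotated.groupby(["genet_id", "survey_year"])
    }
    score_rows = []
    categories: dict[tuple[int, int], int] = {}
    for g in cohort:
        for year in g.years():
            at_t = grouped[(g.genet_id, year)]
            gb = score_genet(g.genet_id, year, at_t, method=config.method, rubric=rubric)
            categories[(g.genet_id, year)] = gb.category
            score_rows.append(
                {
                    "genet_id": g.genet_id,
                    "year": year,
                    "weighted_extent": gb.weighted_extent,
                    "weighted_severity": gb.weighted_severity,
                    "category": gb.category,
                    "method": gb.method,
                }
            )
    scores_df = pd.DataFrame(score_rows)

    # responses for genets alive in both bleaching events
    resp_rows = []
    for g in cohort:
        years = set(g.years())
        if e1 in years and e2 in years:
            c1, c2 = categories[(g.genet_id, e1)], categories[(g.genet_id, e2)]
            resp_rows.append(
                {
                    "genet_id": g.genet_id,
                    "site": g.site,
                    "taxon": g.taxon,
                    f"cat_{e1}": c1,
                    f"cat_{e2}": c2,
                    "delta": change_statistic(c1, c2),
                    "response": classify_response(c1, c2).value,
                }
            )
    responses_df = pd.DataFrame(resp_rows)

    # bootstrap acclimatization test per population (site x taxon)
    acclim_rows = []
    if len(responses_df):
        for (site, taxon), grp in responses_df.groupby(["site", "taxon"]):
            seed = population_seed(config.seed, site, taxon)
            res = acclim_test(
                grp["delta"].to_numpy(),
                n_resamples=config.n_resamples,
                seed=seed,
                min_survivors=config.min_survivors,
                alpha=config.alpha,
            )
            acclim_rows.append(
                {
                    "site": site,
                    "taxon": taxon,
                    "n": res.n,
                    "eligible": res.eligible,
                    "observed_median": res.observed_median,
                    "p": res.p,
                    "n_resamples": res.n_resamples,
                    "seed": res.seed,
                }
            )
    acclim_df = pd.DataFrame(acclim_rows)

    popstats_report, letters_rows = _stage(
        "popstats",
        _popstats_block,
        config,
        genets_df,
        responses_df,
        categories,
        cohort,
        patches,
        surveys,
    )

    results = {
        "genets": genets_df,
        "bleaching_scores": scores_df,
        "responses": responses_df,
        "acclim_results": acclim_df,
        "popstats": popstats_report,
        "letters": pd.DataFrame(letters_rows, columns=["taxon", "site", "letters"]),
    }

    float_fmt = "%.10g"
    genets_df.to_csv(out_dir / "genets.csv", index=False, float_format=float_fmt)
    scores_df.to_csv(out_dir / "bleaching_scores.csv", index=False, float_format=float_fmt)
    responses_df.to_csv(out_dir / "responses.csv", index=False, float_format=float_fmt)
    acclim_df.to_csv(out_dir / "acclim_results.csv", index=False, float_format=float_fmt)
    results["letters"].to_csv(out_dir / "letters.csv", index=False)
    with open(out_dir / "popstats.json", "w") as fh:
        json.dump(popstats_report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log("wrote genets.csv bleaching_scores.csv responses.csv acclim_results.csv "
        "popstats.json letters.csv")
    log("pipeline done")
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return results


def _popstats_block(config, genets_df, responses_df, categories, cohort, patches, surveys):
    """Per-taxon population statistics: Fisher/letters, logistic fits, ANCOVA."""
    e1, e2 = config.event_years
    report: dict = {}
    letters_rows: list[dict] = []
    survivors = genets_df[genets_df["survived"]]
    by_id = genets_df.set_index("genet_id")

    for taxon in sorted(genets_df["taxon"].unique()):
        block: dict = {}
        tax_resp = (
            responses_df[responses_df["taxon"] == taxon]
            if len(responses_df)
            else pd.DataFrame()
        )
        surv_ids = set(survivors[survivors["taxon"] == taxon]["genet_id"])
        tax_surv_resp = (
            tax_resp[tax_resp["genet_id"].isin(surv_ids)] if len(tax_resp) else tax_resp
        )

        # Fisher's exact tests between sites + compact letters
        if len(tax_surv_resp) and tax_surv_resp["site"].nunique() >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = build_response_table(tax_surv_resp, group_by="site")
            pw = pairwise_fisher(table, alpha=config.alpha, seed=config.seed)
            sig = {
                frozenset((r.group_a, r.group_b)): r.significant for r in pw
            }
            letters = compact_letters(list(table.index), sig)
            block["pairwise_fisher"] = [
                {
                    "sites": sorted([r.group_a, r.group_b]),
                    "p_raw": _fmt(r.p_raw),
                    "p_adj": _fmt(r.p_adj),
                    "significant": r.significant,
                }
                for r in pw
            ]
            block["letters"] = letters
            block["response_table"] = {
                str(site): [int(v) for v in row]
                for site, row in zip(table.index, table.to_numpy())
            }
            for site in sorted(letters):
                letters_rows.append(
                    {"taxon": taxon, "site": site, "letters": letters[site]}
                )

        # logistic bleaching probability vs ln(area), pooled across sites
        block["logistic_bleaching"] = {}
        for year in (e1, e2):
            rows = []
            for g in cohort:
                if g.taxon != taxon or (g.genet_id, year) not in categories:
                    continue
                area = by_id.at[g.genet_id, f"area_{year}"]
                if area <= 0:
                    continue
                rows.append(
                    {
                        "bleached": binarize(categories[(g.genet_id, year)]),
                        "ln_area": float(np.log(area)),
                    }
                )
            dfb = pd.DataFrame(rows)
            if len(dfb) >= 10 and dfb["bleached"].nunique() == 2:
                X = pd.DataFrame({"const": 1.0, "ln_area": dfb["ln_area"]})
                fit = logistic_fit(dfb["bleached"].to_numpy(), X)
                block["logistic_bleaching"][str(year)] = _logistic_json(fit)

        # logistic survivorship vs ln(area) x site, all cohort genets
        tax_genets = genets_df[
            (genets_df["taxon"] == taxon) & (genets_df[f"area_{config.t_first}"] > 0)
        ].copy()
        if len(tax_genets) >= 20 and tax_genets["survived"].nunique() == 2:
            tax_genets["ln_area"] = np.log(tax_genets[f"area_{config.t_first}"])
            multi_site = tax_genets["site"].nunique() >= 2
            X, ref, sites = survivorship_design(
                tax_genets, interaction=multi_site
            ) if multi_site else (
                pd.DataFrame(
                    {"const": 1.0, "ln_area": tax_genets["ln_area"].to_numpy()},
                    index=tax_genets.index,
                ),
                None,
                sorted(tax_genets["site"].unique()),
            )
            try:
                fit = logistic_fit(tax_genets["survived"].astype(float).to_numpy(), X)
                block["logistic_survivorship"] = _logistic_json(fit)
                if multi_site and not fit.separated:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        contrasts = pairwise_site_contrasts(
                            fit, sites, ref, alpha=config.alpha
                        )
                    block["survivorship_contrasts"] = [
                        {
                            "sites": sorted([r.group_a, r.group_b]),
                            "p_raw": _fmt(r.p_raw),
                            "p_adj": _fmt(r.p_adj),
                            "significant": r.significant,
                        }
                        for r in contrasts
                    ]
            except ValueError as exc:
                block["logistic_survivorship"] = {"error": str(exc)}

        # ANCOVA of growth vs bleaching response for survivors
        if len(tax_surv_resp) >= 20:
            merged = tax_surv_resp.merge(
                genets_df[["genet_id", f"area_{config.t_first}", f"area_{config.t_last}"]],
                on="genet_id",
            )
            merged = merged[
                (merged[f"area_{config.t_first}"] > 0)
                & (merged[f"area_{config.t_last}"] > 0)
            ]
            try:
                fit = ancova(
                    np.log(merged[f"area_{config.t_last}"]),
                    np.log(merged[f"area_{config.t_first}"]),
                    merged["response"],
                    include_interaction=config.ancova_interaction,
                )
                diag = diagnostics(
                    fit.residuals,
                    merged[merged["response"].isin(fit.retained_levels)]["response"],
                )
                block["ancova"] = {
                    "slope": _fmt(fit.slope),
                    "n": fit.n,
                    "retained_levels": fit.retained_levels,
                    "terms": {
                        str(term): {
                            "df": _fmt(row["df"]),
                            "F": _fmt(row["F"]) if np.isfinite(row["F"]) else None,
                            "p": _fmt(row["p"]) if np.isfinite(row["p"]) else None,
                        }
                        for term, row in fit.terms.iterrows()
                    },
                }
                block["diagnostics"] = {
                    "shapiro_w": _fmt(diag.shapiro_w),
                    "shapiro_p": _fmt(diag.shapiro_p),
                    "cochran_c": _fmt(diag.cochran_c) if diag.cochran_c is not None else None,
                    "cochran_p": _fmt(diag.cochran_p) if diag.cochran_p is not None else None,
                }
            except ValueError as exc:
                block["ancova"] = {"error": str(exc)}
        report[taxon] = block
    return report, letters_rows


def _logistic_json(fit) -> dict:
    return {
        "terms": {
            name: {
                "coef": _fmt(c),
                "se": _fmt(s),
                "p": _fmt(p) if np.isfinite(p) else None,
            }
            for name, c, s, p in zip(fit.names, fit.params, fit.bse, fit.pvalues)
        },
        "converged": fit.converged,
        "separated": fit.separated,
        "llf": _fmt(fit.llf),
        "n": fit.n,
    }
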