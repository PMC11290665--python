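"""Population-level statistics for bleaching-response comparisons.

Contents:

* contingency tables of surviving genets by bleaching response,
* Fisher's exact test — full hypergeometric enumeration for 2x2 tables,
  exact network enumeration for r x c tables while the table space stays
  tractable, seeded Monte-Carlo otherwise,
* Bonferroni adjustment and a compact letter display (groups share a letter
  iff they are not significantly different),
* logistic regression via iteratively reweighted least squares with
  separation detection, used for bleaching-vs-size and survivorship models,
* pairwise Wald contrasts between sites whose size interactions are
  non-significant,
* ANCOVA of log final area on log initial area plus a factor (sequential,
  covariate-first sums of squares) with Shapiro normality and Cochran
  variance-homogeneity diagnostics.
"""

from __future__ import annotations

import math
import string
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import special, stats

from coralfate.bleaching import RESPONSE_ORDER

MAX_EXACT_TABLES = 1_000_000
MC_DRAWS = 100_000


# ---------------------------------------------------------------------------
# contingency tables and Fisher's exact test


def build_response_table(
    classified: pd.DataFrame, group_by: str = "site"
) -> pd.DataFrame:
    """Cross-tabulate surviving genets' response classes by group.

    ``classified`` must carry a ``response`` column (ResponseClass values)
    and the grouping column.  Columns follow the fixed response order;
    groups with zero genets are dropped with a warning.
    """
    if len(classified) == 0:
        raise ValueError("no classified genets to tabulate")
    order = [r.value for r in RESPONSE_ORDER]
    resp = classified["response"].map(lambda r: getattr(r, "value", r))
    table = pd.crosstab(classified[group_by], resp)
    for col in order:
        if col not in table.columns:
            table[col] = 0
    table = table[order]
    empty = table.index[table.sum(axis=1) == 0]
    if len(empty):
        warnings.warn(f"dropping groups with no survivors: {list(empty)}", stacklevel=2)
        table = table.drop(index=empty)
    return table


def _table_logprob(table: np.ndarray, lr: np.ndarray, lc: np.ndarray, ln: float) -> float:
    return float(lr.sum() + lc.sum() - ln - sum(math.lgamma(x + 1) for x in table.flat))


def _enumerate_tables(row_sums, col_sums, max_tables):
    """Yield all non-negative integer tables with the given margins.

    Returns None (via StopIteration sentinel) by raising ``_TooMany`` when
    the count exceeds ``max_tables``.
    """
    r = len(row_sums)

    def rows_for(total, remaining_cols):
        # all compositions of `total` across columns bounded by remaining sums
        c = len(remaining_cols)

        def rec(j, left):
            if j == c - 1:
                if left <= remaining_cols[j]:
                    yield (left,)
                return
            hi = min(left, remaining_cols[j])
            for v in range(hi + 1):
                for rest in rec(j + 1, left - v):
                    yield (v,) + rest

        yield from rec(0, total)

    count = 0

    def rec_rows(i, remaining_cols, acc):
        nonlocal count
        if i == r - 1:
            # last row is forced by the remaining column sums (margins match
            # by construction, and each entry is non-negative)
            count += 1
            if count > max_tables:
                raise _TooMany
            yield acc + [tuple(remaining_cols)]
            return
        for row in rows_for(row_sums[i], remaining_cols):
            new_remaining = [s - v for s, v in zip(remaining_cols, row)]
            yield from rec_rows(i + 1, new_remaining, acc + [row])

    yield from rec_rows(0, list(col_sums), [])


class _TooMany(Exception):
    pass


@dataclass(frozen=True)
class FisherResult:
    p: float
    method: str  # "exact-2x2" | "exact-enum" | "monte-carlo"
    n_draws: int | None = None
    seed: int | None = None


def fisher_exact(table, seed: int = 0, mc_draws: int = MC_DRAWS) -> FisherResult:
    """Two-sided Fisher's exact test for an r x c contingency table.

    The p-value is the total probability, under fixed margins, of tables no
    more probable than the observed one.  2x2 tables are enumerated over the
    hypergeometric support; larger tables are enumerated exactly while the
    table space holds at most ``MAX_EXACT_TABLES`` tables, otherwise a
    seeded Monte-Carlo sample of tables from the margins is used and flagged.
    """
    arr = np.asarray(table)
    if arr.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float)
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            raise ValueError("table must hold non-negative integer counts")
        arr = arr.astype(int)
    # degenerate margins: no association possible
    arr = arr[arr.sum(axis=1) > 0][:, arr.sum(axis=0) > 0]
    if arr.size == 0 or min(arr.shape) < 2:
        return FisherResult(p=1.0, method="exact-2x2")

    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    n = int(arr.sum())
    lr = np.array([math.lgamma(s + 1) for s in row_sums])
    lc = np.array([math.lgamma(s + 1) for s in col_sums])
    ln = math.lgamma(n + 1)
    obs_lp = _table_logprob(arr, lr, lc, ln)
    tol = 1e-7  # relative tolerance for "no more probable than observed"

    if arr.shape == (2, 2):
        # enumerate the hypergeometric support of the top-left cell; table
        # probabilities are integer weights C(r1, x) C(r2, c1-x) over
        # C(n, c1), so the two-sided inclusion rule is decided exactly
        r1, r2 = int(row_sums[0]), int(row_sums[1])
        c1 = int(col_sums[0])
        lo, hi = max(0, c1 - r2), min(r1, c1)
        w_obs = math.comb(r1, int(arr[0, 0])) * math.comb(r2, c1 - int(arr[0, 0]))
        num = sum(
            w
            for x in range(lo, hi + 1)
            if (w := math.comb(r1, x) * math.comb(r2, c1 - x)) <= w_obs
        )
        return FisherResult(p=min(1.0, num / math.comb(n, c1)), method="exact-2x2")

    try:
        p = 0.0
        for rows in _enumerate_tables(row_sums.tolist(), col_sums.tolist(), MAX_EXACT_TABLES):
            t = np.array(rows)
            lp = _table_logprob(t, lr, lc, ln)
            if lp <= obs_lp + tol:
                p += math.exp(lp)
        return FisherResult(p=min(1.0, p), method="exact-enum")
    except _TooMany:
        pass

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(mc_draws):
        remaining = col_sums.copy()
        rows = []
        for i in range(len(row_sums) - 1):
            row = rng.multivariate_hypergeometric(remaining, int(row_sums[i]))
            rows.append(row)
            remaining = remaining - row
        rows.append(remaining)
        lp = _table_logprob(np.array(rows), lr, lc, ln)
        if lp <= obs_lp + tol:
            hits += 1
    return FisherResult(
        p=hits / mc_draws, method="monte-carlo", n_draws=mc_draws, seed=seed
    )


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, m * p), m = family size."""
    ps = list(p_values)
    if m is None:
        m = len(ps)
    out = []
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, m * p))
    return out


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    p_raw: float
    p_adj: float
    significant: bool


def pairwise_fisher(
    table: pd.DataFrame, alpha: float = 0.05, seed: int = 0
) -> list[PairwiseResult]:
    """All pairwise two-group Fisher tests with Bonferroni over the family."""
    groups = list(table.index)
    pairs = list(combinations(groups, 2))
    raws = [
        fisher_exact(table.loc[[a, b]].to_numpy(), seed=seed).p for a, b in pairs
    ]
    adjs = bonferroni(raws, m=len(pairs))
    return [
        PairwiseResult(a, b, p_raw=pr, p_adj=pa, significant=pa < alpha)
        for (a, b), pr, pa in zip(pairs, raws, adjs)
    ]


# ---------------------------------------------------------------------------
# compact letter display


def compact_letters(groups, significant) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant`` maps unordered group pairs (frozenset or 2-tuple) to a
    boolean.  Two groups share a letter iff their comparison is
    non-significant.  The letter count is not guaranteed minimal but the
    defining invariant is verified before returning.
    """
    groups = list(groups)
    sig = {}
    for key, value in dict(significant).items():
        sig[frozenset(key)] = bool(value)
    for a, b in combinations(groups, 2):
        if frozenset((a, b)) not in sig:
            raise ValueError(f"missing significance for pair ({a}, {b})")

    sets: list[set[str]] = [set(groups)]
    for a, b in combinations(groups, 2):
        if not sig[frozenset((a, b))]:
            continue
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb: deduplicate, then drop sets contained in a larger set
        unique = []
        for s in new_sets:
            if s and s not in unique:
                unique.append(s)
        sets = [s for s in unique if not any(s < t for t in unique)]

    sets.sort(key=lambda s: sorted(s))
    letters = {g: "" for g in groups}
    alphabet = string.ascii_lowercase
    for i, s in enumerate(sets):
        symbol = alphabet[i % 26] * (1 + i // 26)
        for g in sorted(s):
            letters[g] += symbol

    for a, b in combinations(groups, 2):
        shares = bool(set(letters[a]) & set(letters[b]))
        if shares == sig[frozenset((a, b))]:
            raise AssertionError("letter display violates its defining invariant")
    if any(not v for v in letters.values()):
        raise AssertionError("every group must carry at least one letter")
    return letters


# ---------------------------------------------------------------------------
# logistic regression (IRLS)


@dataclass
class LogisticFit:
    names: list[str]
    params: np.ndarray
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    llf: float
    deviance_path: list[float]
    converged: bool
    separated: bool
    cov: np.ndarray
    n: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            },
            index=self.names,
        )

    def term_p(self, name: str) -> float:
        return float(self.pvalues[self.names.index(name)])


def logistic_fit(
    y,
    X: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 100,
    separation_bound: float = 15.0,
) -> LogisticFit:
    """Binary logistic regression by iteratively reweighted least squares.

    The design matrix must include an intercept column.  Convergence is
    declared when the largest coefficient update falls below ``tol``
    (or after ``max_iter`` sweeps).  Quasi-complete separation is flagged
    when a coefficient runs beyond ``separation_bound`` while the deviance
    is still improving; Wald p-values are withheld in that case.
    """
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])
    ]
    Xm = np.asarray(X, dtype=float)
    n, k = Xm.shape
    rank = np.linalg.matrix_rank(Xm)
    if rank < k:
        # identify offending columns from the QR decomposition
        _, R = np.linalg.qr(Xm)
        bad = [names[j] for j in range(k) if abs(R[j, j]) < 1e-10]
        raise ValueError(f"rank-deficient design; collinear columns: {bad or names}")

    beta = np.zeros(k)
    deviance_path: list[float] = []
    converged = False
    eps = 1e-10
    for _ in range(max_iter):
        eta = Xm @ beta
        mu = np.clip(special.expit(eta), eps, 1 - eps)
        dev = -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        deviance_path.append(dev)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        WX = Xm * w[:, None]
        beta_new = np.linalg.solve(Xm.T @ WX, WX.T @ z)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break

    eta = Xm @ beta
    mu = np.clip(special.expit(eta), eps, 1 - eps)
    llf = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    improving = len(deviance_path) >= 2 and (
        deviance_path[-2] - deviance_path[-1] > 1e-6
    )
    separated = bool(np.max(np.abs(beta)) > separation_bound and (improving or not converged))

    w = mu * (1 - mu)
    info = Xm.T @ (Xm * w[:, None])
    cov = np.linalg.inv(info)
    bse = np.sqrt(np.diag(cov))
    zvals = beta / bse
    pvals = 2.0 * stats.norm.sf(np.abs(zvals))
    if separated:
        pvals = np.full(k, np.nan)
    return LogisticFit(
        names=names,
        params=beta,
        bse=bse,
        zvalues=zvals,
        pvalues=pvals,
        llf=llf,
        deviance_path=deviance_path,
        converged=converged,
        separated=separated,
        cov=cov,
        n=n,
    )


def survivorship_design(
    df: pd.DataFrame,
    size_col: str = "ln_area",
    site_col: str = "site",
    interaction: bool = True,
) -> tuple[pd.DataFrame, str, list[str]]:
    """Design matrix for survivorship ~ ln(area) * site (treatment coding).

    Returns (X, reference_site, site_levels).  The alphabetically first site
    is the reference level and carries no dummy.
    """
    sites = sorted(df[site_col].unique())
    ref = sites[0]
    X = pd.DataFrame({"const": 1.0, size_col: df[size_col].to_numpy()}, index=df.index)
    for s in sites[1:]:
        dummy = (df[site_col] == s).astype(float)
        X[f"site[{s}]"] = dummy
        if interaction:
            X[f"{size_col}:site[{s}]"] = dummy * df[size_col]
    return X, ref, sites


def pairwise_site_contrasts(
    fit: LogisticFit,
    sites: list[str],
    reference: str,
    alpha: float = 0.05,
    size_col: str = "ln_area",
) -> list[PairwiseResult]:
    """Pairwise Wald contrasts of site main effects, Bonferroni-adjusted.

    Sites whose size interaction term is significant at ``alpha`` are
    excluded from the contrasts (their main effect is not interpretable on
    its own); the reference site carries no interaction term and is always
    eligible.  Returns an empty list (with a warning) when fewer than two
    sites remain.
    """
    idx = {name: i for i, name in enumerate(fit.names)}
    eligible = []
    for s in sites:
        if s == reference:
            eligible.append(s)
            continue
        term = f"{size_col}:site[{s}]"
        if term in idx:
            p_int = fit.pvalues[idx[term]]
            if np.isnan(p_int) or p_int < alpha:
                continue
        eligible.append(s)
    if len(eligible) < 2:
        warnings.warn("fewer than two sites eligible for pairwise contrasts", stacklevel=2)
        return []

    def coef_var(site: str) -> tuple[float, float, int | None]:
        if site == reference:
            return 0.0, 0.0, None
        j = idx[f"site[{site}]"]
        return float(fit.params[j]), float(fit.cov[j, j]), j

    pairs = list(combinations(eligible, 2))
    raws = []
    for a, b in pairs:
        ba, va, ja = coef_var(a)
        bb, vb, jb = coef_var(b)
        cov_ab = float(fit.cov[ja, jb]) if ja is not None and jb is not None else 0.0
        var = va + vb - 2.0 * cov_ab
        if var <= 0:
            raws.append(1.0)
            continue
        z = (ba - bb) / math.sqrt(var)
        raws.append(float(2.0 * stats.norm.sf(abs(z))))
    adjs = bonferroni(raws, m=len(pairs))
    return [
        PairwiseResult(a, b, p_raw=pr, p_adj=pa, significant=pa < alpha)
        for (a, b), pr, pa in zip(pairs, raws, adjs)
    ]


# ---------------------------------------------------------------------------
# ANCOVA and diagnostics


@dataclass
class AncovaFit:
    terms: pd.DataFrame  # index: term; columns: df, sum_sq, F, p
    params: pd.Series
    residuals: pd.Series
    slope: float
    retained_levels: list[str]
    n: int


def ancova(
    ln_final,
    ln_initial,
    factor,
    include_interaction: bool = False,
    min_group_n: int = 10,
) -> AncovaFit:
    """ANCOVA of log final area on log initial area and a factor.

    Factor levels with fewer than ``min_group_n`` observations are dropped
    before fitting.  Per-term F statistics come from sequential (Type I)
    sums of squares with the covariate entered first, so the factor is
    tested after adjusting for initial size.
    """
    df = pd.DataFrame(
        {
            "ln_final": np.asarray(ln_final, dtype=float),
            "ln_initial": np.asarray(ln_initial, dtype=float),
            "factor": [getattr(f, "value", f) for f in factor],
        }
    )
    counts = df["factor"].value_counts()
    retained = sorted(counts.index[counts >= min_group_n])
    if not retained:
        raise ValueError(f"no factor level reaches n >= {min_group_n}")
    df = df[df["factor"].isin(retained)].reset_index(drop=True)
    small = df["factor"].value_counts()
    if (small < 2).any():
        raise ValueError("retained factor level with < 2 observations")

    # sequential (covariate-first) sums of squares from explicit nested fits;
    # the factor is always tested after adjusting for initial size
    formulas = ["ln_final ~ ln_initial", "ln_final ~ ln_initial + C(factor)"]
    term_names = ["ln_initial", "C(factor)"]
    if include_interaction:
        formulas.append("ln_final ~ ln_initial + C(factor) + ln_initial:C(factor)")
        term_names.append("ln_initial:C(factor)")
    fits = [smf.ols(f, data=df).fit() for f in formulas]
    full = fits[-1]
    ss_total = float(np.sum((df["ln_final"] - df["ln_final"].mean()) ** 2))
    mse = full.ssr / full.df_resid
    rows = []
    prev_ssr, prev_df = ss_total, len(df) - 1
    for name, fit in zip(term_names, fits):
        ss = max(prev_ssr - fit.ssr, 0.0)  # guard tiny negative round-off
        ddf = prev_df - fit.df_resid
        f_stat = (ss / ddf) / mse if ddf > 0 else np.nan
        p = float(stats.f.sf(f_stat, ddf, full.df_resid)) if ddf > 0 else np.nan
        rows.append({"term": name, "df": ddf, "sum_sq": ss, "F": f_stat, "p": p})
        prev_ssr, prev_df = fit.ssr, fit.df_resid
    rows.append(
        {"term": "Residual", "df": full.df_resid, "sum_sq": full.ssr,
         "F": np.nan, "p": np.nan}
    )
    table = pd.DataFrame(rows).set_index("term")
    return AncovaFit(
        terms=table,
        params=full.params,
        residuals=full.resid,
        slope=float(full.params["ln_initial"]),
        retained_levels=retained,
        n=len(df),
    )


@dataclass(frozen=True)
class DiagnosticsResult:
    shapiro_w: float | None
    shapiro_p: float | None
    cochran_c: float | None
    cochran_p: float | None
    constant_residuals: bool


def cochran_c(group_variances) -> float:
    """Cochran's C: largest group variance over the sum of group variances."""
    v = np.asarray(list(group_variances), dtype=float)
    total = v.sum()
    if total == 0:
        raise ValueError("all group variances are zero")
    return float(v.max() / total)


def _cochran_p(c: float, k: int, n_bar: float) -> float:
    """Classical critical-value approximation for Cochran's C.

    Inverts the relation between the C critical value and the F
    distribution: C_crit = 1 / (1 + (k-1)/F), with df (n-1, (n-1)(k-1))
    and a Bonferroni factor k.  Mean group size is used for unbalanced data.
    """
    if c >= 1.0:
        return 0.0
    nu = max(n_bar - 1.0, 1.0)
    f_obs = (k - 1) * c / (1.0 - c)
    p = k * stats.f.sf(f_obs, nu, nu * (k - 1))
    return float(min(1.0, p))


def diagnostics(residuals, group_labels) -> DiagnosticsResult:
    """Shapiro normality of residuals and Cochran homogeneity of variance."""
    resid = np.asarray(residuals, dtype=float)
    if resid.size < 3:
        raise ValueError("need at least 3 residuals")
    if np.allclose(resid, resid[0]):
        return DiagnosticsResult(None, None, None, None, constant_residuals=True)
    w, shapiro_p = stats.shapiro(resid)

    labels = pd.Series(list(group_labels))
    groups = labels.unique()
    c = cp = None
    if len(groups) >= 2:
        variances = [
            float(np.var(resid[(labels == g).to_numpy()], ddof=1))
            for g in groups
            if (labels == g).sum() >= 2
        ]
        if len(variances) >= 2 and sum(variances) > 0:
            c = cochran_c(variances)
            sizes = [int((labels == g).sum()) for g in groups if (labels == g).sum() >= 2]
            cp = _cochran_p(c, k=len(variances), n_bar=float(np.mean(sizes)))
    return DiagnosticsResult(
        shapiro_w=float(w),
        shapiro_p=float(shapiro_p),
        cochran_c=c,
        cochran_p=cp,
        constant_residuals=False,
    )
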