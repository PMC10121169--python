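"""Statistics for the GFP-Trap TMT interactome and the imaging endpoints.

The interactome stage reproduces a Perseus-style analysis from first
principles: protein groups flagged as contaminants or reverse hits, or with
fewer than two unique peptides, are removed; reporter intensities are
log2-transformed; per-protein Welch's t statistics (optionally moderated by
an s0 variance fudge) are compared against balanced label permutations to
estimate a false discovery rate at 1% and 5%; interactors are called by the
conjunction of >2.0-fold enrichment and the 1% FDR, and the top set by
fold enrichment >= 3.0.

The imaging endpoints use textbook machinery implemented from formulas:
Student's and Welch's t, balanced two-way ANOVA with a partitioned
sum-of-squares table, Tukey HSD from the studentized-range distribution,
Sidak adjustment, and the ELISA normalization arithmetic (concentration
rescaled to a reference protein content).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthgen import TmtTable

logger = logging.getLogger(__name__)

__all__ = [
    "preprocess_tmt",
    "welch_t",
    "student_t",
    "permutation_fdr",
    "call_interactors",
    "top_set",
    "two_way_anova",
    "tukey_hsd",
    "sidak_adjust",
    "normalize_cytokine",
]


def preprocess_tmt(
    table: TmtTable,
    min_unique_peptides: int = 2,
    zero_policy: str = "drop",
    zero_offset: float = 1.0,
) -> pd.DataFrame:
    """Filter a protein-group table and log2-transform the reporter matrix.

    Removes contaminant rows, reverse-database rows, and rows with fewer
    than ``min_unique_peptides`` unique peptides; the remaining intensities
    are log2-transformed.  Rows containing a zero in any used channel are
    dropped by default (``zero_policy="drop"``, count logged) or offset by a
    small constant (``zero_policy="offset"``).  Row order is preserved.

    Returns a DataFrame indexed by protein_id with the log2 reporter
    columns (control first, then GFP).
    """
    df = table.frame
    if df.empty:
        raise ValueError("empty protein-group table")
    keep = (~df["is_contaminant"]) & (~df["is_reverse"]) & (
        df["unique_peptides"] >= min_unique_peptides
    )
    filtered = df.loc[keep]
    if filtered.empty:
        n_flag = int((df["is_contaminant"] | df["is_reverse"]).sum())
        n_pep = int((df["unique_peptides"] < min_unique_peptides).sum())
        dominant = "contaminant/reverse flags" if n_flag >= n_pep else "unique-peptide minimum"
        raise ValueError(f"all rows removed; dominant filter: {dominant}")

    cols = table.control_cols + table.gfp_cols
    values = filtered[cols].to_numpy(dtype=float)
    has_zero = (values <= 0).any(axis=1)
    if has_zero.any():
        if zero_policy == "drop":
            logger.info("dropping %d rows with zero reporter intensities", int(has_zero.sum()))
            filtered = filtered.loc[~has_zero]
            values = values[~has_zero]
        elif zero_policy == "offset":
            values = values + zero_offset
        else:
            raise ValueError(f"unknown zero_policy {zero_policy!r}")
    out = pd.DataFrame(np.log2(values), columns=cols, index=filtered["protein_id"].to_numpy())
    out.index.name = "protein_id"
    return out


# --------------------------------------------------------------------------
# t statistics


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Unequal-variance two-sample t test.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2), df by Welch-Satterthwaite,
    two-sided p from the t distribution.  Both groups constant with equal
    means -> (0, n1+n2-2, 1); with unequal means -> (+-inf, n1+n2-2, 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    v1 = a.var(ddof=1)
    v2 = b.var(ddof=1)
    diff = a.mean() - b.mean()
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, float(n1 + n2 - 2), 1.0
        return float(np.copysign(np.inf, diff)), float(n1 + n2 - 2), 0.0
    t = diff / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def student_t(group_a, group_b) -> tuple[float, float, float]:
    """Pooled-variance two-sample t test (t, df, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, float(df), 1.0
        return float(np.copysign(np.inf, diff)), float(df), 0.0
    t = diff / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


# --------------------------------------------------------------------------
# permutation FDR


def _d_statistic(x: np.ndarray, gfp_mask: np.ndarray, s0: float) -> np.ndarray:
    """Vectorized moderated Welch statistic per row of x."""
    g = x[:, gfp_mask]
    c = x[:, ~gfp_mask]
    n1 = g.shape[1]
    n2 = c.shape[1]
    diff = g.mean(axis=1) - c.mean(axis=1)
    se = np.sqrt(g.var(axis=1, ddof=1) / n1 + c.var(axis=1, ddof=1) / n2)
    denom = s0 + se
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, diff / denom, np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    return d


def _balanced_relabelings(
    n_samples: int, gfp_mask: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Distinct balanced relabelings, excluding the observed labeling and
    its complement (which reproduce the observed statistics and would floor
    the FDR estimate at 1/#relabelings)."""
    n_g = int(gfp_mask.sum())
    observed = frozenset(np.flatnonzero(gfp_mask).tolist())
    complement = frozenset(np.flatnonzero(~gfp_mask).tolist())
    all_sets = [
        frozenset(s)
        for s in combinations(range(n_samples), n_g)
        if frozenset(s) not in (observed, complement)
    ]
    total = comb(n_samples, n_g) - (2 if n_g * 2 == n_samples else 1)
    assert len(all_sets) == total
    if n_permutations >= len(all_sets):
        if n_permutations > len(all_sets):
            logger.info(
                "requested %d permutations but only %d distinct balanced "
                "relabelings exist; using the exhaustive set",
                n_permutations,
                len(all_sets),
            )
        chosen = all_sets
    else:
        idx = rng.choice(len(all_sets), size=n_permutations, replace=False)
        chosen = [all_sets[i] for i in idx]
    masks = []
    for s in chosen:
        m = np.zeros(n_samples, dtype=bool)
        m[list(s)] = True
        masks.append(m)
    return masks


@dataclass
class FdrResult:
    table: pd.DataFrame  # protein_id, log2fc, d, t, welch_df, p, significant_1pct/5pct
    fdr_curve: pd.DataFrame  # threshold, n_observed, mean_permuted, raw_fdr, fdr
    thresholds: dict[float, float]  # level -> |d| cutoff (inf if never reached)


def permutation_fdr(
    log2_matrix: pd.DataFrame,
    gfp_cols: list[str],
    levels: tuple[float, ...] = (0.01, 0.05),
    n_permutations: int = 1000,
    s0: float = 0.0,
    rng_seed: int = 0,
    estimator: str = "mean",
) -> FdrResult:
    """Permutation-based FDR calls on per-protein Welch statistics.

    For every candidate threshold tau (the observed |d| values), the FDR is
    estimated as (average over label permutations of the number of permuted
    |d| >= tau) / (number of observed |d| >= tau), monotonized to be
    non-increasing in tau; a protein is significant at level alpha iff its
    |d| reaches the smallest tau whose monotonized FDR is <= alpha.
    Permutations are balanced relabelings of the sample columns, exhaustive
    when fewer than ``n_permutations`` exist.  ``estimator`` selects the
    mean (default) or median of the permuted exceedance counts.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    cols = list(log2_matrix.columns)
    gfp_mask = np.array([c in gfp_cols for c in cols])
    if gfp_mask.sum() < 2 or (~gfp_mask).sum() < 2:
        raise ValueError("need >= 2 samples per group")
    x = log2_matrix.to_numpy(dtype=float)
    rng = np.random.default_rng(rng_seed)

    d_obs = _d_statistic(x, gfp_mask, s0)
    perm_masks = _balanced_relabelings(len(cols), gfp_mask, n_permutations, rng)
    perm_abs = np.abs(
        np.concatenate([_d_statistic(x, m, s0) for m in perm_masks])
    )
    n_perm = len(perm_masks)

    abs_obs = np.abs(d_obs)
    taus = np.unique(abs_obs)  # ascending
    obs_sorted = np.sort(abs_obs)
    n_obs_ge = abs_obs.size - np.searchsorted(obs_sorted, taus, side="left")
    if estimator == "mean":
        perm_sorted = np.sort(perm_abs)
        mean_perm_ge = (perm_abs.size - np.searchsorted(perm_sorted, taus, side="left")) / n_perm
    elif estimator == "median":
        per_perm = np.abs(np.stack([_d_statistic(x, m, s0) for m in perm_masks]))
        counts = np.stack(
            [p.size - np.searchsorted(np.sort(p), taus, side="left") for p in per_perm]
        )
        mean_perm_ge = np.median(counts, axis=0)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(n_obs_ge > 0, mean_perm_ge / n_obs_ge, 0.0)
    raw = np.clip(raw, 0.0, 1.0)
    mono = np.minimum.accumulate(raw[::-1])[::-1]  # non-increasing in tau

    cutoffs: dict[float, float] = {}
    for level in levels:
        ok = np.flatnonzero(mono <= level)
        cutoffs[level] = float(taus[ok[0]]) if ok.size else np.inf

    g = x[:, gfp_mask]
    c = x[:, ~gfp_mask]
    log2fc = g.mean(axis=1) - c.mean(axis=1)
    n1, n2 = g.shape[1], c.shape[1]
    v1 = g.var(axis=1, ddof=1)
    v2 = c.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t_plain = np.where(se2 > 0, log2fc / np.sqrt(se2), 0.0)
        df = np.where(
            se2 > 0,
            se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)),
            n1 + n2 - 2,
        )
    p = np.minimum(2.0 * sps.t.sf(np.abs(t_plain), df), 1.0)

    table = pd.DataFrame(
        {
            "protein_id": log2_matrix.index.to_numpy(),
            "log2fc": log2fc,
            "d": d_obs,
            "t": t_plain,
            "welch_df": df,
            "p": p,
        }
    )
    for level in levels:
        table[f"significant_{_level_name(level)}"] = abs_obs >= cutoffs[level]
    curve = pd.DataFrame(
        {
            "threshold": taus,
            "n_observed": n_obs_ge,
            "mean_permuted": mean_perm_ge,
            "raw_fdr": raw,
            "fdr": mono,
        }
    )
    return FdrResult(table=table, fdr_curve=curve, thresholds=cutoffs)


def _level_name(level: float) -> str:
    return f"{level * 100:g}pct"


def call_interactors(
    results: pd.DataFrame, fold_min: float = 2.0, fdr_level: float = 0.01
) -> pd.DataFrame:
    """Interactors: strictly more than ``fold_min``-fold enriched in the GFP
    pulldown AND significant at ``fdr_level`` permutation FDR."""
    col = f"significant_{_level_name(fdr_level)}"
    if col not in results.columns:
        raise ValueError(f"results were not computed at FDR level {fdr_level}")
    mask = (results["log2fc"] > np.log2(fold_min)) & results[col]
    return results.loc[mask].reset_index(drop=True)


def top_set(results: pd.DataFrame, fold_min: float = 3.0, k: int = 50) -> pd.DataFrame:
    """The k most enriched proteins among those with fold >= fold_min,
    stable-sorted by (-log2fc, protein_id)."""
    eligible = results.loc[results["log2fc"] >= np.log2(fold_min)]
    ordered = eligible.sort_values(
        ["log2fc", "protein_id"], ascending=[False, True], kind="stable"
    )
    return ordered.head(k).reset_index(drop=True)


# --------------------------------------------------------------------------
# ANOVA and friends


def two_way_anova(values, factor_a, factor_b) -> pd.DataFrame:
    """Two-way ANOVA table with sources A, B, A:B interaction, residual.

    Balanced designs (equal cell counts > 1) use the textbook partitioned
    sums of squares; with one observation per cell the interaction is the
    residual (additive model); unbalanced designs fall back to Type II SS
    via an OLS fit.  Returns a DataFrame indexed by source with columns
    sum_sq, df, mean_sq, F, p, plus a Total row.
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (y.size == fa.size == fb.size):
        raise ValueError("values and factors must have equal length")
    a_levels = np.unique(fa)
    b_levels = np.unique(fb)
    if a_levels.size < 2 or b_levels.size < 2:
        raise ValueError("each factor needs at least two levels")
    cell_counts = np.zeros((a_levels.size, b_levels.size), dtype=int)
    for i, al in enumerate(a_levels):
        for j, bl in enumerate(b_levels):
            cell_counts[i, j] = int(np.sum((fa == al) & (fb == bl)))
    if (cell_counts == 0).any():
        raise ValueError("empty design cell")
    balanced = cell_counts.min() == cell_counts.max()
    if not balanced:
        return _anova_type2(y, fa, fb)

    n = int(cell_counts[0, 0])
    a, b = a_levels.size, b_levels.size
    grand = y.mean()
    mean_a = np.array([y[fa == al].mean() for al in a_levels])
    mean_b = np.array([y[fb == bl].mean() for bl in b_levels])
    cell_mean = np.array(
        [[y[(fa == al) & (fb == bl)].mean() for bl in b_levels] for al in a_levels]
    )
    ss_a = b * n * np.sum((mean_a - grand) ** 2)
    ss_b = a * n * np.sum((mean_b - grand) ** 2)
    ss_ab = n * np.sum((cell_mean - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    resid = y - np.array(
        [
            cell_mean[np.searchsorted(a_levels, al), np.searchsorted(b_levels, bl)]
            for al, bl in zip(fa, fb)
        ]
    )
    ss_resid = float(np.sum(resid**2))
    ss_total = float(np.sum((y - grand) ** 2))

    if n == 1:
        # no replication: interaction becomes the residual
        rows = {
            "A": (ss_a, a - 1),
            "B": (ss_b, b - 1),
            "Residual": (ss_ab, (a - 1) * (b - 1)),
        }
    else:
        rows = {
            "A": (ss_a, a - 1),
            "B": (ss_b, b - 1),
            "A:B": (ss_ab, (a - 1) * (b - 1)),
            "Residual": (ss_resid, a * b * (n - 1)),
        }
    return _assemble_anova(rows, ss_total, len(y) - 1)


def _assemble_anova(rows: dict[str, tuple[float, int]], ss_total: float, df_total: int):
    ms_resid = rows["Residual"][0] / rows["Residual"][1] if rows["Residual"][1] > 0 else np.nan
    records = []
    for source, (ss, df) in rows.items():
        ms = ss / df if df > 0 else np.nan
        if source == "Residual" or not np.isfinite(ms_resid) or ms_resid == 0:
            f_val, p = np.nan, np.nan
        else:
            f_val = ms / ms_resid
            p = float(sps.f.sf(f_val, df, rows["Residual"][1]))
        records.append({"source": source, "sum_sq": ss, "df": df, "mean_sq": ms, "F": f_val, "p": p})
    records.append(
        {"source": "Total", "sum_sq": ss_total, "df": df_total, "mean_sq": np.nan, "F": np.nan, "p": np.nan}
    )
    out = pd.DataFrame(records).set_index("source")
    if (out.loc[out.index != "Total", "sum_sq"] == 0).all():
        logger.warning("degenerate ANOVA input: all observations equal")
        out.attrs["degenerate"] = True
    return out


def _anova_type2(y, fa, fb) -> pd.DataFrame:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": y, "A": pd.Categorical(fa.astype(str)), "B": pd.Categorical(fb.astype(str))})
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    rows = {
        "A": (float(tab.loc["C(A)", "sum_sq"]), int(tab.loc["C(A)", "df"])),
        "B": (float(tab.loc["C(B)", "sum_sq"]), int(tab.loc["C(B)", "df"])),
        "A:B": (float(tab.loc["C(A):C(B)", "sum_sq"]), int(tab.loc["C(A):C(B)", "df"])),
        "Residual": (float(tab.loc["Residual", "sum_sq"]), int(tab.loc["Residual", "df"])),
    }
    ss_total = float(np.sum((y - y.mean()) ** 2))
    return _assemble_anova(rows, ss_total, len(y) - 1)


def tukey_hsd(values, groups) -> pd.DataFrame:
    """Tukey's multiple-comparisons test across group means.

    Adjusted p values come from the studentized-range distribution on the
    residual degrees of freedom of the one-way fit; unequal group sizes use
    the Tukey-Kramer standard error."""
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = np.unique(g)
    if levels.size < 2:
        raise ValueError("need at least two groups")
    ns = np.array([np.sum(g == lv) for lv in levels])
    if (ns < 2).any():
        raise ValueError("each group needs at least two observations")
    means = np.array([y[g == lv].mean() for lv in levels])
    df_resid = int(y.size - levels.size)
    ss_resid = float(sum(np.sum((y[g == lv] - y[g == lv].mean()) ** 2) for lv in levels))
    ms_resid = ss_resid / df_resid
    k = levels.size
    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        se = np.sqrt(ms_resid / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        if se == 0:
            q = 0.0 if diff == 0 else np.inf
        else:
            q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_resid)) if np.isfinite(q) else 0.0
        rows.append(
            {"group_1": levels[i], "group_2": levels[j], "mean_diff": diff, "q": q, "p_adj": min(p, 1.0)}
        )
    return pd.DataFrame(rows)


def sidak_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Sidak correction: p_adj = 1 - (1 - p)^m, capped at 1."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if m is None:
        m = p.size
    return np.minimum(1.0 - (1.0 - p) ** m, 1.0)


def normalize_cytokine(concentration: float, protein_content: float, reference: float) -> float:
    """Rescale an ELISA concentration (pg/ml) to a reference protein content
    (100 ug for microglia monocultures, 500 ug for cocultures)."""
    if protein_content <= 0:
        raise ValueError("protein content must be positive")
    if reference <= 0:
        raise ValueError("reference protein content must be positive")
    return concentration * reference / protein_content
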