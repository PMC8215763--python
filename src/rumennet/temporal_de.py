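"""Temporal differential-expression analysis of (family x functional cluster)
features.

Counts are summarised per feature, screened for a time effect (and for an
animal effect, whose carriers are excluded, mirroring the removal of features
confounded with the animal of origin), compared between all timepoint pairs,
and labelled with compact-letter significance groups built from the maximal
cliques of the non-significance graph — the construction analogous to the
letter display of Tukey's HSD.

The default testing engine is a linear-model surrogate: an additive
``animal + time`` model fitted to regularized-log feature values, with the
time (resp. animal) p-value from the F-test of the full model against the
animal-only (resp. time-only) reduction, and pairwise timepoint contrasts as
t-tests on the fitted time coefficients.  The stage's contract is defined on
the p-value tables, so an externally computed table (e.g. from a
negative-binomial likelihood-ratio engine) can be plugged in unchanged via
``run_de(..., engine="external", external_pvalues=...)``.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_tables import ExpressionTable, SampleDesign, timepoint_label

UNCLUSTERED_ID = "unclustered"


def summarize_features(table: ExpressionTable) -> pd.DataFrame:
    """Sum counts per (family, functional cluster) feature per sample.

    Genes lacking a functional cluster are assigned to a reserved
    ``unclustered`` id with a warning.
    """
    meta = table.gene_meta
    clusters = meta["functional_cluster"].astype("object")
    missing = clusters.isna() | (clusters == "")
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} gene(s) lack a functional cluster; assigned "
            f"to {UNCLUSTERED_ID!r}",
            stacklevel=2,
        )
        clusters = clusters.where(~missing, UNCLUSTERED_ID)
    ft = table.counts.groupby([meta["family"], clusters]).sum()
    ft.index.names = ["family", "functional_cluster"]
    return ft


def rlog_features(ft: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Sample-sum scaling to the median depth followed by log2(x + pc)."""
    sums = ft.sum(axis=0)
    if (sums == 0).any():
        raise ValueError(f"sample {sums.index[sums == 0][0]!r} has zero total count")
    scaled = ft / sums * float(np.median(sums.to_numpy()))
    return np.log2(scaled + pseudocount)


# ---------------------------------------------------------------------------
# surrogate linear-model engine
# ---------------------------------------------------------------------------

def _design_matrices(design: SampleDesign, samples: list[str]) -> dict[str, np.ndarray]:
    """Treatment-coded design matrices for the full and reduced models."""
    sub = design.table.loc[samples]
    if (sub["timepoint_h"] == 0).any():
        raise ValueError("baseline (0 h) samples must be excluded from DE testing")
    animals = sorted(sub["animal_id"].unique())
    tps = sorted(sub["timepoint_h"].unique())
    if len(animals) < 2 or len(tps) < 2:
        raise ValueError("DE testing requires >= 2 animals and >= 2 timepoints")
    per_tp = sub.groupby("timepoint_h")["animal_id"].nunique()
    if (per_tp < 2).any():
        t = per_tp.index[per_tp < 2][0]
        raise ValueError(
            f"timepoint {t:g} h is not replicated across animals"
        )
    n = len(samples)
    a_dum = np.zeros((n, len(animals) - 1))
    t_dum = np.zeros((n, len(tps) - 1))
    for i, s in enumerate(samples):
        ai = animals.index(sub.loc[s, "animal_id"])
        ti = tps.index(float(sub.loc[s, "timepoint_h"]))
        if ai > 0:
            a_dum[i, ai - 1] = 1.0
        if ti > 0:
            t_dum[i, ti - 1] = 1.0
    ones = np.ones((n, 1))
    return {
        "full": np.hstack([ones, a_dum, t_dum]),
        "animal_only": np.hstack([ones, a_dum]),
        "time_only": np.hstack([ones, t_dum]),
        "timepoints": np.array(tps, dtype=float),
        "n_animal_cols": a_dum.shape[1],
    }


def _rss(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual sums of squares of y (features x samples) on x, plus rank."""
    pinv = np.linalg.pinv(x)
    beta = y @ pinv.T
    resid = y - beta @ x.T
    return (resid**2).sum(axis=1), int(np.linalg.matrix_rank(x))


def _nested_f_pvalues(
    y: np.ndarray, x_full: np.ndarray, x_red: np.ndarray
) -> np.ndarray:
    rss_f, rank_f = _rss(y, x_full)
    rss_r, rank_r = _rss(y, x_red)
    df_num = rank_f - rank_r
    df_den = y.shape[1] - rank_f
    if df_num <= 0 or df_den <= 0:
        raise ValueError("degenerate model comparison (no testable degrees of freedom)")
    diff = np.maximum(rss_r - rss_f, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (diff / df_num) / (rss_f / df_den)
    p = stats.f.sf(f, df_num, df_den)
    tiny = rss_f <= 1e-12 * np.maximum(1.0, rss_r)
    p[tiny & (diff <= 1e-12)] = 1.0  # constant fit: nothing to explain
    p[tiny & (diff > 1e-12)] = 0.0
    return p


def test_time_effect(
    ft: pd.DataFrame, design: SampleDesign, alpha: float = 0.1
) -> pd.DataFrame:
    """Per-feature time- and animal-effect p-values from the surrogate model.

    Returns a frame indexed like ``ft`` with columns ``p_time``, ``p_animal``,
    BH-adjusted versions (across features), ``significant_time`` and
    ``excluded_animal`` at the given ``alpha``.
    """
    samples = [s for s in ft.columns if design.table.loc[s, "timepoint_h"] != 0]
    mats = _design_matrices(design, samples)
    y = rlog_features(ft[samples]).to_numpy(dtype=float)
    p_time = _nested_f_pvalues(y, mats["full"], mats["animal_only"])
    p_animal = _nested_f_pvalues(y, mats["full"], mats["time_only"])
    out = pd.DataFrame(
        {
            "p_time": p_time,
            "p_animal": p_animal,
            "p_adj_time": multipletests(p_time, method="fdr_bh")[1],
            "p_adj_animal": multipletests(p_animal, method="fdr_bh")[1],
        },
        index=ft.index,
    )
    out["excluded_animal"] = out["p_adj_animal"] < alpha
    out["significant_time"] = (out["p_adj_time"] < alpha) & ~out["excluded_animal"]
    return out


def pairwise_timepoints(
    ft: pd.DataFrame,
    design: SampleDesign,
    features: list | None = None,
) -> pd.DataFrame:
    """All pairwise timepoint contrasts per feature, BH-adjusted within feature.

    Returns a long frame with one row per (feature, timepoint pair): columns
    ``t_a``, ``t_b``, ``p`` and ``p_adj``.  Five timepoints yield exactly 10
    contrasts per feature.
    """
    samples = [s for s in ft.columns if design.table.loc[s, "timepoint_h"] != 0]
    mats = _design_matrices(design, samples)
    sub = ft if features is None else ft.loc[features]
    y = rlog_features(ft[samples]).loc[sub.index].to_numpy(dtype=float)

    x = mats["full"]
    tps = list(mats["timepoints"])
    n_a = mats["n_animal_cols"]
    pinv = np.linalg.pinv(x)
    beta = y @ pinv.T
    rank = int(np.linalg.matrix_rank(x))
    df = y.shape[1] - rank
    rss = ((y - beta @ x.T) ** 2).sum(axis=1)
    sigma2 = rss / df
    xtx_inv = np.linalg.pinv(x.T @ x)

    def contrast(i: int, j: int) -> np.ndarray:
        c = np.zeros(x.shape[1])
        if i > 0:
            c[1 + n_a + i - 1] = 1.0
        if j > 0:
            c[1 + n_a + j - 1] = -1.0
        return c

    rows = []
    for idx, feat in enumerate(sub.index):
        pvals = []
        pairs = list(combinations(range(len(tps)), 2))
        # constant features carry no information: every contrast is null
        scale = max(1.0, float((y[idx] ** 2).mean()))
        degenerate = sigma2[idx] <= 1e-14 * scale
        for i, j in pairs:
            c = contrast(i, j)
            est = beta[idx] @ c
            var = sigma2[idx] * (c @ xtx_inv @ c)
            if degenerate or var <= 0:
                p = 1.0 if abs(est) <= 1e-6 * np.sqrt(scale) else 0.0
            else:
                t = est / np.sqrt(var)
                p = float(2.0 * stats.t.sf(abs(t), df))
            pvals.append(p)
        adj = multipletests(pvals, method="fdr_bh")[1]
        for (i, j), p, pa in zip(pairs, pvals, adj):
            rows.append(
                {
                    "feature": feat,
                    "t_a": tps[i],
                    "t_b": tps[j],
                    "p": p,
                    "p_adj": float(pa),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# compact-letter significance groups from maximal cliques
# ---------------------------------------------------------------------------

def significance_letters(
    pair_p: dict[tuple[float, float], float],
    timepoints: list[float],
    alpha: float = 0.1,
) -> dict[float, str]:
    """Letter labels per timepoint from maximal cliques of the
    non-significance graph.

    Timepoints are joined by an edge when their adjusted p >= ``alpha``; the
    maximal cliques of that graph (each timepoint alone forms one if isolated)
    each receive a letter, ordered by the clique's earliest timepoint, and a
    timepoint's label concatenates the letters of all cliques containing it.
    Two timepoints share a letter iff they lie in a common maximal clique.
    """
    g = nx.Graph()
    g.add_nodes_from(timepoints)
    for (a, b), p in pair_p.items():
        if a == b:
            continue
        if p >= alpha:
            g.add_edge(a, b)
    order = {t: k for k, t in enumerate(sorted(timepoints))}
    cliques = [tuple(sorted(c, key=order.get)) for c in nx.find_cliques(g)]
    cliques.sort(key=lambda c: (order[c[0]], [order[t] for t in c]))
    letters = string.ascii_lowercase
    if len(cliques) > len(letters):
        raise ValueError("more significance groups than available letters")
    labels: dict[float, list[str]] = {t: [] for t in timepoints}
    for li, cl in enumerate(cliques):
        for t in cl:
            labels[t].append(letters[li])
    return {t: "".join(sorted(labels[t])) for t in timepoints}


def canonical_pattern_key(labels_in_time_order: list[str]) -> str:
    """Pattern key invariant to arbitrary clique naming.

    Letters are re-indexed by first appearance scanning timepoints in time
    order, so two features with the same grouping structure map to the same
    key regardless of which clique got which letter.
    """
    mapping: dict[str, str] = {}
    letters = string.ascii_lowercase
    for lab in labels_in_time_order:
        for ch in lab:
            if ch not in mapping:
                mapping[ch] = letters[len(mapping)]
    return "|".join("".join(sorted(mapping[ch] for ch in lab)) for lab in labels_in_time_order)


def letters_table(
    pairwise: pd.DataFrame,
    timepoints: list[float],
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Per-feature letter labels and canonical pattern keys.

    ``pairwise`` is the long frame from :func:`pairwise_timepoints`.
    """
    cols = [timepoint_label(t) for t in timepoints]
    rows = []
    for feat, grp in pairwise.groupby("feature", sort=False):
        pair_p = {
            (r.t_a, r.t_b): r.p_adj for r in grp.itertuples(index=False)
        }
        lab = significance_letters(pair_p, timepoints, alpha=alpha)
        in_order = [lab[t] for t in timepoints]
        rows.append(
            dict(zip(cols, in_order), feature=feat,
                 pattern_key=canonical_pattern_key(in_order))
        )
    out = pd.DataFrame(rows).set_index("feature")
    return out[cols + ["pattern_key"]]


# ---------------------------------------------------------------------------
# DE-pattern grouping
# ---------------------------------------------------------------------------

def pattern_grouping(
    letters: pd.DataFrame,
    ft: pd.DataFrame,
    design: SampleDesign,
    top_fraction: float = 0.9,
    mode: str = "cumulative",
) -> dict[str, pd.DataFrame]:
    """Group features by canonical DE pattern.

    Features are first restricted to the most highly expressed: with
    ``mode="cumulative"`` (default) the descending-total prefix holding
    ``top_fraction`` of summed expression, with ``mode="quantile"`` the
    features above the ``1 - top_fraction`` total-expression quantile.
    Returns ``summary`` (per pattern: feature count, mean expression per
    timepoint) and ``contributions`` (per pattern, per family: proportion of
    the pattern's total expression).
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    totals = ft.loc[letters.index].sum(axis=1).sort_values(ascending=False)
    if mode == "cumulative":
        share = totals.cumsum() / totals.sum()
        n_keep = int(np.searchsorted(share.to_numpy(), top_fraction) + 1)
        kept = totals.index[:n_keep]
    elif mode == "quantile":
        cut = totals.quantile(1 - top_fraction)
        kept = totals.index[totals >= cut]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    sub_letters = letters.loc[list(kept)]
    sub_ft = ft.loc[list(kept)]
    tps = design.timepoints
    tp_cols = {}
    for t in tps:
        samples = design.table.index[
            (design.table["timepoint_h"] == t)
        ]
        samples = [s for s in samples if s in sub_ft.columns]
        tp_cols[timepoint_label(t)] = sub_ft[samples].mean(axis=1)
    tp_expr = pd.DataFrame(tp_cols)

    summary_rows = []
    contrib_rows = []
    for key, grp in sub_letters.groupby("pattern_key", sort=True):
        feats = grp.index
        expr = tp_expr.loc[feats].sum(axis=0)
        summary_rows.append(
            {"pattern_key": key, "n_features": len(feats),
             "total_expression": float(sub_ft.loc[feats].to_numpy().sum()),
             **{c: float(expr[c]) for c in tp_expr.columns}}
        )
        fam_tot = sub_ft.loc[feats].groupby(level="family").sum().sum(axis=1)
        shares = fam_tot / fam_tot.sum() if fam_tot.sum() > 0 else fam_tot * np.nan
        for fam, s in shares.items():
            contrib_rows.append(
                {"pattern_key": key, "family": fam, "proportion": float(s)}
            )
    summary = pd.DataFrame(summary_rows).sort_values(
        "total_expression", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    contributions = pd.DataFrame(contrib_rows)
    return {"summary": summary, "contributions": contributions, "kept_features": sub_letters}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DEResult:
    feature_table: pd.DataFrame
    screen: pd.DataFrame
    pairwise: pd.DataFrame
    letters: pd.DataFrame
    patterns: dict[str, pd.DataFrame]


def run_de(
    table: ExpressionTable,
    design: SampleDesign,
    alpha: float = 0.1,
    top_fraction: float = 0.9,
    engine: str = "surrogate",
    external_pvalues: dict[str, pd.DataFrame] | None = None,
) -> DEResult:
    """Full temporal DE stage.

    With ``engine="external"``, ``external_pvalues`` must provide ``screen``
    (indexed like the feature table, columns ``p_time`` and ``p_animal``) and
    ``pairwise`` (long frame with ``feature``, ``t_a``, ``t_b``, ``p``); BH
    adjustment and all downstream steps are then identical to the surrogate
    path.
    """
    ft = summarize_features(table)
    non_base = [s for s in ft.columns if design.table.loc[s, "timepoint_h"] != 0]
    ft = ft[non_base]
    tps = design.timepoints

    if engine == "surrogate":
        screen = test_time_effect(ft, design, alpha=alpha)
    elif engine == "external":
        if external_pvalues is None or "screen" not in external_pvalues:
            raise ValueError("external engine requires external_pvalues['screen']")
        ext = external_pvalues["screen"].reindex(ft.index)
        screen = ext[["p_time", "p_animal"]].copy()
        screen["p_adj_time"] = multipletests(screen["p_time"], method="fdr_bh")[1]
        screen["p_adj_animal"] = multipletests(screen["p_animal"], method="fdr_bh")[1]
        screen["excluded_animal"] = screen["p_adj_animal"] < alpha
        screen["significant_time"] = (screen["p_adj_time"] < alpha) & ~screen["excluded_animal"]
    else:
        raise ValueError(f"unknown engine {engine!r}")

    sig = list(screen.index[screen["significant_time"]])
    if engine == "external" and external_pvalues is not None and "pairwise" in external_pvalues:
        raw = external_pvalues["pairwise"]
        raw = raw[raw["feature"].isin(sig)]
        rows = []
        for feat, grp in raw.groupby("feature", sort=False):
            adj = multipletests(grp["p"].to_numpy(), method="fdr_bh")[1]
            for (_, r), pa in zip(grp.iterrows(), adj):
                rows.append({"feature": feat, "t_a": r["t_a"], "t_b": r["t_b"],
                             "p": r["p"], "p_adj": float(pa)})
        pairwise = pd.DataFrame(rows)
    else:
        pairwise = pairwise_timepoints(ft, design, features=sig)

    if len(pairwise):
        letters = letters_table(pairwise, tps, alpha=alpha)
        patterns = pattern_grouping(letters, ft, design, top_fraction=top_fraction)
    else:
        cols = [timepoint_label(t) for t in tps] + ["pattern_key"]
        letters = pd.DataFrame(columns=cols, index=pd.Index([], name="feature"))
        patterns = {"summary": pd.DataFrame(), "contributions": pd.DataFrame(),
                    "kept_features": letters}
    return DEResult(feature_table=ft, screen=screen, pairwise=pairwise,
                    letters=letters, patterns=patterns)
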