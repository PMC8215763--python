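"""TPM-based temporal profiling of glycoside hydrolase (GH), peptidase and
LuxS (AI-2 quorum-sensing) gene families.

Counts are normalised to transcripts per million over the entire
transcriptome (length in kilobases, then depth), summed per enzyme family per
sample (per taxonomic family for LuxS), restricted to the 95% most highly
expressed families of each type, tested for a time effect by two-way
fixed-effects ANOVA (time + animal, no interaction) with Benjamini-Hochberg
correction at 0.1, and lettered across timepoints with Tukey's HSD using the
same maximal-clique letter construction as the temporal DE stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_tables import ExpressionTable, SampleDesign, timepoint_label
from .temporal_de import significance_letters

_MEROPS_RE = re.compile(r"^[ACGIMNPSTU]\d+[a-z]?$", re.IGNORECASE)


def classify_tag(tag: str | float | None) -> str | None:
    """Enzyme type of an annotation tag: ``GH``, ``peptidase`` or ``LuxS``."""
    if tag is None or pd.isna(tag) or tag == "":
        return None
    tag = str(tag)
    if tag.upper().startswith("GH"):
        return "GH"
    if tag.lower() == "luxs":
        return "LuxS"
    if _MEROPS_RE.match(tag):
        return "peptidase"
    return None


def compute_tpm(table: ExpressionTable) -> pd.DataFrame:
    """Transcripts per million for every gene, over the entire table.

    ``rate = count / length_kb``; ``TPM = rate / sum(rate) * 1e6`` per sample,
    so each sample column sums to 1e6.
    """
    lengths_kb = table.gene_meta["length_bp"].to_numpy(dtype=float) / 1000.0
    rate = table.counts.to_numpy(dtype=float) / lengths_kb[:, None]
    col = rate.sum(axis=0)
    if (col == 0).any():
        s = table.counts.columns[np.where(col == 0)[0][0]]
        raise ValueError(f"sample {s!r} has zero total expression")
    tpm = rate / col * 1e6
    return pd.DataFrame(tpm, index=table.counts.index, columns=table.counts.columns)


def sum_by_enzyme_family(tpm: pd.DataFrame, gene_meta: pd.DataFrame) -> pd.DataFrame:
    """Summed TPM per enzyme family per sample.

    Rows are indexed by (enzyme_type, unit): for GH and peptidase the unit is
    the enzyme family tag (e.g. ``GH5``, ``M24``); for LuxS the per-taxon sums
    are kept, so the unit is the taxonomic family expressing LuxS.  Untagged
    genes contribute to nothing.
    """
    etype = gene_meta["enzyme_tag"].map(classify_tag)
    tagged = etype.notna()
    if not tagged.any():
        return pd.DataFrame(
            index=pd.MultiIndex.from_tuples([], names=["enzyme_type", "unit"]),
            columns=tpm.columns,
        )
    unit = gene_meta["enzyme_tag"].astype("object").where(etype != "LuxS",
                                                          gene_meta["family"])
    sub = tpm[tagged.to_numpy()]
    sums = sub.groupby([etype[tagged], unit[tagged]]).sum()
    sums.index.names = ["enzyme_type", "unit"]
    return sums.sort_index()


def top95_filter(sums: pd.DataFrame, fraction: float = 0.95) -> pd.DataFrame:
    """Retain, per enzyme type, the most highly expressed families.

    Families of a type are sorted by total TPM descending and the minimal
    prefix whose cumulative share reaches ``fraction`` is kept.  LuxS rows
    pass through unfiltered (every expressing taxon is analysed).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    kept = []
    for etype in sums.index.get_level_values("enzyme_type").unique():
        block = sums.loc[etype]
        if etype == "LuxS":
            kept.extend((etype, u) for u in block.index)
            continue
        totals = block.sum(axis=1).sort_values(ascending=False, kind="mergesort")
        share = totals.cumsum() / totals.sum()
        n_keep = int(np.searchsorted(share.to_numpy(), fraction) + 1)
        kept.extend((etype, u) for u in totals.index[:n_keep])
    return sums.loc[[k for k in sums.index if k in set(kept)]]


# ---------------------------------------------------------------------------
# two-way fixed-effects ANOVA (time + animal, balanced design)
# ---------------------------------------------------------------------------

def _anova_groups(design: SampleDesign, samples: list[str]):
    sub = design.table.loc[samples]
    if (sub["timepoint_h"] == 0).any():
        raise ValueError("baseline (0 h) samples must be excluded from the ANOVA")
    tps = sorted(sub["timepoint_h"].unique())
    animals = sorted(sub["animal_id"].unique())
    if len(tps) < 2 or len(animals) < 2:
        raise ValueError("ANOVA requires >= 2 animals and >= 2 timepoints")
    cells = sub.groupby(["animal_id", "timepoint_h"]).size()
    if len(cells) != len(tps) * len(animals) or (cells != 1).any():
        raise ValueError("ANOVA requires a balanced complete animal x timepoint design")
    t_idx = np.array([tps.index(float(sub.loc[s, "timepoint_h"])) for s in samples])
    a_idx = np.array([animals.index(sub.loc[s, "animal_id"]) for s in samples])
    return tps, animals, t_idx, a_idx


def anova_time(sums: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Time F and p per enzyme family from the additive two-way ANOVA.

    The replicate unit is the animal x timepoint summed TPM.  On a balanced
    design SS_total = SS_time + SS_animal + SS_residual exactly.  Families
    with zero variance return F = 0, p = 1.  BH adjustment runs across all
    rows of ``sums``.
    """
    samples = [s for s in sums.columns if design.table.loc[s, "timepoint_h"] != 0]
    tps, animals, t_idx, a_idx = _anova_groups(design, samples)
    y = sums[samples].to_numpy(dtype=float)
    n_t, n_a = len(tps), len(animals)
    grand = y.mean(axis=1, keepdims=True)
    t_means = np.stack([y[:, t_idx == k].mean(axis=1) for k in range(n_t)], axis=1)
    a_means = np.stack([y[:, a_idx == k].mean(axis=1) for k in range(n_a)], axis=1)
    ss_time = n_a * ((t_means - grand) ** 2).sum(axis=1)
    ss_animal = n_t * ((a_means - grand) ** 2).sum(axis=1)
    ss_total = ((y - grand) ** 2).sum(axis=1)
    ss_resid = np.maximum(ss_total - ss_time - ss_animal, 0.0)
    df_time = n_t - 1
    df_resid = (n_t - 1) * (n_a - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_time / df_time) / (ss_resid / df_resid)
    p = stats.f.sf(f, df_time, df_resid)
    null = ss_time <= 1e-12 * np.maximum(1.0, ss_total)
    f = np.where(null, 0.0, f)
    p = np.where(null, 1.0, p)
    exact = (ss_resid <= 1e-12 * np.maximum(1.0, ss_total)) & ~null
    p = np.where(exact, 0.0, p)

    out = pd.DataFrame({"F": f, "p": p}, index=sums.index)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < 0.1
    return out


def tukey_pairwise(
    values: pd.Series, design: SampleDesign
) -> dict[tuple[float, float], float]:
    """Tukey-Kramer pairwise p-values across timepoints for one family.

    ``q = |mean_i - mean_j| / sqrt((MSE/2) (1/n_i + 1/n_j))`` with MSE and
    residual df from the additive time + animal model; p from the studentized
    range distribution with k = number of timepoints.  For k = 2 this equals
    the pooled two-sample t-test (q = sqrt(2) |t|).
    """
    samples = [s for s in values.index if design.table.loc[s, "timepoint_h"] != 0]
    tps, animals, t_idx, a_idx = _anova_groups(design, samples)
    y = values[samples].to_numpy(dtype=float)
    n_t, n_a = len(tps), len(animals)
    grand = y.mean()
    t_means = np.array([y[t_idx == k].mean() for k in range(n_t)])
    a_means = np.array([y[a_idx == k].mean() for k in range(n_a)])
    ss_total = ((y - grand) ** 2).sum()
    ss_resid = max(
        ss_total - n_a * ((t_means - grand) ** 2).sum()
        - n_t * ((a_means - grand) ** 2).sum(),
        0.0,
    )
    df_resid = (n_t - 1) * (n_a - 1)
    mse = ss_resid / df_resid
    out: dict[tuple[float, float], float] = {}
    for i, j in combinations(range(n_t), 2):
        diff = abs(t_means[i] - t_means[j])
        se = np.sqrt((mse / 2.0) * (2.0 / n_a))  # n_i = n_j = n_a replicates
        if se == 0:
            p = 1.0 if diff <= 1e-12 else 0.0
        else:
            q = diff / se
            p = float(stats.studentized_range.sf(q, k=n_t, df=df_resid))
        out[(tps[i], tps[j])] = p
    return out


def tukey_letters(
    values: pd.Series, design: SampleDesign, alpha: float = 0.05
) -> dict[float, str]:
    """Compact-letter significance groups across timepoints for one family."""
    samples = [s for s in values.index if design.table.loc[s, "timepoint_h"] != 0]
    tps = sorted(design.table.loc[samples, "timepoint_h"].unique())
    pair_p = tukey_pairwise(values, design)
    return significance_letters(pair_p, [float(t) for t in tps], alpha=alpha)


def taxon_contributions(
    tpm: pd.DataFrame, gene_meta: pd.DataFrame, design: SampleDesign
) -> pd.DataFrame:
    """Per-taxon share of each enzyme family's expression at each timepoint.

    Shares are computed per sample (taxon TPM within the enzyme family divided
    by the family total) and averaged over the animals of each timepoint, so
    shares per (enzyme family, timepoint) sum to 1; timepoints where the
    enzyme family is entirely silent are emitted with missing shares.
    """
    etype = gene_meta["enzyme_tag"].map(classify_tag)
    mask = etype.isin(["GH", "peptidase"])
    if not mask.any():
        return pd.DataFrame(
            columns=["enzyme_type", "enzyme_family", "timepoint_h", "family", "proportion"]
        )
    sub = tpm[mask.to_numpy()]
    meta = gene_meta[mask.to_numpy()]
    by = sub.groupby([etype[mask], meta["enzyme_tag"], meta["family"]]).sum()
    by.index.names = ["enzyme_type", "enzyme_family", "family"]

    rows = []
    non_base = design.table[design.table["timepoint_h"] != 0]
    for (et, ef), block in by.groupby(level=["enzyme_type", "enzyme_family"]):
        taxa = block.index.get_level_values("family")
        for t in sorted(non_base["timepoint_h"].unique()):
            samples = [s for s in non_base.index[non_base["timepoint_h"] == t]
                       if s in block.columns]
            vals = block[samples].to_numpy(dtype=float)
            totals = vals.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                shares = vals / totals
            ok = totals > 0
            if ok.any():
                mean_share = shares[:, ok].mean(axis=1)
            else:
                mean_share = np.full(len(taxa), np.nan)
            for taxon, s in zip(taxa, mean_share):
                rows.append(
                    {"enzyme_type": et, "enzyme_family": ef, "timepoint_h": float(t),
                     "family": taxon, "proportion": float(s)}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnzymeResult:
    tpm_sums: pd.DataFrame
    retained: pd.DataFrame
    anova: pd.DataFrame
    letters: pd.DataFrame
    contributions: pd.DataFrame


def run_enzymes(
    table: ExpressionTable,
    design: SampleDesign,
    top_fraction: float = 0.95,
    alpha: float = 0.1,
    tukey_alpha: float = 0.05,
) -> EnzymeResult:
    """Full enzyme-profiling stage on the non-baseline samples."""
    tpm = compute_tpm(table)
    non_base = design.non_baseline_samples()
    sums = sum_by_enzyme_family(tpm[non_base], table.gene_meta)
    if sums.empty:
        empty = pd.DataFrame()
        return EnzymeResult(sums, sums, empty, empty, empty)
    retained = top95_filter(sums, fraction=top_fraction)
    anova = anova_time(retained, design)
    anova["significant"] = anova["p_adj"] < alpha

    tps = design.timepoints
    cols = [timepoint_label(t) for t in tps]
    letter_rows = []
    for key in anova.index[anova["significant"]]:
        lab = tukey_letters(retained.loc[key], design, alpha=tukey_alpha)
        letter_rows.append({"enzyme_type": key[0], "unit": key[1],
                            **{timepoint_label(t): lab[t] for t in tps}})
    letters = pd.DataFrame(letter_rows, columns=["enzyme_type", "unit"] + cols)
    contributions = taxon_contributions(tpm[non_base], table.gene_meta, design)
    return EnzymeResult(tpm_sums=sums, retained=retained, anova=anova,
                        letters=letters, contributions=contributions)
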