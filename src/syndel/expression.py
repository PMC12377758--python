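"""Count normalization, negative-binomial differential expression, and
dosage-compensation statistics.

Normalization uses median-of-ratios size factors. Differential expression
is a transparent per-gene NB log-linear model: the gene-wise dispersion is
estimated by maximizing the Cox-Reid adjusted profile likelihood (the
restricted-likelihood analogue for GLMs; plain ML dispersion is biased low
with few replicates and makes the Wald test anticonservative), the
genotype contrast is a Wald test referred to a t distribution with
residual degrees of freedom, and p-values are Benjamini-Hochberg adjusted
across genes. No empirical-Bayes shrinkage of dispersions or fold changes
is applied.

Dosage statistics follow the orthogroup logic of deletion studies: for
each orthogroup touched by a deletion, total normalized expression of the
member genes inside and outside the deleted region is compared between
wild-type and deletion genotypes.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

_LOG_ALPHA_BOUNDS = (np.log(1e-8), 3.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For genes whose geometric mean across samples is positive (i.e. no zero
    count), factor_j = median_g count_gj / geomean_g. Raises if any sample
    is all zeros or no gene is everywhere-positive.
    """
    if (counts < 0).to_numpy().any():
        raise ValueError("negative counts")
    if (counts.sum(axis=0) == 0).any():
        bad = counts.columns[counts.sum(axis=0) == 0].tolist()
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    log_counts = np.log(counts.where(counts > 0))
    log_geomean = log_counts.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError("no gene with positive counts in every sample")
    ratios = log_counts.loc[usable].sub(log_geomean.loc[usable], axis=0)
    sf = np.exp(ratios.median(axis=0))
    sf.name = "size_factor"
    return sf


def normalize(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts divided by per-sample size factors."""
    factors = size_factors(counts) if factors is None else factors
    return counts.div(factors, axis=1)


def _cr_dispersion(y: np.ndarray, design: np.ndarray) -> float:
    """Gene-wise NB dispersion maximizing the Cox-Reid adjusted profile
    likelihood, floored at 1e-8."""

    def neg_apl(log_alpha: float) -> float:
        alpha = float(np.exp(log_alpha))
        try:
            res = sm.GLM(y, design, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
        except Exception:
            return 1e12
        mu = res.mu
        w = mu / (1.0 + alpha * mu)
        _, logdet = np.linalg.slogdet(design.T @ (design * w[:, None]))
        return -(res.llf - 0.5 * logdet)

    res = optimize.minimize_scalar(neg_apl, bounds=_LOG_ALPHA_BOUNDS,
                                   method="bounded", options={"xatol": 1e-2})
    return float(np.exp(res.x))


def nb_test(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: tuple[str, str],
    group_col: str = "genotype",
    timepoint: str | None = None,
    factors: pd.Series | None = None,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-gene NB differential expression for one two-group contrast.

    ``contrast`` is (test_level, reference_level) of ``group_col``. When
    ``timepoint`` is given, only samples of that timepoint enter (each
    timepoint is analyzed as a separate contrast rather than an
    interaction model). Returns a frame indexed by gene with columns
    log2fc / pvalue / fdr / status / base_mean / dispersion.
    """
    test_level, ref_level = contrast
    sel = meta[group_col].isin([test_level, ref_level])
    if timepoint is not None:
        sel &= meta["timepoint"] == timepoint
    meta_sub = meta[sel]
    for level in contrast:
        if (meta_sub[group_col] == level).sum() < 2:
            raise ValueError(f"need >= 2 replicates in group {level!r}")
    sub = counts[meta_sub["sample"]]
    factors = size_factors(sub) if factors is None else factors[meta_sub["sample"]]
    offset = np.log(factors.to_numpy())
    design = np.column_stack([
        np.ones(len(meta_sub)),
        (meta_sub[group_col] == test_level).to_numpy(float),
    ])
    df_resid = len(meta_sub) - design.shape[1]

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for gene, y in sub.iterrows():
            y = y.to_numpy(float)
            base_mean = float(np.mean(y / factors.to_numpy()))
            if y.sum() == 0:
                rows.append((gene, np.nan, np.nan, base_mean, np.nan))
                continue
            try:
                alpha = _cr_dispersion(y, design)
                fit = sm.GLM(y, design, offset=offset,
                             family=sm.families.NegativeBinomial(alpha=alpha)).fit()
                coef, se = fit.params[1], fit.bse[1]
                p = 2.0 * stats.t.sf(abs(coef / se), df=df_resid) if se > 0 else np.nan
                rows.append((gene, coef / np.log(2.0), p, base_mean, alpha))
            except Exception:
                rows.append((gene, np.nan, np.nan, base_mean, np.nan))

    out = pd.DataFrame(rows, columns=["gene", "log2fc", "pvalue", "base_mean",
                                      "dispersion"]).set_index("gene")
    out["fdr"] = bh_adjust(out["pvalue"])
    sig = (out["fdr"] < fdr_threshold) & (out["log2fc"].abs() >= lfc_threshold)
    out["status"] = np.where(sig & (out["log2fc"] > 0), "up",
                             np.where(sig & (out["log2fc"] < 0), "down", "ns"))
    return out[["log2fc", "pvalue", "fdr", "status", "base_mean", "dispersion"]]


def bh_adjust(pvalues: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through."""
    out = pd.Series(np.nan, index=pvalues.index, dtype=float)
    mask = pvalues.notna()
    if mask.any():
        out[mask] = multipletests(pvalues[mask], method="fdr_bh")[1]
    return out


def orthogroup_dosage(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    orthogroups: pd.Series,
    region_genes: list[str],
    mutant: str,
    wt: str = "wt",
    group_col: str = "genotype",
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Orthogroup-level dosage summary for one mutant-vs-wt comparison.

    For every orthogroup containing at least one deleted gene, normalized
    counts of members inside and outside the deleted region are summed per
    sample; the mutant/wt ratio of group means and a two-sided Welch test
    on the out-of-region totals quantify compensation. A positive
    ``compensation`` signal shows as out_ratio > 1.
    """
    norm = normalize(counts, factors)
    region_set = set(region_genes)
    affected = sorted(set(orthogroups.loc[orthogroups.index.isin(region_set)]))
    wt_samples = meta.loc[meta[group_col] == wt, "sample"]
    mut_samples = meta.loc[meta[group_col] == mutant, "sample"]

    rows = []
    for og in affected:
        members = orthogroups.index[orthogroups == og]
        inside = [g for g in members if g in region_set and g in norm.index]
        outside = [g for g in members if g not in region_set and g in norm.index]
        in_tot = norm.loc[inside].sum(axis=0) if inside else pd.Series(0.0, index=norm.columns)
        out_tot = norm.loc[outside].sum(axis=0) if outside else pd.Series(0.0, index=norm.columns)
        wt_in, mut_in = in_tot[wt_samples].mean(), in_tot[mut_samples].mean()
        wt_out, mut_out = out_tot[wt_samples].mean(), out_tot[mut_samples].mean()
        if outside and out_tot[wt_samples].var() + out_tot[mut_samples].var() > 0:
            p = float(stats.ttest_ind(out_tot[mut_samples], out_tot[wt_samples],
                                      equal_var=False).pvalue)
        else:
            p = np.nan
        rows.append({
            "orthogroup": og, "n_inside": len(inside), "n_outside": len(outside),
            "wt_in_mean": wt_in, "mut_in_mean": mut_in,
            "in_ratio": mut_in / wt_in if wt_in > 0 else np.nan,
            "wt_out_mean": wt_out, "mut_out_mean": mut_out,
            "out_ratio": mut_out / wt_out if wt_out > 0 else np.nan,
            "comparison_p": p,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["comparison_fdr"] = bh_adjust(out["comparison_p"])
    return out


def paralogue_de(
    region_genes: list[str],
    paralogue_sources: dict[str, dict[str, list[str]]],
    de_results: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-paralogue differential expression of retained partners of
    deleted genes.

    ``paralogue_sources`` maps a source label (e.g. 'synteny',
    'orthogroup') to {deleted_gene: [retained paralogues]}. One row per
    (deleted gene, paralogue, source); ``compensating`` flags paralogues
    significantly up in the deletion line.
    """
    region_set = set(region_genes)
    rows = []
    for source, mapping in sorted(paralogue_sources.items()):
        for deleted in sorted(region_set):
            for para in sorted(mapping.get(deleted, [])):
                if para in region_set or para not in de_results.index:
                    continue
                r = de_results.loc[para]
                rows.append({
                    "deleted_gene": deleted, "paralogue": para, "source": source,
                    "log2fc": r["log2fc"], "fdr": r["fdr"], "status": r["status"],
                    "compensating": bool(r["status"] == "up" and r["fdr"] < fdr_threshold),
                })
    return pd.DataFrame(rows, columns=["deleted_gene", "paralogue", "source",
                                       "log2fc", "fdr", "status", "compensating"])


def log_counts_heatmap_table(
    og_counts: pd.DataFrame,
    block_orthogroups: set[str] | None = None,
) -> pd.DataFrame:
    """log2(count + 1) transform of an orthogroup-by-species gene-count
    table, keeping only orthogroups intersecting the focal block."""
    if (og_counts < 0).to_numpy().any():
        raise ValueError("negative count in orthogroup table")
    if block_orthogroups is not None:
        og_counts = og_counts.loc[og_counts.index.isin(block_orthogroups)]
    return np.log2(og_counts + 1)
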