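"""Coexpression-network analyses around deleted gene sets.

Covers module membership statistics (hypergeometric enrichment with BH
correction and observed/expected log fold change), gene centrality as
weighted network connectivity (WNC, the sum of a gene's edge weights) with
a bootstrap null for gene-set means, connectivity-to-deletion logistic
regression with McFadden pseudo-R², single-gene exclusion reruns, and
edge-density filtering for visualization.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .expression import bh_adjust
from .models import CoexpressionNetwork


@dataclass
class RegressionResult:
    """One connectivity-vs-DE logistic regression row."""

    deletion_label: str
    comparison_label: str
    coef: float
    pvalue: float
    pseudo_r2: float
    fdr: float = np.nan
    significant: bool = False
    separation: bool = False

    def as_row(self) -> dict:
        return {
            "Deletion": self.deletion_label, "Comparison": self.comparison_label,
            "Coef.": self.coef, "pval": self.pvalue, "PR2": self.pseudo_r2,
            "FDR": self.fdr, "Significant": self.significant,
            "separation_flag": self.separation,
        }


def wnc(network: CoexpressionNetwork) -> pd.Series:
    """Weighted network connectivity: per-gene sum of incident edge
    weights (0 for isolated genes)."""
    degrees = dict(network.graph.degree(weight="weight"))
    return pd.Series({g: float(degrees.get(g, 0.0)) for g in network.nodes},
                     name="wnc").sort_index()


def module_enrichment(
    gene_list: list[str],
    network: CoexpressionNetwork,
    universe: list[str] | None = None,
    list_name: str = "list",
    pseudo_count: float = 0.5,
    alternative: str = "enrichment",
) -> pd.DataFrame:
    """Hypergeometric module enrichment of a gene list.

    Per module: the upper-tail hypergeometric p-value of the observed
    overlap (lower tail when ``alternative='depletion'``), BH-adjusted
    across the module family; expected = |list|*|module|/|universe|;
    log2(observed/expected) uses ``pseudo_count`` on a zero observed count
    (the raw observed count is also emitted).
    """
    universe = list(network.modules.index) if universe is None else universe
    uni_set = set(universe)
    outside = set(gene_list) - uni_set
    if outside:
        raise ValueError(f"gene list members outside the universe: {sorted(outside)[:3]}")
    list_set = set(gene_list)
    M, n_list = len(uni_set), len(list_set)
    rows = []
    for module in sorted(network.modules.unique()):
        members = {g for g in network.module_members(module) if g in uni_set}
        observed = len(members & list_set)
        expected = n_list * len(members) / M if M else np.nan
        if alternative == "enrichment":
            p = float(stats.hypergeom.sf(observed - 1, M, len(members), n_list))
        elif alternative == "depletion":
            p = float(stats.hypergeom.cdf(observed, M, len(members), n_list))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        obs_for_ratio = observed if observed > 0 else pseudo_count
        rows.append({
            "module": module, "list_name": list_name, "observed": observed,
            "expected": expected,
            "log2_obs_exp": float(np.log2(obs_for_ratio / expected)) if expected > 0 else np.nan,
            "pvalue": p,
        })
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["pvalue"])
    out["significant"] = out["fdr"] < 0.05
    return out


def centrality_bootstrap(
    network: CoexpressionNetwork,
    gene_set: list[str],
    n_boot: int = 10_000,
    seed: int = 0,
    wnc_values: pd.Series | None = None,
) -> tuple[float, float]:
    """Mean WNC of a gene set against a bootstrap null of random equal-size
    gene sets.

    Each of ``n_boot`` draws samples ``len(gene_set)`` genes without
    replacement from the full node universe (deleted genes are not
    excluded). The two-tailed p-value is the proportion of draws whose
    mean deviates from the bootstrap-distribution mean at least as much
    (in absolute value) as the observed mean does.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not gene_set:
        raise ValueError("gene_set must contain at least one gene")
    w = wnc(network) if wnc_values is None else wnc_values
    missing = set(gene_set) - set(w.index)
    if missing:
        raise ValueError(f"gene set members absent from network: {sorted(missing)[:3]}")
    k, universe = len(gene_set), w.to_numpy()
    if k > len(universe):
        raise ValueError("gene set larger than the network universe")
    observed = float(w.loc[list(gene_set)].mean())
    rng = np.random.default_rng(seed)
    # k smallest of random keys per row == a uniform draw without replacement
    keys = rng.random((n_boot, len(universe)))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    boot_means = universe[idx].mean(axis=1)
    null_mean = boot_means.mean()
    # epsilon guards the degenerate all-equal case against summation-order noise
    eps = 1e-12 * max(1.0, abs(null_mean))
    p = float(np.mean(np.abs(boot_means - null_mean) >= abs(observed - null_mean) - eps))
    return observed, p


def max_edge_to_set(network: CoexpressionNetwork, deleted_set: list[str]) -> pd.Series:
    """For each non-deleted gene, the strongest edge weight connecting it
    to any deleted gene (0 when none)."""
    deleted = set(deleted_set)
    missing = deleted - set(network.nodes)
    if missing:
        raise ValueError(f"deleted genes absent from network: {sorted(missing)[:3]}")
    out = {g: 0.0 for g in network.nodes if g not in deleted}
    for d in deleted:
        for nbr, attrs in network.graph[d].items():
            if nbr in deleted:
                continue
            w = float(attrs.get("weight", 0.0))
            if w > out[nbr]:
                out[nbr] = w
    return pd.Series(out, name="max_edge_to_deleted").sort_index()


def logistic_connectivity(
    weights: pd.Series,
    de_status: pd.Series,
    deletion_label: str = "",
    comparison_label: str = "",
) -> RegressionResult:
    """Logistic regression of DE status (binary) on connection strength to
    the deleted genes.

    Fit by iteratively reweighted least squares to the ML solution; Wald
    p-value for the slope; McFadden pseudo-R² = 1 - llf/llnull clipped to
    [0, 1). Complete or quasi-complete separation is flagged rather than
    silently reported with a diverged coefficient.
    """
    common = weights.index.intersection(de_status.index)
    x = weights.loc[common].to_numpy(float)
    y = de_status.loc[common].to_numpy(float)
    if y.min() == y.max():
        raise ValueError("DE status needs at least one positive and one negative outcome")
    if np.ptp(x) == 0:
        # degenerate design: the predictor carries no information
        return RegressionResult(deletion_label, comparison_label, np.nan, np.nan,
                                0.0, separation=True)
    X = sm.add_constant(x)
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200, tol=1e-10)
        except Exception:
            separation = True
            fit = sm.Logit(y, X).fit_regularized(disp=0, alpha=1e-8, maxiter=500)
        for w in caught:
            if "separation" in str(w.message).lower() or "convergence" in str(w.message).lower():
                separation = True
    coef = float(fit.params[1])
    try:
        p = float(fit.pvalues[1])
    except Exception:
        p = np.nan
    llf, llnull = float(fit.llf), float(sm.Logit(y, np.ones_like(y)).fit(disp=0).llf)
    pr2 = 1.0 - llf / llnull if llnull != 0 else 0.0
    pr2 = float(np.clip(pr2, 0.0, 1.0 - 1e-12))
    return RegressionResult(deletion_label, comparison_label, coef, p, pr2,
                            separation=separation)


def adjust_regressions(results: list[RegressionResult],
                       fdr_threshold: float = 0.05) -> pd.DataFrame:
    """BH-adjust a family of regression rows jointly (one invocation = one
    family) and return the summary table."""
    pvals = pd.Series([r.pvalue for r in results])
    fdr = bh_adjust(pvals)
    for r, q in zip(results, fdr):
        r.fdr = float(q) if np.isfinite(q) else np.nan
        r.significant = bool(np.isfinite(q) and q < fdr_threshold)
    return pd.DataFrame([r.as_row() for r in results])


def exclude_and_rerun(
    network: CoexpressionNetwork,
    excluded_gene: str,
    deleted_set: list[str],
    de_status: pd.Series,
    deletion_label: str = "",
    comparison_label: str = "",
) -> RegressionResult:
    """Drop every edge of one deleted gene, recompute connectivity to the
    deletion, and refit the logistic regression (the exclusion-rerun used
    to test whether a single hub drives the association)."""
    if excluded_gene not in network.nodes:
        raise ValueError(f"excluded gene {excluded_gene!r} absent from network")
    if excluded_gene not in set(deleted_set):
        raise ValueError("excluded gene must be part of the deleted set")
    pruned = network.copy()
    pruned.graph.remove_edges_from(list(pruned.graph.edges(excluded_gene)))
    remaining = [g for g in deleted_set if g != excluded_gene]
    w = max_edge_to_set(pruned, remaining)
    return logistic_connectivity(w, de_status, deletion_label, comparison_label)


def filter_density(network: CoexpressionNetwork,
                   target_edges_per_gene: float = 2.15) -> CoexpressionNetwork:
    """Keep the round(target * n_nodes) highest-weight edges (ties broken
    by lexicographic endpoint order), then drop genes left isolated."""
    if target_edges_per_gene <= 0:
        raise ValueError("target must be positive")
    n_keep = round(target_edges_per_gene * network.graph.number_of_nodes())
    edges = sorted(network.graph.edges(data="weight"),
                   key=lambda e: (-e[2], min(e[0], e[1]), max(e[0], e[1])))
    if n_keep >= len(edges):
        return network.copy()
    g = type(network.graph)()
    for u, v, w in edges[:n_keep]:
        g.add_edge(u, v, weight=w)
    kept_nodes = list(g.nodes)
    return CoexpressionNetwork(g, network.modules.loc[network.modules.index.isin(kept_nodes)])
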