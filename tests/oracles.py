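"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately naive: exhaustive enumeration, direct
formula evaluation, or generic numerical optimization, sharing no code
with the package paths it checks.
"""
from __future__ import annotations

import itertools
import math
from statistics import median

import numpy as np
from scipy import optimize


def max_collinear_chain(ranks_a, ranks_b, max_gap: int) -> int:
    """Length of the longest collinear chain by exhaustive subset search.

    A chain is a subsequence strictly increasing in rank_a, strictly
    monotone (either direction) in rank_b, with consecutive gaps at most
    ``max_gap`` on both sides. Feasible only for ~12 anchors.
    """
    n = len(ranks_a)
    pairs = sorted(zip(ranks_a, ranks_b))
    best = 1 if n else 0
    for r in range(2, n + 1):
        for combo in itertools.combinations(pairs, r):
            for sign in (1, -1):
                ok = True
                for (a1, b1), (a2, b2) in zip(combo, combo[1:]):
                    da, db = a2 - a1, (b2 - b1) * sign
                    if da <= 0 or da > max_gap or db <= 0 or db > max_gap:
                        ok = False
                        break
                if ok:
                    best = max(best, r)
                    break
    return best


def hypergeom_enrichment_p(universe: set, module: set, gene_list: set) -> float:
    """Upper-tail overlap probability by enumerating every equal-size draw."""
    observed = len(module & gene_list)
    n = len(gene_list)
    count = 0
    total = 0
    for draw in itertools.combinations(sorted(universe), n):
        total += 1
        if len(module & set(draw)) >= observed:
            count += 1
    return count / total


def size_factors_median_ratio(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors by direct per-sample loops."""
    n_genes, n_samples = counts.shape
    geomeans = []
    for g in range(n_genes):
        row = counts[g]
        if (row > 0).all():
            geomeans.append(math.exp(sum(math.log(c) for c in row) / n_samples))
        else:
            geomeans.append(0.0)
    factors = []
    for j in range(n_samples):
        ratios = [counts[g, j] / geomeans[g] for g in range(n_genes) if geomeans[g] > 0]
        factors.append(median(ratios))
    return np.array(factors)


def bh_stepup(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, direct step-up definition."""
    m = len(pvalues)
    order = np.argsort(pvalues)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, pvalues[idx] * m / rank)
        adj[idx] = running
    return adj


def logistic_mle(x: np.ndarray, y: np.ndarray):
    """Maximum-likelihood logistic fit by generic numerical optimization.

    Returns (intercept, slope, loglik).
    """

    def negll(beta):
        eta = beta[0] + beta[1] * x
        return float(np.sum(np.logaddexp(0.0, eta)) - np.sum(y * eta))

    res = optimize.minimize(negll, x0=np.zeros(2), method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 1000})
    res = optimize.minimize(negll, x0=res.x, method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 5000})
    return res.x[0], res.x[1], -res.fun


def kde_mode_gaussian(sample: np.ndarray, grid: np.ndarray) -> float:
    """Mode of a Gaussian-kernel density computed by direct summation with
    Silverman's factor (the scipy convention: std * (0.75 n)^(-1/5))."""
    sample = np.asarray(sample, dtype=float)
    h = sample.std(ddof=1) * (0.75 * len(sample)) ** (-0.2)
    dens = np.exp(-0.5 * ((grid[:, None] - sample[None, :]) / h) ** 2).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def tandem_groups_exhaustive(positions: dict[str, int], max_gap: int) -> list[set[str]]:
    """Transitive closure of the 'at most max_gap intervening genes'
    relation on one chromosome's same-family genes, by repeated scanning."""
    items = sorted(positions.items(), key=lambda kv: kv[1])
    groups: list[set[str]] = []
    for name, pos in items:
        joined = None
        for grp in groups:
            if any(abs(pos - positions[m]) - 1 <= max_gap for m in grp):
                grp.add(name)
                joined = grp
                break
        if joined is None:
            groups.append({name})
    # merge any groups linked transitively
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if any(abs(positions[a] - positions[b]) - 1 <= max_gap
                       for a in groups[i] for b in groups[j]):
                    groups[i] |= groups[j]
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    return [g for g in groups if len(g) >= 2]
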