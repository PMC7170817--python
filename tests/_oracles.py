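"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from the defining formulas, without
importing the implementation paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def ensemble_oracle(consequence: str, calls: list[str]) -> tuple[str, str]:
    """(verdict, basis) for the deleteriousness rule, re-derived from scratch.

    calls are 'D'/'N'/'.' strings for the five algorithms.
    """
    protein = {
        "missense", "frameshift", "inframe_indel", "start_lost", "stop_gained", "splice_site",
    }
    by_class = {"frameshift", "inframe_indel", "start_lost", "stop_gained", "splice_site"}
    if consequence not in protein:
        return "neutral", "not_protein_affecting"
    if consequence in by_class:
        return "deleterious", "lof_class"
    available = [c for c in calls if c != "."]
    if not available:
        return "unscored", "no_calls"
    k = available.count("D")
    if 2 * k >= len(available):  # k/m >= 1/2 without float division
        return "deleterious", "ensemble"
    return "neutral", "ensemble"


def ld_oracle(counts4) -> dict:
    """D, D', r2 evaluated directly from the definitions."""
    c = np.asarray(counts4, dtype=float)
    f = c / c.sum()
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    D = f[0] - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = math.nan if denom == 0 else D * D / denom
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = 0.0 if D == 0 else (math.nan if dmax == 0 else abs(D) / dmax)
    return {"D": D, "d_prime": d_prime, "r2": r2}


def genotype_probs_oracle(f) -> np.ndarray:
    """3x3 genotype probabilities from haplotype frequencies, enumerated over
    ordered haplotype pairs."""
    haps = [(1, 1), (1, 0), (0, 1), (0, 0)]  # AB, Ab, aB, ab
    probs = np.zeros((3, 3))
    for i, (a1, b1) in enumerate(haps):
        for j, (a2, b2) in enumerate(haps):
            probs[a1 + a2, b1 + b2] += f[i] * f[j]
    return probs


def grid_max_log_likelihood(geno_counts: np.ndarray, step: float = 1e-3) -> float:
    """Max multinomial log-likelihood over a regular grid on the haplotype simplex.

    Maximizes the likelihood product directly (total genotype count is small),
    taking a single log at the end; vectorized over (f_Ab, f_aB) slices at
    fixed f_AB.
    """
    n = np.asarray(geno_counts, dtype=float)
    m = int(round(1.0 / step))
    j = np.arange(m + 1, dtype=np.float64)[:, None] / m  # f_Ab
    k = np.arange(m + 1, dtype=np.float64)[None, :] / m  # f_aB
    nonzero = [(g1, g2, n[g1, g2]) for g1 in range(3) for g2 in range(3) if n[g1, g2] > 0]
    best = 0.0
    for i in range(m + 1):
        f11 = i / m
        f00 = 1.0 - f11 - j - k
        valid = f00 >= -1e-12
        f00 = np.where(valid, np.maximum(f00, 0.0), 0.0)
        prod = np.ones_like(f00)
        for g1, g2, count in nonzero:
            if (g1, g2) == (2, 2):
                p = f11 * f11
            elif (g1, g2) == (2, 1):
                p = 2 * f11 * j
            elif (g1, g2) == (2, 0):
                p = j * j
            elif (g1, g2) == (1, 2):
                p = 2 * f11 * k
            elif (g1, g2) == (1, 1):
                p = 2 * f11 * f00 + 2 * j * k
            elif (g1, g2) == (1, 0):
                p = 2 * j * f00
            elif (g1, g2) == (0, 2):
                p = k * k
            elif (g1, g2) == (0, 1):
                p = 2 * k * f00
            else:
                p = f00 * f00
            prod = prod * np.power(p, count)
        prod = np.where(valid, prod, 0.0)
        cand = float(prod.max())
        if cand > best:
            best = cand
    return -math.inf if best <= 0.0 else math.log(best)


def anova_oracle(groups: list[list[float]]) -> tuple[float, float]:
    """One-way ANOVA F and p from the raw sum-of-squares decomposition."""
    from scipy.stats import f as fdist

    all_vals = [x for g in groups for x in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((x - sum(g) / len(g)) ** 2 for g in groups for x in g)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    if ssw == 0:
        return math.inf if ssb > 0 else 0.0, 1.0
    F = (ssb / df_b) / (ssw / df_w)
    return F, float(fdist.sf(F, df_b, df_w))


def pearson_oracle(x, y) -> float:
    """Pearson r from the covariance formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def fst_moment_estimate(panel_freqs: np.ndarray) -> float:
    """Method-of-moments F_ST from latent panel frequencies.

    panel_freqs has shape (n_variants, n_panels); panels are i.i.d. draws with
    variance F * p * (1 - p) around the ancestral p, so the ratio of averaged
    sample variances to averaged p_bar(1 - p_bar), corrected for the K-panel
    mean bias E[pbar(1-pbar)] = p(1-p)(1 - F/K), recovers F.
    """
    q = np.asarray(panel_freqs, dtype=float)
    K = q.shape[1]
    s2 = q.var(axis=1, ddof=1)
    pbar = q.mean(axis=1)
    raw = s2.sum() / (pbar * (1 - pbar)).sum()
    return raw / (1.0 + raw / K)
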