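"""Two-locus linkage disequilibrium from haplotypes or unphased genotypes.

For two biallelic loci with haplotype frequencies (p_AB, p_Ab, p_aB, p_ab),

    D  = p_AB - p_A * p_B
    D' = |D| / D_max,   D_max = min(p_A p_b, p_a p_B) for D > 0,
                        min(p_A p_B, p_a p_b) for D < 0
    r2 = D**2 / (p_A p_a p_B p_b).

With unphased genotype dosages the haplotype frequencies are estimated by
maximum likelihood with an EM algorithm over the double-heterozygote phase
ambiguity, assuming Hardy-Weinberg equilibrium (random union of haplotypes).
The observed-data log-likelihood is non-decreasing across EM iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import MonomorphicLocusError

#: Canonical haplotype order: (AB, Ab, aB, ab), A/B the alternate alleles.
HAPLOTYPES = ("AB", "Ab", "aB", "ab")


@dataclass
class LDResult:
    hap_freqs: tuple[float, float, float, float]
    D: float
    d_prime: float
    r2: float
    em_iterations: int = 0
    converged: bool = True
    monomorphic: bool = False
    loglik: float = math.nan
    loglik_trace: tuple[float, ...] = field(default_factory=tuple, repr=False)

    @property
    def p_A(self) -> float:
        return self.hap_freqs[0] + self.hap_freqs[1]

    @property
    def p_B(self) -> float:
        return self.hap_freqs[0] + self.hap_freqs[2]


def _ld_measures(f: np.ndarray) -> tuple[float, float, float, bool]:
    """(D, D', r2, monomorphic) from a haplotype-frequency vector."""
    p_a1 = f[0] + f[1]  # alt at locus 1
    p_b1 = f[0] + f[2]  # alt at locus 2
    q1 = 1.0 - p_a1
    q2 = 1.0 - p_b1
    D = f[0] - p_a1 * p_b1
    denom = p_a1 * q1 * p_b1 * q2
    if denom <= 0.0:
        return float(D), math.nan, math.nan, True
    r2 = min(D * D / denom, 1.0)  # clip float round-off at the boundary
    if D > 0:
        d_max = min(p_a1 * q2, q1 * p_b1)
    elif D < 0:
        d_max = min(p_a1 * p_b1, q1 * q2)
    else:
        return 0.0, 0.0, 0.0, False
    d_prime = min(abs(D) / d_max, 1.0)
    return float(D), float(d_prime), float(r2), False


def ld_from_haplotypes(counts: Sequence[float]) -> LDResult:
    """Closed-form LD from observed counts of the four haplotypes (AB, Ab, aB, ab)."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (4,) or (c < 0).any():
        raise ValueError("expected four non-negative haplotype counts")
    total = c.sum()
    if total <= 0:
        raise ValueError("total haplotype count must be positive")
    f = c / total
    D, d_prime, r2, mono = _ld_measures(f)
    return LDResult(
        hap_freqs=tuple(f.tolist()),
        D=D,
        d_prime=d_prime,
        r2=r2,
        monomorphic=mono,
    )


def genotype_class_probs(f: Sequence[float]) -> np.ndarray:
    """3x3 genotype-class probabilities P[g1, g2] under random haplotype union."""
    fAB, fAb, faB, fab = f
    return np.array(
        [
            [fab**2, 2 * faB * fab, faB**2],
            [2 * fAb * fab, 2 * fAB * fab + 2 * fAb * faB, 2 * fAB * faB],
            [fAb**2, 2 * fAB * fAb, fAB**2],
        ]
    )


def genotype_log_likelihood(geno_counts: np.ndarray, f: Sequence[float]) -> float:
    """Multinomial log-likelihood of a 3x3 genotype count table given
    haplotype frequencies (HWE)."""
    probs = genotype_class_probs(f)
    n = np.asarray(geno_counts, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > 0, n * np.log(probs), 0.0)
    if np.isneginf(terms).any() or np.isnan(terms[np.asarray(n) > 0]).any():
        return -math.inf
    return float(terms.sum())


def genotype_counts(g1: Sequence[int], g2: Sequence[int]) -> np.ndarray:
    """Cross-tabulate two dosage vectors into a 3x3 table indexed [g1, g2]."""
    a = np.asarray(g1, dtype=int)
    b = np.asarray(g2, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need equal-length dosage vectors with n >= 2")
    if not (np.isin(a, (0, 1, 2)).all() and np.isin(b, (0, 1, 2)).all()):
        raise ValueError("dosages must lie in {0, 1, 2}")
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (a, b), 1)
    return table


def ld_from_genotypes(
    g1: Sequence[int],
    g2: Sequence[int],
    tol: float = 1e-10,
    max_iterations: int = 1000,
) -> LDResult:
    """EM maximum-likelihood haplotype frequencies and LD from unphased dosages.

    Starts from linkage equilibrium (products of observed allele frequencies)
    and iterates until the largest absolute frequency change falls below
    ``tol`` or ``max_iterations`` is reached (``converged`` records which).
    Without double heterozygotes the first M-step already counts haplotypes
    exactly. Monomorphic loci yield a flagged result with undefined r2.
    """
    n = genotype_counts(g1, g2)
    total = int(n.sum())
    p1 = float((n * np.arange(3)[:, None]).sum()) / (2 * total)  # alt freq, locus 1
    p2 = float((n * np.arange(3)[None, :]).sum()) / (2 * total)
    f = np.array(
        [p1 * p2, p1 * (1 - p2), (1 - p1) * p2, (1 - p1) * (1 - p2)], dtype=float
    )
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        D, d_prime, r2, _ = _ld_measures(f)
        return LDResult(
            hap_freqs=tuple(f.tolist()),
            D=D,
            d_prime=d_prime,
            r2=r2,
            monomorphic=True,
            loglik=genotype_log_likelihood(n, f),
        )

    trace = [genotype_log_likelihood(n, f)]
    converged = False
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        # E-step: expected haplotype counts; only (1,1) is phase-ambiguous
        cAB = 2 * n[2, 2] + n[2, 1] + n[1, 2]
        cAb = 2 * n[2, 0] + n[2, 1] + n[1, 0]
        caB = 2 * n[0, 2] + n[0, 1] + n[1, 2]
        cab = 2 * n[0, 0] + n[0, 1] + n[1, 0]
        dh = n[1, 1]
        if dh:
            coupling = f[0] * f[3]
            repulsion = f[1] * f[2]
            w = 0.5 if coupling + repulsion == 0 else coupling / (coupling + repulsion)
            cAB, cab = cAB + dh * w, cab + dh * w
            cAb, caB = cAb + dh * (1 - w), caB + dh * (1 - w)
        new = np.array([cAB, cAb, caB, cab], dtype=float) / (2 * total)
        delta = float(np.abs(new - f).max())
        f = new
        trace.append(genotype_log_likelihood(n, f))
        if delta < tol:
            converged = True
            break

    D, d_prime, r2, mono = _ld_measures(f)
    return LDResult(
        hap_freqs=tuple(f.tolist()),
        D=D,
        d_prime=d_prime,
        r2=r2,
        em_iterations=iterations,
        converged=converged,
        monomorphic=mono,
        loglik=trace[-1],
        loglik_trace=tuple(trace),
    )


def pairwise_r2_matrix(
    genotypes: dict[str, Sequence[int]], threshold: float | None = None
) -> "pd.DataFrame":
    """Symmetric r2 matrix over named dosage vectors; optional block flagging.

    With ``threshold`` set, entries at or above it are additionally reported
    in a long-format frame of flagged pairs (returned as a DataFrame attr
    ``flagged``).
    """
    import pandas as pd

    names = list(genotypes)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    flagged = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = ld_from_genotypes(genotypes[a], genotypes[b])
            mat.loc[a, b] = mat.loc[b, a] = res.r2
            if threshold is not None and not math.isnan(res.r2) and res.r2 >= threshold:
                flagged.append({"variant_a": a, "variant_b": b, "r2": res.r2})
    mat.attrs["flagged"] = pd.DataFrame(flagged, columns=["variant_a", "variant_b", "r2"])
    return mat
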