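"""Diversity and neutrality statistics.

Haplotype diversity follows Nei: Hd = n/(n-1) * (1 - sum p_i^2) over
haplotype frequencies. Nucleotide diversity pi is the mean per-site
pairwise difference with pairwise deletion of gap/N sites. Tajima's D
uses the 1989 constants with S (not Eta) in the Watterson term; sites
containing any gap or missing base are excluded listwise for S and D,
matching the masked-pan workflow. Significance is flagged from the
beta-distribution approximation of D's null, two-tailed, at 0.05/0.01.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrix import AlignedMatrix
from .sites import classify_sites, collapse_haplotypes

_ACGT_MASK = np.zeros(256, dtype=bool)
for _b in b"ACGT":
    _ACGT_MASK[_b] = True

FLAG_UNDEFINED = "undefined"
FLAG_NS = "ns"
FLAG_05 = "p<0.05"
FLAG_01 = "p<0.01"


@dataclass
class TajimaResult:
    d: float          # nan when undefined (S == 0)
    p_flag: str
    S: int
    pi_total: float   # mean pairwise difference count over usable sites


@dataclass
class DiversityStats:
    n: int
    L: int            # listwise-complete sites used for S/Eta/D
    S: int
    Eta: int
    h: int
    Hd: float
    pi: float         # per-site, pairwise deletion
    tajima_d: float
    tajima_p_flag: str
    gap_mode: str


def _complete_columns(m: AlignedMatrix) -> np.ndarray:
    """Columns where every row is A/C/G/T (listwise deletion)."""
    return _ACGT_MASK[m.to_array()].all(axis=0)


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima (1989) for sample size n."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _mean_pairwise_differences(arr: np.ndarray) -> float:
    """Mean pairwise difference count over rows (columns assumed clean)."""
    n = arr.shape[0]
    total = 0
    for i in range(n - 1):
        total += (arr[i + 1:] != arr[i]).sum()
    return total / (n * (n - 1) / 2)


def _beta_p_flag(d: float, n: int, e2: float, a1: float) -> str:
    """Two-tailed significance flag for D via Tajima's beta approximation."""
    if e2 <= 0:
        return FLAG_NS
    dmin = (2.0 / n - 1.0 / a1) / math.sqrt(e2)
    dmax = (n / (2.0 * (n - 1.0)) - 1.0 / a1) / math.sqrt(e2)
    if not dmin < dmax:
        return FLAG_NS
    ab = dmin * dmax
    alpha = -(1.0 + ab) * dmax / (dmax - dmin)
    beta = (1.0 + ab) * dmin / (dmax - dmin)
    if alpha <= 0 or beta <= 0:
        return FLAG_NS
    x = (d - dmin) / (dmax - dmin)
    x = min(max(x, 0.0), 1.0)
    # density is (dmax-D)^(alpha-1) (D-dmin)^(beta-1): Beta(beta, alpha) in x
    cdf = stats.beta.cdf(x, beta, alpha)
    p = 2.0 * min(cdf, 1.0 - cdf)
    if p < 0.01:
        return FLAG_01
    if p < 0.05:
        return FLAG_05
    return FLAG_NS


def tajimas_d(m: AlignedMatrix) -> TajimaResult:
    """Tajima's D on listwise-complete sites; S = 0 yields an undefined
    result (NaN, flag ``undefined``) rather than an exception."""
    if m.n < 4:
        raise ValueError("Tajima's D needs n >= 4 sequences")
    keep = _complete_columns(m)
    arr = m.to_array()[:, keep]
    n = m.n
    cls = classify_sites(m.slice_columns(keep)) if keep.any() else None
    S = cls.S if cls is not None else 0
    if S == 0:
        return TajimaResult(float("nan"), FLAG_UNDEFINED, 0, 0.0)
    c = tajima_constants(n)
    pi_total = _mean_pairwise_differences(arr)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    d = (pi_total - S / c["a1"]) / math.sqrt(var)
    return TajimaResult(d, _beta_p_flag(d, n, c["e2"], c["a1"]), S, pi_total)


def nucleotide_diversity(m: AlignedMatrix) -> float:
    """pi: mean over pairs of (differences / comparable sites), pairwise
    deletion of gap/N columns."""
    arr = m.to_array()
    ok = _ACGT_MASK[arr]
    n = m.n
    ratios = []
    for i in range(n - 1):
        for j in range(i + 1, n):
            usable = ok[i] & ok[j]
            ns = int(usable.sum())
            if ns == 0:
                continue
            diff = int((arr[i, usable] != arr[j, usable]).sum())
            ratios.append(diff / ns)
    return float(np.mean(ratios)) if ratios else 0.0


def haplotype_diversity(m: AlignedMatrix, gap_mode: str = "gaps_as_state"
                        ) -> tuple[int, float]:
    """(h, Hd) with Hd = n/(n-1) (1 - sum p_i^2); Hd = 0 for a single haplotype."""
    haps = collapse_haplotypes(m, gap_mode)
    n = m.n
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    freq_sq = sum((h.count / n) ** 2 for h in haps)
    hd = n / (n - 1) * (1.0 - freq_sq)
    return len(haps), hd


def diversity_stats(m: AlignedMatrix, gap_mode: str = "gaps_as_state"
                    ) -> DiversityStats:
    """The per-alignment summary the pipeline reports: n, usable sites,
    S, Eta, haplotype count and diversity, pi, and Tajima's D with flag."""
    if m.n < 2:
        raise ValueError("diversity statistics need n >= 2 sequences")
    keep = _complete_columns(m)
    L = int(keep.sum())
    if L:
        cls = classify_sites(m.slice_columns(keep))
        S, eta = cls.S, cls.Eta
    else:
        S = eta = 0
    h, hd = haplotype_diversity(m, gap_mode)
    pi = nucleotide_diversity(m)
    if m.n >= 4:
        taj = tajimas_d(m)
        d, flag = taj.d, taj.p_flag
    else:
        d, flag = float("nan"), FLAG_UNDEFINED
    return DiversityStats(m.n, L, S, eta, h, hd, pi, d, flag, gap_mode)
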