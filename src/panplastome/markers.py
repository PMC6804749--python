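"""Rule-based selection of plastid barcode marker candidates.

A locus qualifies as a candidate when it (a) varies in at least four
groups, (b) collapses into more than four haplotypes across the
pan-plastomes, and (c) is neutral (non-significant Tajima's D). Candidate
sets are then verified to reproduce the whole-plastome phylogenetic
signal: the concatenated locus slices must yield a tree congruent with
the reference tree (Robinson-Foulds 0 and K-score below a threshold).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .matrix import AlignedMatrix, LocusTable
from .loci import LocusVariantReport
from .phylo import TreeComparison, compare_trees, nj_tree, pdistance_matrix
from .popgen import FLAG_NS, FLAG_UNDEFINED
from .sites import classify_sites

logger = logging.getLogger(__name__)

DEFAULT_MIN_GROUPS = 4
DEFAULT_MIN_H = 4          # criterion is h > 4
DEFAULT_KSCORE_MAX = 0.01


@dataclass
class MarkerCandidate:
    loci: tuple[str, ...]
    variable_in_groups: int
    h: int
    neutral: bool
    size_informative: bool = False
    n_snps: int = 0
    comparison: TreeComparison | None = None
    discriminated_groups: frozenset[str] = frozenset()
    signal_retrieved: bool | None = None


def select_candidates(reports: list[LocusVariantReport],
                      min_groups: int = DEFAULT_MIN_GROUPS,
                      min_h: int = DEFAULT_MIN_H,
                      size_deviation: dict[str, bool] | None = None,
                      ) -> tuple[list[MarkerCandidate], list[MarkerCandidate]]:
    """Apply the three marker criteria to per-locus reports.

    Returns ``(selected, unneutral)``: loci passing all criteria ranked by
    SNP count then haplotype count (both descending), and loci that failed
    only the neutrality criterion (the asterisked loci in reports).
    """
    selected, unneutral = [], []
    for r in reports:
        neutral = r.tajima_flag in (FLAG_NS, FLAG_UNDEFINED)
        cand = MarkerCandidate(
            loci=(r.locus,), variable_in_groups=r.variable_in_groups,
            h=r.h, neutral=neutral,
            size_informative=bool((size_deviation or {}).get(r.locus, False)),
            n_snps=r.n_snps)
        if r.variable_in_groups >= min_groups and r.h > min_h:
            (selected if neutral else unneutral).append(cand)
    selected.sort(key=lambda c: (-c.n_snps, -c.h, c.loci))
    unneutral.sort(key=lambda c: (-c.n_snps, -c.h, c.loci))
    return selected, unneutral


def concatenate_loci(m: AlignedMatrix, loci: LocusTable,
                     names: tuple[str, ...]) -> AlignedMatrix:
    """Concatenate the alignment slices of the named loci (order of names)."""
    cols: list[np.ndarray] = []
    for name in names:
        sel = loci.df[loci.df["name"] == name]
        if sel.empty:
            raise KeyError(f"locus {name!r} not in table")
        for _, rec in sel.iterrows():
            cols.append(np.arange(int(rec["start"]), int(rec["end"])))
    return m.slice_columns(np.concatenate(cols))


def _discriminated(m: AlignedMatrix) -> frozenset[str]:
    """Groups whose slice sequence differs from every other group's
    (N treated as wildcard)."""
    arr = m.to_array()
    n_char = ord("N")
    out = []
    for i, g in enumerate(m.ids):
        distinct = True
        for j in range(m.n):
            if j == i:
                continue
            eq = (arr[i] == arr[j]) | (arr[i] == n_char) | (arr[j] == n_char)
            if eq.all():
                distinct = False
                break
        if distinct:
            out.append(g)
    return frozenset(out)


def signal_check(candidate: MarkerCandidate, masked_pans: AlignedMatrix,
                 loci: LocusTable, reference_tree: dendropy.Tree,
                 gap_mode: str = "pairwise_deletion",
                 kscore_max: float = DEFAULT_KSCORE_MAX) -> MarkerCandidate:
    """Verify that the candidate loci reproduce the reference (whole
    pan-alignment) phylogenetic signal.

    Builds an NJ tree from the concatenated locus slices of the pan
    alignment and fills in congruence (K-score, RF) against the reference
    tree; ``signal_retrieved`` is True when RF = 0 and the K-score is
    below ``kscore_max``. A concatenation with zero variable sites leaves
    congruence undefined.
    """
    sub = concatenate_loci(masked_pans, loci, candidate.loci)
    if classify_sites(sub).S == 0:
        logger.warning("candidate %s has no variable sites; congruence undefined",
                       candidate.loci)
        return replace(candidate, comparison=None, signal_retrieved=False,
                       discriminated_groups=frozenset())
    dm = pdistance_matrix(sub, gap_mode=gap_mode)
    tree = nj_tree(dm)
    comp = compare_trees(reference_tree, tree)
    retrieved = comp.rf_distance == 0 and comp.k_score < kscore_max
    return replace(candidate, comparison=comp, signal_retrieved=retrieved,
                   discriminated_groups=_discriminated(sub))


def primer_windows(masked_pans: AlignedMatrix, loci: LocusTable,
                   names: tuple[str, ...], flank: int = 200) -> dict[str, str]:
    """Consensus-frame windows (locus +/- ``flank`` bp) for external primer
    design, keyed by locus name; first pan row is used as the template."""
    out = {}
    template = masked_pans.seqs[0]
    for name in names:
        rec = loci.get(name)
        s = max(0, int(rec["start"]) - flank)
        e = min(len(template), int(rec["end"]) + flank)
        out[name] = template[s:e]
    return out
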