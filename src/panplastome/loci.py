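"""Locus-level analysis of between-group variation.

Variants on the masked pan alignment are polarized against a designated
reference (outgroup) group: the reference allele is taken as ancestral and
each derived allele is classified by its carrier set — unique to one leaf
group, common to a named composite (carried by exactly its leaves), or
shared-unclassified. Amino-acid changes are called per CDS by translating
each pan against the reference with the bacterial/plastid genetic code
(translation table 11).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .matrix import AlignedMatrix, LocusTable, revcomp
from .pan import PROV_INDEL_MASKED, PanPlastome
from .popgen import FLAG_NS, FLAG_UNDEFINED, tajimas_d
from .sites import collapse_haplotypes

logger = logging.getLogger(__name__)

#: default functional-group prefixes for CDS rollups (editable)
FUNCTIONAL_PREFIXES = [
    "ndh", "rpo", "ycf", "rps", "rpl", "atp", "psa", "psb", "pet",
    "ccs", "mat", "rbc", "acc", "cem", "inf", "clp", "cha",
]

UNIQUE = "unique"
COMMON = "common"
SHARED = "shared-unclassified"


@dataclass
class GroupHierarchy:
    """Leaf groups, named composite groups (unions of leaves), and the
    reference (outgroup) group excluded from unique/common tallies."""

    leaves: list[str]
    composites: dict[str, frozenset[str]]
    reference: str

    def __post_init__(self) -> None:
        leafset = set(self.leaves)
        for name, members in self.composites.items():
            extra = set(members) - leafset
            if extra:
                raise ValueError(f"composite {name!r} names non-leaf groups {sorted(extra)}")
        if self.reference in leafset:
            raise ValueError("reference group must not be a leaf group")

    def composite_for(self, carriers: frozenset[str]) -> str | None:
        for name, members in self.composites.items():
            if carriers == members:
                return name
        return None


def functional_group(locus_name: str, prefixes: list[str] | None = None) -> str:
    name = locus_name.split("-")[0]
    for p in (prefixes or FUNCTIONAL_PREFIXES):
        if name.lower().startswith(p):
            return p
    return "other"


# ---------------------------------------------------------------------------
# SNP polarization and unique/common assignment


def polarize_snps(masked: AlignedMatrix, hier: GroupHierarchy) -> pd.DataFrame:
    """Table of derived alleles on the masked pan alignment.

    One row per (column, derived allele): reference allele, derived allele,
    carrier leaf-group set. Columns where the reference is N, or with no
    derived A/C/G/T allele, yield no rows; multi-allelic columns yield one
    row per derived state.
    """
    ref = hier.reference
    if ref not in masked.ids:
        raise ValueError(f"reference group {ref!r} not in pan alignment")
    arr = masked.to_array()
    ridx = masked.ids.index(ref)
    leaf_rows = [(g, masked.ids.index(g)) for g in hier.leaves]
    rows = []
    bases = frozenset(b"ACGT")
    for col in np.flatnonzero((arr != arr[ridx]).any(axis=0)):
        anc = arr[ridx, col]
        if anc not in bases:
            continue
        derived: dict[int, list[str]] = {}
        for g, i in leaf_rows:
            c = arr[i, col]
            if c in bases and c != anc:
                derived.setdefault(int(c), []).append(g)
        for allele, carriers in sorted(derived.items()):
            rows.append({"column": int(col), "ancestral": chr(anc),
                         "derived": chr(allele),
                         "carriers": frozenset(carriers)})
    return pd.DataFrame(rows, columns=["column", "ancestral", "derived", "carriers"])


def assign_unique_common(snp_table: pd.DataFrame, hier: GroupHierarchy) -> pd.DataFrame:
    """Label each derived allele unique-to-leaf / common-to-composite /
    shared-unclassified; every allele gets exactly one label."""
    out = snp_table.copy()
    labels, scopes = [], []
    for carriers in (out["carriers"] if not out.empty else []):
        if len(carriers) == 1:
            labels.append(UNIQUE)
            scopes.append(next(iter(carriers)))
        else:
            comp = hier.composite_for(carriers)
            if comp is not None:
                labels.append(COMMON)
                scopes.append(comp)
            else:
                labels.append(SHARED)
                scopes.append("")
    out["label"] = labels
    out["scope"] = scopes
    return out


# ---------------------------------------------------------------------------
# per-locus variant reports


@dataclass
class LocusVariantReport:
    locus: str
    cls: str
    n_snps: int
    n_indel_sites: int
    h: int
    tajima_d: float
    tajima_flag: str
    variable_in_groups: int
    unique_per_group: dict[str, int] = field(default_factory=dict)
    common_per_composite: dict[str, int] = field(default_factory=dict)
    n_shared_unclassified: int = 0
    uninformative: bool = False


def partition_variants_by_locus(masked: AlignedMatrix, loci: LocusTable,
                                hier: GroupHierarchy,
                                pans: list[PanPlastome] | None = None,
                                ) -> list[LocusVariantReport]:
    """Per-locus SNP/InDel-site counts, haplotype count, Tajima flag and
    unique/common tallies on the masked pan alignment.

    ``n_indel_sites`` counts columns flagged ``indel_masked`` in any pan
    when ``pans`` are supplied, else columns masked to N. A locus whose
    columns are all masked reports zeros and is flagged uninformative.
    """
    arr = masked.to_array()
    n_mask = (arr == ord("N")).any(axis=0)
    if pans is not None:
        indel_cols = np.zeros(masked.length, dtype=bool)
        for p in pans:
            indel_cols |= np.asarray(p.provenance) == PROV_INDEL_MASKED
    else:
        indel_cols = n_mask

    snps = assign_unique_common(polarize_snps(masked, hier), hier)
    reports = []
    for rec in loci:
        s, e = int(rec["start"]), int(rec["end"])
        sub = masked.slice_columns(np.arange(s, e))
        loc_snps = snps[(snps["column"] >= s) & (snps["column"] < e)] if not snps.empty else snps
        n_snps = int(loc_snps["column"].nunique()) if not loc_snps.empty else 0
        n_indel = int(indel_cols[s:e].sum())
        haps = collapse_haplotypes(sub, "gaps_as_state")
        taj = tajimas_d(sub) if sub.n >= 4 else None
        d = taj.d if taj else float("nan")
        flag = taj.p_flag if taj else FLAG_UNDEFINED
        uniq: dict[str, int] = {}
        common: dict[str, int] = {}
        shared = 0
        carrier_scopes: set[str] = set()
        if not loc_snps.empty:
            for _, row in loc_snps.iterrows():
                if row["label"] == UNIQUE:
                    uniq[row["scope"]] = uniq.get(row["scope"], 0) + 1
                    carrier_scopes.add(row["scope"])
                elif row["label"] == COMMON:
                    common[row["scope"]] = common.get(row["scope"], 0) + 1
                    carrier_scopes.add(row["scope"])
                else:
                    shared += 1
                    carrier_scopes.update(row["carriers"])
        all_masked = bool(n_mask[s:e].all())
        reports.append(LocusVariantReport(
            locus=str(rec["name"]), cls=str(rec["cls"]), n_snps=n_snps,
            n_indel_sites=n_indel, h=len(haps), tajima_d=d, tajima_flag=flag,
            variable_in_groups=len(carrier_scopes),
            unique_per_group=uniq, common_per_composite=common,
            n_shared_unclassified=shared, uninformative=all_masked))
    return reports


def reports_to_frame(reports: list[LocusVariantReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {"locus": r.locus, "class": r.cls, "n_snps": r.n_snps,
               "n_indel_sites": r.n_indel_sites, "h": r.h,
               "tajima_d": r.tajima_d, "tajima_flag": r.tajima_flag,
               "variable_in_groups": r.variable_in_groups,
               "n_shared_unclassified": r.n_shared_unclassified,
               "uninformative": r.uninformative,
               "functional_group": functional_group(r.locus)}
        for g, c in r.unique_per_group.items():
            row[f"unique_{g}"] = c
        for g, c in r.common_per_composite.items():
            row[f"common_{g}"] = c
        rows.append(row)
    return pd.DataFrame(rows).fillna(0)


# ---------------------------------------------------------------------------
# amino-acid changes


@dataclass(frozen=True)
class AAChange:
    locus: str
    codon_index: int
    from_aa: str
    to_aa: str
    carriers: frozenset[str]
    unique: bool
    scope: str  # carrier leaf group, composite name, or "" when unclassified


def amino_acid_changes(pans: list[PanPlastome], loci: LocusTable,
                       hier: GroupHierarchy,
                       exclude: tuple[str, ...] = ("accD", "rpl20", "ycf1"),
                       ) -> list[AAChange]:
    """Translate every CDS per pan (genetic code table 11) and report amino
    acids differing from the reference pan. Codons containing N, gaps or
    ambiguity codes are skipped; loci on the exclusion list (large InDel
    tracts by default) are not scanned; a CDS whose length is not a multiple
    of 3 is flagged and skipped."""
    by_group = {p.group: p for p in pans}
    ref = by_group.get(hier.reference)
    if ref is None:
        raise ValueError(f"no pan for reference group {hier.reference!r}")
    changes: dict[tuple[str, int, str, str], set[str]] = {}
    for rec in loci.of_class("CDS").itertuples():
        if rec.name in exclude:
            continue
        s, e = int(rec.start), int(rec.end)
        if (e - s) % 3 != 0:
            logger.warning("CDS %s length %d not divisible by 3; skipped",
                           rec.name, e - s)
            continue

        def codons(p: PanPlastome) -> list[str]:
            seq = p.sequence[s:e]
            if rec.strand == "-":
                seq = revcomp(seq)
            return [seq[i:i + 3] for i in range(0, len(seq), 3)]

        ref_codons = codons(ref)
        for g in hier.leaves:
            pan = by_group.get(g)
            if pan is None:
                continue
            for ci, (ca, cb) in enumerate(zip(ref_codons, codons(pan))):
                if ca == cb:
                    continue
                if set(ca + cb) - set("ACGT"):
                    continue  # N / ambiguity / gap in codon
                aa_a = str(Seq(ca).translate(table=11))
                aa_b = str(Seq(cb).translate(table=11))
                if aa_a != aa_b:
                    changes.setdefault((rec.name, ci, aa_a, aa_b), set()).add(g)
    out = []
    for (locus, ci, aa_a, aa_b), carriers in sorted(changes.items()):
        fs = frozenset(carriers)
        comp = hier.composite_for(fs)
        scope = next(iter(fs)) if len(fs) == 1 else (comp or "")
        out.append(AAChange(locus, ci, aa_a, aa_b, fs, len(fs) == 1, scope))
    return out


# ---------------------------------------------------------------------------
# locus size deviation


def locus_lengths(m: AlignedMatrix, loci: LocusTable) -> pd.DataFrame:
    """Per-group modal ungapped locus length from the member alignment
    (groups required). Rows: loci; columns: group labels."""
    if not m.groups:
        raise ValueError("locus lengths need group labels")
    arr = m.to_array()
    nongap = arr != ord("-")
    data = {}
    for g in m.group_labels():
        idx = [m.ids.index(a) for a in m.group_members(g)]
        lens = {}
        for rec in loci:
            vals = nongap[idx, int(rec["start"]):int(rec["end"])].sum(axis=1)
            v, counts = np.unique(vals, return_counts=True)
            lens[str(rec["name"])] = int(v[np.argmax(counts)])
        data[g] = lens
    return pd.DataFrame(data)


def locus_size_deviation(lengths: pd.DataFrame, reference_group: str,
                         threshold: float = 25.0) -> pd.DataFrame:
    """Mean absolute length deviation from the reference group per locus.

    ``deviation_avg`` = mean |len_g - len_ref| over the non-reference
    groups; loci above ``threshold`` bp are flagged ``pcr_suitable``
    (enough intraspecific length variation for gel-based genotyping).
    """
    if reference_group not in lengths.columns:
        raise ValueError(f"reference group {reference_group!r} not in length table")
    others = [c for c in lengths.columns if c != reference_group]
    dev = (lengths[others].sub(lengths[reference_group], axis=0)).abs().mean(axis=1)
    out = lengths.copy()
    out["deviation_avg"] = dev
    out["pcr_suitable"] = dev > threshold
    return out.sort_values("deviation_avg", ascending=False)


# ---------------------------------------------------------------------------
# hypervariability grading


_aligner = PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 2
_aligner.mismatch_score = -3
_aligner.open_gap_score = -5
_aligner.extend_gap_score = -2


def hypervariability_score(locus_consensus: str, pan_consensus: str) -> float:
    """Similarity of a locus consensus to its pan counterpart in [0, 1].

    Global alignment with match +2, mismatch -3, gap open -5, gap extend
    -2, normalized by 2 x query length and clamped. Identical sequences
    score 1; scores < 0.5 indicate InDel/SSR-driven divergence, >= 0.5
    SNP-only divergence.
    """
    if not locus_consensus or not pan_consensus:
        raise ValueError("empty sequence")
    score = _aligner.score(locus_consensus.upper(), pan_consensus.upper())
    norm = score / (2.0 * len(locus_consensus))
    return float(min(max(norm, 0.0), 1.0))


def hypervariability_band(score: float) -> str:
    """Plotting bands: <0.25 (least similar), 0.25-0.5 (InDel-driven),
    0.5-0.75 (SNP-only), >0.75 (very similar)."""
    if score < 0.25:
        return "<0.25"
    if score < 0.5:
        return "0.25-0.5"
    if score <= 0.75:
        return "0.5-0.75"
    return ">0.75"
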