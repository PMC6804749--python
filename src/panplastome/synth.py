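"""Synthetic plastome datasets with planted ground truth.

The generator emits an aligned accession matrix in one shared coordinate
frame (insertions pre-gapped in non-carriers, so no external aligner is
needed), a locus table tiling the genome, and a truth record from which
every planted feature — quadripartite structure, branch SNPs with carrier
clades, InDel events, SSR and tandem-repeat copy numbers, the haplotype
partition and the group tree — is recoverable by construction. A fixed
seed fully determines the output.

``emulate_study_shape`` is a preset with seven ingroup pepper-like groups
plus an outgroup (CP), a 44 bp tandem-repeat locus at 3-6 copies in
rpl23-trnI, an AT microsatellite spanning 30-101 bp in rps16-trnQ, and
branch SNPs placed so that the rps16-trnQ + rbcL-accD + ycf3-trnS trio
jointly covers every branch of the group tree.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

from .matrix import AlignedMatrix, LocusTable
from .structure import RegionPartition

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# truth containers


@dataclass(frozen=True)
class PlantedSNP:
    column: int
    ancestral: str
    derived: str
    branch: str
    carriers: frozenset[str]                # leaf groups below the branch
    carriers_vs_reference: frozenset[str]   # polarity relative to the outgroup


@dataclass(frozen=True)
class PlantedIndel:
    start: int
    end: int
    gapped_ids: frozenset[str]
    origin: str  # "indel", "ssr", or "tandem"


@dataclass
class SyntheticTruth:
    seed: int
    tree_newick: str
    groups: dict[str, str]
    haplotypes: dict[str, str]
    snps: list[PlantedSNP]
    indel_events: list[PlantedIndel]
    ssr: dict[str, Any] | None
    tandem: dict[str, Any] | None
    partition: RegionPartition
    params: dict[str, Any] = field(default_factory=dict)

    def haplotype_partition(self) -> set[frozenset[str]]:
        out: dict[str, set[str]] = {}
        for acc, hap in self.haplotypes.items():
            out.setdefault(hap, set()).add(acc)
        return {frozenset(v) for v in out.values()}

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, frozenset):
                return sorted(o)
            if isinstance(o, RegionPartition):
                return {"lsc": o.lsc, "ira": o.ira, "ssc": o.ssc,
                        "irb": o.irb, "rotation": o.rotation}
            if hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            raise TypeError(type(o))
        d = {k: v for k, v in self.__dict__.items()}
        return json.dumps(d, default=default, indent=1)


# ---------------------------------------------------------------------------
# genome backbone: quadripartite structure plus a locus tiling

# (name, class); sizes are drawn at generation time. Special loci carry
# minimum sizes so planted features and targeted SNPs fit.
_LSC_TEMPLATE = [
    ("psbA", "CDS"), ("psbA-trnK", "IGS"), ("trnK", "tRNA"), ("trnK", "intron"),
    ("matK", "CDS"), ("matK-rps16", "IGS"), ("rps16", "CDS"), ("rps16", "intron"),
    ("rps16-trnQ", "IGS"), ("trnQ", "tRNA"), ("trnQ-psbK", "IGS"), ("psbK", "CDS"),
    ("psbK-atpA", "IGS"), ("atpA", "CDS"), ("atpA-atpF", "IGS"), ("atpF", "CDS"),
    ("atpF", "intron"), ("atpF-atpH", "IGS"), ("atpH", "CDS"), ("atpH-atpI", "IGS"),
    ("atpI", "CDS"), ("atpI-rpoB", "IGS"), ("rpoB", "CDS"), ("rpoB-rpoC2", "IGS"),
    ("rpoC2", "CDS"), ("rpoC2-ndhC", "IGS"), ("ndhC", "CDS"), ("ndhC-trnV", "IGS"),
    ("trnV", "tRNA"), ("trnV-rbcL", "IGS"), ("rbcL", "CDS"), ("rbcL-accD", "IGS"),
    ("accD", "CDS"), ("accD-psaI", "IGS"), ("psaI", "CDS"), ("psaI-psaA", "IGS"),
    ("psaA", "CDS"), ("psaA-ycf3", "IGS"), ("ycf3", "CDS"), ("ycf3", "intron"),
    ("ycf3-trnS", "IGS"), ("trnS", "tRNA"), ("trnS-trnL", "IGS"), ("trnL", "tRNA"),
    ("trnL-trnF", "IGS"), ("trnF", "tRNA"), ("trnF-rpl20", "IGS"), ("rpl20", "CDS"),
    ("rpl20-rpl23", "IGS"), ("rpl23", "CDS"), ("rpl23-trnI", "IGS"), ("trnI", "tRNA"),
    ("trnI-rpl2", "IGS"), ("rpl2", "CDS"), ("rpl2-trnH", "IGS"),
]
_IRA_TEMPLATE = [("rrn16_a", "rRNA"), ("rrn16-rrn23_a", "IGS"), ("rrn23_a", "rRNA")]
_SSC_TEMPLATE = [
    ("ndhF", "CDS"), ("ndhF-rpl32", "IGS"), ("rpl32", "CDS"), ("rpl32-trnL2", "IGS"),
    ("trnL2", "tRNA"), ("trnL2-ndhA", "IGS"), ("ndhA", "CDS"), ("ndhA", "intron"),
    ("ndhA-ycf1", "IGS"), ("ycf1", "CDS"),
]
_IRB_TEMPLATE = [("rrn23_b", "rRNA"), ("rrn23-rrn16_b", "IGS"), ("rrn16_b", "rRNA")]

_MIN_SIZES = {
    "rps16-trnQ": 230, "rpl23-trnI": 300, "rbcL-accD": 160, "ycf3-trnS": 140,
    "psaA-ycf3": 160, "ndhC-trnV": 150, "trnL-trnF": 120, "atpH-atpI": 120,
    "rpoB": 180, "rpoC2": 150, "ndhF": 180, "matK": 150, "ycf1": 240,
    "rbcL": 150, "ndhA": 120, "accD": 120,
}
_BASE_MIN = {"CDS": 99, "intron": 70, "IGS": 70, "tRNA": 60, "rRNA": 90}


def _allocate(rng: np.random.Generator, template, budget: int) -> list[int]:
    mins = [max(_MIN_SIZES.get(n, 0), _BASE_MIN[c]) for n, c in template]
    rem = budget - sum(mins)
    if rem < 0:
        raise ValueError(f"region budget {budget} too small for locus template")
    extra = rng.multinomial(rem, np.full(len(mins), 1.0 / len(mins)))
    sizes = [m + int(e) for m, e in zip(mins, extra)]
    # keep CDS lengths divisible by 3 (remainder shifts to the next record)
    carry = 0
    for i, (name, cls) in enumerate(template):
        sizes[i] += carry
        carry = 0
        if cls == "CDS":
            carry = sizes[i] % 3
            sizes[i] -= carry
    if carry:  # template regions end in a non-CDS record except SSC (handled there)
        sizes[-1] += carry
    return sizes


def generate_plastome(genome_length: int = 15000, ir_length: int = 1500,
                      ssc_length: int | None = None, seed: int = 0,
                      ycf1_irb_overlap: int = 300,
                      ) -> tuple[str, RegionPartition, LocusTable]:
    """A random quadripartite plastome (no variation): LSC + IRa + SSC + IRb
    with IRb the exact reverse complement of IRa, plus a locus table tiling
    it. Boundary bases are fixed so the planted IR pair is not extendable,
    making it the unique longest inverted repeat."""
    rng = np.random.default_rng(seed)
    if ssc_length is None:
        ssc_length = genome_length * 3 // 20
    lsc_length = genome_length - 2 * ir_length - ssc_length
    if lsc_length <= ssc_length:
        raise ValueError("LSC must be longer than SSC; reduce ir/ssc lengths")
    if genome_length < 4 * ir_length:
        raise ValueError("genome_length must be >= 4 * ir_length")

    arr = _BASES[rng.integers(0, 4, genome_length)].copy()
    a = lsc_length                      # IRa start
    b = lsc_length + ir_length + ssc_length  # IRb start
    comp = np.zeros(256, dtype=np.uint8)
    for x, y in zip(b"ACGT", b"TGCA"):
        comp[x] = y
    arr[b:b + ir_length] = comp[arr[a:a + ir_length]][::-1]
    # forbid IR extension: (left of IRa, right of IRb wraps to 0) and
    # (right of IRa, left of IRb)
    while arr[0] == comp[arr[a - 1]]:
        arr[0] = _BASES[rng.integers(0, 4)]
    while arr[a + ir_length] == comp[arr[b - 1]]:
        arr[a + ir_length] = _BASES[rng.integers(0, 4)]

    part = RegionPartition((0, a), (a, a + ir_length), (a + ir_length, b),
                           (b, genome_length), rotation=0)

    rows = []
    pos = 0
    sizes_lsc = _allocate(rng, _LSC_TEMPLATE, lsc_length)
    for (name, cls), size in zip(_LSC_TEMPLATE, sizes_lsc):
        rows.append((name, cls, pos, pos + size, "+"))
        pos += size
    sizes_ira = _allocate(rng, _IRA_TEMPLATE, ir_length)
    for (name, cls), size in zip(_IRA_TEMPLATE, sizes_ira):
        rows.append((name, cls, pos, pos + size, "+"))
        pos += size
    # SSC: last record (ycf1) extends ycf1_irb_overlap bp into IRb
    sizes_ssc = _allocate(rng, _SSC_TEMPLATE, ssc_length)
    ycf1_total = sizes_ssc[-1] + ycf1_irb_overlap
    trim3 = ycf1_total % 3
    sizes_ssc[-1] -= trim3
    sizes_ssc[-2] += trim3
    for i, ((name, cls), size) in enumerate(zip(_SSC_TEMPLATE, sizes_ssc)):
        end = pos + size + (ycf1_irb_overlap if i == len(_SSC_TEMPLATE) - 1 else 0)
        rows.append((name, cls, pos, end, "+"))
        pos = end
    sizes_irb = _allocate(rng, _IRB_TEMPLATE, genome_length - pos)
    for (name, cls), size in zip(_IRB_TEMPLATE, sizes_irb):
        rows.append((name, cls, pos, pos + size, "+"))
        pos += size
    loci = LocusTable(pd.DataFrame(rows, columns=["name", "cls", "start", "end", "strand"]),
                      coord_system="frame", length=genome_length)
    return bytes(arr).decode("ascii"), part, loci


# ---------------------------------------------------------------------------
# group trees


@dataclass
class CladeNode:
    name: str
    children: list["CladeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [x for c in self.children for x in c.leaves()]

    def branches(self) -> list["CladeNode"]:
        """Every node except this (root): one entry per tree branch."""
        out = []
        for c in self.children:
            out.append(c)
            out.extend(c.branches())
        return out


def study_tree() -> CladeNode:
    """The study-shape group tree: ((CAA,CAG),((CC,CF),CG)) + (CCha,CB),
    rooted with CP as outgroup."""
    ca = CladeNode("CA", [CladeNode("CAA"), CladeNode("CAG")])
    ccf = CladeNode("CCF", [CladeNode("CC"), CladeNode("CF")])
    cfg = CladeNode("CFG", [ccf, CladeNode("CG")])
    a = CladeNode("A", [ca, cfg])
    b = CladeNode("B", [CladeNode("CCha"), CladeNode("CB")])
    stem = CladeNode("stem", [a, b])
    return CladeNode("root", [stem, CladeNode("CP")])


def random_group_tree(rng: np.random.Generator, names: list[str]) -> CladeNode:
    nodes = [CladeNode(n) for n in names]
    k = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        k += 1
        merged = CladeNode(f"clade{k}", [nodes[i], nodes[j]])
        nodes = [x for t, x in enumerate(nodes) if t not in (i, j)] + [merged]
    root = nodes[0]
    root.name = "root"
    return root


def _newick(node: CladeNode, branch_snps: dict[str, int]) -> str:
    def rec(n: CladeNode) -> str:
        if n.is_leaf:
            return f"{n.name}:{branch_snps.get(n.name, 0)}"
        inner = ",".join(rec(c) for c in n.children)
        if n.name == "root":
            return f"({inner})"
        return f"({inner}):{branch_snps.get(n.name, 0)}"
    return rec(node) + ";"


# ---------------------------------------------------------------------------
# dataset generation


#: branch -> locus names, two inside the marker trio and two outside, so the
#: concatenated trio carries every branch with lengths proportional to the
#: full alignment (the study's combined-set phenomenon, by construction).
STUDY_SNP_PLACEMENT = {
    "stem": ["rps16-trnQ", "rbcL-accD", "matK", "psbA-trnK"],
    "A":    ["rps16-trnQ", "rbcL-accD", "psaA-ycf3", "ndhF"],
    "CA":   ["rps16-trnQ", "ycf3-trnS", "trnL-trnF", "psaA-ycf3"],
    "CAA":  ["rps16-trnQ", "rbcL-accD", "atpH-atpI", "psaA-ycf3"],
    "CAG":  ["rps16-trnQ", "ycf3-trnS", "trnL-trnF", "atpH-atpI"],
    "CFG":  ["rbcL-accD", "ycf3-trnS", "ndhF", "rpoC2"],
    "CCF":  ["ycf3-trnS", "rbcL-accD", "ndhC-trnV", "rpoC2"],
    "CC":   ["rbcL-accD", "rbcL-accD", "ndhC-trnV", "psbA-trnK"],
    "CF":   ["ycf3-trnS", "ycf3-trnS", "trnQ-psbK", "atpA-atpF"],
    "CG":   ["ycf3-trnS", "rbcL-accD", "ndhC-trnV", "ndhF"],
    "B":    ["rps16-trnQ", "rbcL-accD", "rpoB", "ndhA"],
    "CCha": ["rbcL-accD", "rps16-trnQ", "rpoB", "trnK"],
    "CB":   ["rbcL-accD", "ycf3-trnS", "ycf1", "rpoB"],
    "CP":   ["rps16-trnQ", "rbcL-accD", "matK", "rpoB"],
}

#: planted amino-acid changes: (branch, CDS locus, codon, ref codon,
#: position in codon, derived base) — the first two recreate the study's
#: B-complex L->I and A-complex V->I pattern; the third is synonymous.
STUDY_AA_CHANGES = [
    ("B", "rpoB", 10, "CTT", 0, "A"),   # Leu -> Ile, common to the B complex
    ("A", "ndhF", 10, "GTT", 0, "A"),   # Val -> Ile, common to the A complex
    ("CP", "rpoB", 20, "GGA", 2, "G"),  # Gly -> Gly (synonymous control)
]

STUDY_TANDEM = {"locus": "rpl23-trnI", "unit_length": 44,
                "copies": {"CAA": 6, "CAG": 5, "CC": 4, "CF": 4, "CG": 3,
                           "CCha": 5, "CB": 6, "CP": 3}}
STUDY_SSR = {"locus": "rps16-trnQ", "motif": "AT",
             "lengths": {"CAA": 101, "CAG": 30, "CC": 44, "CF": 48, "CG": 60,
                         "CCha": 44, "CB": 44, "CP": 44}}


class FeatureCollisionError(RuntimeError):
    pass


def _free_column_in(rng, free: np.ndarray, lo: int, hi: int) -> int:
    cand = np.flatnonzero(free[lo:hi])
    if cand.size == 0:
        raise FeatureCollisionError(f"no free column in [{lo},{hi})")
    return int(lo + rng.choice(cand))


def generate_dataset(seed: int, n_groups: int = 7, accessions_per_group: int = 4,
                     genome_length: int = 15000, ir_length: int = 1500,
                     n_snps_per_branch: int = 3, n_indel_events: int = 4,
                     haplotypes_per_group: int = 2,
                     group_names: list[str] | None = None,
                     outgroup: str | None = None,
                     tree: CladeNode | None = None,
                     snp_placement: dict[str, list[str]] | None = None,
                     aa_changes: list[tuple] | None = None,
                     ssr_spec: dict | None = None,
                     tandem_spec: dict | None = None,
                     ) -> tuple[AlignedMatrix, LocusTable, SyntheticTruth]:
    """Generate an aligned dataset of ``n_groups`` (plus an optional
    outgroup) evolved down a group tree with per-branch SNPs, planted InDel
    events, optional SSR/tandem copy-number variation and within-group
    haplotype structure. See the module docstring for the frame conventions.
    """
    rng = np.random.default_rng(seed)
    if group_names is None:
        group_names = [f"G{i + 1}" for i in range(n_groups)]
    leaves = list(group_names)
    all_names = leaves + ([outgroup] if outgroup else [])

    frame_str, part, loci = generate_plastome(genome_length, ir_length, seed=seed)
    frame = np.frombuffer(frame_str.encode("ascii"), dtype=np.uint8).copy()
    n = genome_length

    if tree is None:
        if outgroup:
            ingroup = random_group_tree(rng, leaves)
            ingroup.name = "stem"
            tree = CladeNode("root", [ingroup, CladeNode(outgroup)])
        else:
            tree = random_group_tree(rng, leaves)
    branch_nodes = tree.branches()

    # columns free for feature placement: single-copy regions, away from
    # the IRs and region boundaries
    free = np.zeros(n, dtype=bool)
    lsc_s, lsc_e = part.lsc
    ssc_s, ssc_e = part.ssc
    free[lsc_s + 2:lsc_e - 2] = True
    free[ssc_s + 2:ssc_e - 2] = True

    accs = [f"{g}_{i + 1:02d}" for g in all_names
            for i in range(accessions_per_group)]
    groups = {a: a.rsplit("_", 1)[0] for a in accs}
    members = {g: [a for a in accs if groups[a] == g] for g in all_names}
    gap = np.zeros((len(accs), n), dtype=bool)
    row = {a: i for i, a in enumerate(accs)}

    indel_events: list[PlantedIndel] = []

    def plant_length_variants(spec: dict, unit: str, origin: str) -> dict:
        """Write a repeat region into the frame with per-group lengths;
        shorter groups are gapped over the tail. Returns the truth record."""
        lengths = {g: int(v) for g, v in spec["lengths"].items()}
        lmax = max(lengths.values())
        rec = loci.get(spec["locus"])
        lo, hi = int(rec["start"]), int(rec["end"])
        if hi - lo < lmax + 4:
            raise FeatureCollisionError(f"locus {spec['locus']} too small")
        s = lo + 2
        m = len(unit)
        tiled = (unit * (lmax // m + 1))[:lmax]
        frame[s:s + lmax] = np.frombuffer(tiled.encode(), dtype=np.uint8)
        # guard bases: the run must not extend in either direction
        left_bad, right_bad = unit[m - 1], unit[0]
        frame[s - 1] = ord(next(c for c in "ACGT" if c != left_bad))
        frame[s + lmax] = ord(next(c for c in "ACGT"
                                   if c != right_bad and c != tiled[lmax - m]))
        for g, lg in lengths.items():
            if lg < lmax:
                for a in members[g]:
                    gap[row[a], s + lg:s + lmax] = True
        free[s - 2:s + lmax + 2] = False
        distinct = sorted(set(lengths.values()))
        for l_lo, l_hi in zip(distinct, distinct[1:] + [lmax]):
            if l_lo == lmax:
                break
            gapped = frozenset(a for g, lg in lengths.items() if lg <= l_lo
                               for a in members[g])
            indel_events.append(PlantedIndel(s + l_lo, s + l_hi, gapped, origin))
        return {"locus": spec["locus"], "unit": unit, "start": s,
                "lengths": lengths,
                "copies": {g: lg // m for g, lg in lengths.items()}}

    ssr_truth = tandem_truth = None
    if ssr_spec:
        ssr_truth = plant_length_variants(ssr_spec, ssr_spec["motif"], "ssr")
    if tandem_spec:
        ul = int(tandem_spec["unit_length"])
        lengths = {g: c * ul for g, c in tandem_spec["copies"].items()}
        for _ in range(100):
            unit = bytes(_BASES[rng.integers(0, 4, ul)]).decode()
            ok = all(unit != unit[:d] * (ul // d)
                     for d in range(1, ul) if ul % d == 0)
            if ok and len(set(unit)) >= 3:
                break
        else:  # pragma: no cover
            raise FeatureCollisionError("could not draw a primitive tandem unit")
        tandem_truth = plant_length_variants(
            {"locus": tandem_spec["locus"], "lengths": lengths}, unit, "tandem")
        tandem_truth["copies"] = dict(tandem_spec["copies"])

    # extra InDel events (deletion in one group, or insertion carried by one
    # group i.e. all others gapped), placed on free single-copy columns
    target_groups = [all_names[i % len(all_names)] for i in range(n_indel_events)]
    for i, g in enumerate(target_groups):
        length = int(rng.integers(6, 19))
        for _ in range(200):
            s = _free_column_in(rng, free, lsc_s + 2, lsc_e - 2 - length)
            if free[s:s + length + 2].all() and free[s - 2:s].all():
                break
        else:
            raise FeatureCollisionError("could not place an InDel event")
        if i % 2 == 0:  # deletion in g
            gapped = frozenset(members[g])
        else:           # insertion private to g: everyone else is gapped
            gapped = frozenset(a for a in accs if groups[a] != g)
        for a in gapped:
            gap[row[a], s:s + length] = True
        free[s - 2:s + length + 2] = False
        indel_events.append(PlantedIndel(s, s + length, gapped, "indel"))

    # branch SNPs: carried (fixed) by every accession of the clade's leaves
    snp_placement = dict(snp_placement or {})
    snps: list[PlantedSNP] = []
    derived_at: dict[int, list[tuple[frozenset, int]]] = {}
    leafset = frozenset(leaves)

    def plant_snp(col: int, branch: str, carriers: frozenset[str],
                  derived_base: str | None = None) -> None:
        anc = chr(frame[col])
        if derived_base is None:
            choices = [c for c in "ACGT" if c != anc]
            derived_base = choices[int(rng.integers(0, 3))]
        if derived_base == anc:
            raise FeatureCollisionError("derived equals ancestral")
        vs_ref = carriers if (outgroup is None or outgroup not in carriers) \
            else leafset - carriers
        snps.append(PlantedSNP(col, anc, derived_base, branch, carriers, vs_ref))
        free[col] = False

    # pinned amino-acid-change SNPs first (they fix frame codons)
    for branch, locus, codon_i, ref_codon, pos, derived in (aa_changes or []):
        rec = loci.get(locus, "CDS")
        s0 = int(rec["start"]) + 3 * codon_i
        if s0 + 3 > int(rec["end"]):
            raise FeatureCollisionError(f"codon {codon_i} outside {locus}")
        if not free[s0:s0 + 3].all():
            raise FeatureCollisionError(f"codon columns of {locus} not free")
        frame[s0:s0 + 3] = np.frombuffer(ref_codon.encode(), dtype=np.uint8)
        node = next(b for b in branch_nodes if b.name == branch)
        plant_snp(s0 + pos, branch, frozenset(node.leaves()), derived)
        free[s0:s0 + 3] = False
        # a pinned SNP consumes the branch's placement slot for that locus
        if branch in snp_placement and locus in snp_placement[branch]:
            snp_placement[branch] = list(snp_placement[branch])
            snp_placement[branch].remove(locus)

    for node in branch_nodes:
        carriers = frozenset(node.leaves())
        placed = snp_placement.get(node.name)
        if placed is None:
            for _ in range(n_snps_per_branch):
                col = _free_column_in(rng, free, 0, n)
                plant_snp(col, node.name, carriers)
        else:
            for locus_name in placed:
                sel = loci.df[loci.df["name"] == locus_name].iloc[0]
                col = _free_column_in(rng, free, int(sel["start"]), int(sel["end"]))
                plant_snp(col, node.name, carriers)

    # within-group haplotype structure: accessions split round-robin into
    # haplotype classes; each non-first class carries one private SNP
    haplotypes: dict[str, str] = {}
    hap_snps: list[tuple[int, str, list[str]]] = []
    for g in all_names:
        mem = members[g]
        k = min(haplotypes_per_group, len(mem))
        classes = [mem[i::k] for i in range(k)]
        for hi, cls_members in enumerate(classes):
            label = f"{g}.h{hi + 1}"
            for a in cls_members:
                haplotypes[a] = label
            if hi > 0:
                col = _free_column_in(rng, free, 0, n)
                anc = chr(frame[col])
                derived = next(c for c in "ACGT" if c != anc)
                hap_snps.append((col, derived, cls_members))
                free[col] = False

    # ------- emit the alignment -------
    mat = np.tile(frame, (len(accs), 1))
    for s in snps:
        for g in s.carriers:
            for a in members.get(g, []):
                mat[row[a], s.column] = ord(s.derived)
    for col, derived, who in hap_snps:
        for a in who:
            mat[row[a], col] = ord(derived)
    mat[gap] = ord("-")
    seqs = [bytes(r).decode("ascii") for r in mat]
    aligned = AlignedMatrix(accs, seqs, groups)

    branch_counts: dict[str, int] = {}
    for s in snps:
        branch_counts[s.branch] = branch_counts.get(s.branch, 0) + 1
    indel_events.sort(key=lambda e: e.start)
    truth = SyntheticTruth(
        seed=seed, tree_newick=_newick(tree, branch_counts), groups=groups,
        haplotypes=haplotypes, snps=snps, indel_events=indel_events,
        ssr=ssr_truth, tandem=tandem_truth, partition=part,
        params={"n_groups": len(leaves), "outgroup": outgroup,
                "accessions_per_group": accessions_per_group,
                "genome_length": genome_length, "ir_length": ir_length,
                "haplotypes_per_group": haplotypes_per_group})
    return aligned, loci, truth


def emulate_study_shape(seed: int) -> tuple[AlignedMatrix, LocusTable, SyntheticTruth]:
    """The study-shape preset: 7 ingroup groups + CP outgroup, 4 accessions
    each, the fixed group tree, the 44 bp tandem locus at 3-6 copies, the
    30-101 bp AT microsatellite, pinned amino-acid changes, and SNP
    placement covering every branch with the rps16-trnQ/rbcL-accD/ycf3-trnS
    trio."""
    return generate_dataset(
        seed,
        group_names=["CAA", "CAG", "CC", "CF", "CG", "CCha", "CB"],
        outgroup="CP", tree=study_tree(),
        snp_placement=STUDY_SNP_PLACEMENT, aa_changes=STUDY_AA_CHANGES,
        ssr_spec=STUDY_SSR, tandem_spec=STUDY_TANDEM, n_indel_events=4,
        haplotypes_per_group=2)


def study_hierarchy():
    """GroupHierarchy for the study-shape preset (leaves, the A/B/CA/CFG
    composites, CP as reference)."""
    from .loci import GroupHierarchy
    return GroupHierarchy(
        leaves=["CAA", "CAG", "CC", "CF", "CG", "CCha", "CB"],
        composites={
            "A": frozenset({"CAA", "CAG", "CC", "CF", "CG"}),
            "B": frozenset({"CCha", "CB"}),
            "CA": frozenset({"CAA", "CAG"}),
            "CFG": frozenset({"CC", "CF", "CG"}),
            "CCF": frozenset({"CC", "CF"}),
        },
        reference="CP")


def neutral_null_alignment(n: int, S: int, length: int, seed: int) -> AlignedMatrix:
    """A genealogy-free neutral null: S variant sites placed uniformly on a
    random backbone, with derived-allele counts drawn from the standard
    neutral frequency spectrum P(i) proportional to 1/i. Under this null the
    expected pairwise diversity equals Watterson's S/a1, so Tajima's D is
    centered near zero."""
    rng = np.random.default_rng(seed)
    frame = _BASES[rng.integers(0, 4, length)]
    mat = np.tile(frame, (n, 1))
    cols = rng.choice(length, size=S, replace=False)
    weights = 1.0 / np.arange(1, n)
    weights /= weights.sum()
    for col in cols:
        i = int(rng.choice(np.arange(1, n), p=weights))
        rows = rng.choice(n, size=i, replace=False)
        anc = mat[0, col]
        derived = [b for b in _BASES if b != anc][int(rng.integers(0, 3))]
        mat[rows, col] = derived
    return AlignedMatrix([f"s{i}" for i in range(n)],
                         [bytes(r).decode("ascii") for r in mat])
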