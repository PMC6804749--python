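"""SNP polarization, unique/common assignment, AA changes, size deviation,
hypervariability grading."""
import math

import numpy as np
import pandas as pd
import pytest

from panplastome.loci import (GroupHierarchy, amino_acid_changes,
                              assign_unique_common, functional_group,
                              hypervariability_band, hypervariability_score,
                              locus_lengths, locus_size_deviation,
                              partition_variants_by_locus, polarize_snps)
from panplastome.matrix import AlignedMatrix, LocusTable
from panplastome.pan import build_all_pans, mask_ambiguous_columns


def small_hier():
    return GroupHierarchy(
        leaves=["CAA", "CAG", "CC", "CF", "CG", "CCha", "CB"],
        composites={"A": frozenset({"CAA", "CAG", "CC", "CF", "CG"}),
                    "B": frozenset({"CCha", "CB"}),
                    "CFG": frozenset({"CC", "CF", "CG"})},
        reference="CP")


def masked_from(columns: dict[str, str]) -> AlignedMatrix:
    """Build a pan-style matrix from {group: sequence} (CP last reference)."""
    ids = list(columns)
    return AlignedMatrix(ids, list(columns.values()), {g: g for g in ids})


def test_polarization_and_labels():
    seqs = {
        #          0: unique CB; 1: common CFG; 2: shared CB+CAA; 3: clean
        "CAA": "A" + "A" + "G" + "T",
        "CAG": "A" + "A" + "C" + "T",
        "CC":  "A" + "T" + "C" + "T",
        "CF":  "A" + "T" + "C" + "T",
        "CG":  "A" + "T" + "C" + "T",
        "CCha": "A" + "A" + "C" + "T",
        "CB":  "G" + "A" + "G" + "T",
        "CP":  "A" + "A" + "C" + "T",
    }
    table = assign_unique_common(polarize_snps(masked_from(seqs), small_hier()),
                                 small_hier())
    by_col = {r.column: r for r in table.itertuples()}
    assert by_col[0].label == "unique" and by_col[0].scope == "CB"
    assert by_col[1].label == "common" and by_col[1].scope == "CFG"
    assert by_col[2].label == "shared-unclassified"
    assert by_col[2].carriers == frozenset({"CAA", "CB"})
    assert 3 not in by_col
    # every polarized SNP gets exactly one label
    assert set(table["label"]) <= {"unique", "common", "shared-unclassified"}


def test_multiallelic_column_classified_per_derived_state():
    seqs = {g: "A" for g in ["CAA", "CAG", "CC", "CF", "CG", "CCha", "CB", "CP"]}
    seqs["CB"] = "G"
    seqs["CAA"] = "T"
    table = assign_unique_common(polarize_snps(masked_from(seqs), small_hier()),
                                 small_hier())
    assert len(table) == 2
    assert set(table["scope"]) == {"CB", "CAA"}
    assert all(table["label"] == "unique")


def test_reference_n_column_is_skipped():
    seqs = {g: "A" for g in ["CAA", "CAG", "CC", "CF", "CG", "CCha", "CB"]}
    seqs["CP"] = "N"
    assert polarize_snps(masked_from(seqs), small_hier()).empty


def test_planted_carrier_sets_recovered_exactly(preset, preset_pans, hier):
    _, _, truth = preset
    _, masked, _ = preset_pans
    table = assign_unique_common(polarize_snps(masked, hier), hier)
    got = {(r.column, r.carriers) for r in table.itertuples()}
    planted = {(s.column, s.carriers_vs_reference) for s in truth.snps}
    assert got == planted
    # expected label from the planted carrier set
    for r in table.itertuples():
        if len(r.carriers) == 1:
            assert r.label == "unique"
        elif hier.composite_for(r.carriers):
            assert r.label == "common" and r.scope == hier.composite_for(r.carriers)
        else:
            assert r.label == "shared-unclassified"


def test_partition_by_locus_counts_planted_snps(preset, preset_pans, hier):
    m, loci, truth = preset
    pans, masked, _ = preset_pans
    reports = {(r.locus, r.cls): r for r in
               partition_variants_by_locus(masked, loci, hier, pans)}
    planted_per_locus: dict[tuple[str, str], int] = {}
    for s in truth.snps:
        sel = loci.df[(loci.df["start"] <= s.column) & (s.column < loci.df["end"])]
        key = (sel.iloc[0]["name"], sel.iloc[0]["cls"])
        planted_per_locus[key] = planted_per_locus.get(key, 0) + 1
    for key, r in reports.items():
        assert r.n_snps == planted_per_locus.get(key, 0), key
    # no double counting: locus totals add up to all planted SNPs
    assert sum(r.n_snps for r in reports.values()) == len(truth.snps)
    # a locus with no variant columns: h == 1
    quiet = [r for r in reports.values() if r.n_snps == 0 and r.n_indel_sites == 0]
    assert quiet and all(r.h == 1 for r in quiet)


def test_amino_acid_changes_planted_patterns(preset, preset_pans, hier):
    m, loci, _ = preset
    pans, _, _ = preset_pans
    changes = amino_acid_changes(pans, loci, hier)
    li = [c for c in changes if (c.from_aa, c.to_aa) == ("L", "I")]
    vi = [c for c in changes if (c.from_aa, c.to_aa) == ("V", "I")]
    assert any(c.scope == "B" and c.locus == "rpoB" for c in li)
    assert any(c.scope == "A" and c.locus == "ndhF" for c in vi)
    # the synonymous planted substitution must produce no change
    assert not any(c.locus == "rpoB" and c.codon_index == 20 for c in changes)
    # excluded loci are never scanned
    assert not any(c.locus in ("accD", "rpl20", "ycf1") for c in changes)


def test_synonymous_only_groups_yield_no_changes():
    # third-position GGx wobble: all groups differ but all code Gly
    seqs = {"g1": "GGA" * 2, "g2": "GGG" * 2, "g3": "GGC" * 2, "ref": "GGT" * 2}
    m = AlignedMatrix(list(seqs), list(seqs.values()),
                      {k: k for k in seqs})
    pans = build_all_pans(m)
    loci = LocusTable(pd.DataFrame([("gene", "CDS", 0, 6, "+")],
                                   columns=["name", "cls", "start", "end", "strand"]))
    hier = GroupHierarchy(leaves=["g1", "g2", "g3"], composites={}, reference="ref")
    assert amino_acid_changes(pans, loci, hier) == []


def test_cds_not_multiple_of_three_skipped():
    seqs = {"g1": "GGAC", "ref": "GGTC"}
    m = AlignedMatrix(list(seqs), list(seqs.values()), {k: k for k in seqs})
    pans = build_all_pans(m)
    loci = LocusTable(pd.DataFrame([("gene", "CDS", 0, 4, "+")],
                                   columns=["name", "cls", "start", "end", "strand"]))
    hier = GroupHierarchy(leaves=["g1"], composites={}, reference="ref")
    assert amino_acid_changes(pans, loci, hier) == []


def test_minus_strand_cds_translated_on_reverse_complement():
    # reverse complement of ATG GCT = AGC CAT; plant A->G on the minus strand
    fwd_ref = "AGCCAT"   # revcomp -> ATGGCT = M A
    fwd_alt = "AGCCGT"   # revcomp -> ACGGCT = T A
    m = AlignedMatrix(["g1", "ref"], [fwd_alt, fwd_ref],
                      {"g1": "g1", "ref": "ref"})
    pans = build_all_pans(m)
    loci = LocusTable(pd.DataFrame([("gene", "CDS", 0, 6, "-")],
                                   columns=["name", "cls", "start", "end", "strand"]))
    hier = GroupHierarchy(leaves=["g1"], composites={}, reference="ref")
    changes = amino_acid_changes(pans, loci, hier)
    assert len(changes) == 1
    assert (changes[0].from_aa, changes[0].to_aa) == ("M", "T")


def test_size_deviation_arithmetic():
    lengths = pd.DataFrame(
        {"CP": [500, 500], "g1": [680, 500], "g2": [500, 500], "g3": [500, 500],
         "g4": [500, 500], "g5": [500, 500], "g6": [500, 500], "g7": [500, 500]},
        index=["big", "flat"])
    out = locus_size_deviation(lengths, "CP")
    assert math.isclose(out.loc["big", "deviation_avg"], 180 / 7)
    assert bool(out.loc["big", "pcr_suitable"])
    assert out.loc["flat", "deviation_avg"] == 0
    assert not out.loc["flat", "pcr_suitable"]


def test_locus_lengths_modal_ungapped(preset):
    m, loci, truth = preset
    lens = locus_lengths(m, loci)
    tl = truth.tandem
    for g, c in tl["copies"].items():
        assert lens.loc[tl["locus"], g] == c * 44 + (
            lens.loc[tl["locus"], g] - c * 44)  # ungapped length includes flanks
    # differences between groups equal planted copy-number differences
    base = lens.loc[tl["locus"], "CP"]
    for g, c in tl["copies"].items():
        assert lens.loc[tl["locus"], g] - base == (c - tl["copies"]["CP"]) * 44


def test_hypervariability_scoring():
    s = "ACGT" * 25
    assert hypervariability_score(s, s) == 1.0
    one_mismatch = s[:50] + ("A" if s[50] != "A" else "C") + s[51:]
    assert math.isclose(hypervariability_score(s, one_mismatch), 0.975)
    deleted = s[:30] + s[70:]
    assert hypervariability_score(s, deleted) < 0.5
    assert hypervariability_band(0.1) == "<0.25"
    assert hypervariability_band(0.6) == "0.5-0.75"
    assert hypervariability_band(0.99) == ">0.75"


def test_hypervariability_monotone_in_mismatches():
    rng = np.random.default_rng(4)
    s = "".join(rng.choice(list("ACGT"), 120))
    prev = 1.0
    t = list(s)
    for pos in range(0, 60, 7):
        t[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[t[pos]]
        score = hypervariability_score(s, "".join(t))
        assert score <= prev + 1e-12
        prev = score


def test_functional_group_rollup():
    assert functional_group("ndhA") == "ndh"
    assert functional_group("rps16-trnQ") == "rps"
    assert functional_group("trnL-trnF") == "other"
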