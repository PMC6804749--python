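"""Site classification, gap filtering, InDel events, haplotype collapsing."""
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panplastome.matrix import AlignedMatrix
from panplastome.sites import (SiteClass, classify_sites, collapse_haplotypes,
                               detect_indel_events, filter_gap_columns)
from tests.conftest import random_alignment


# ---------------------------------------------------------------------------
# brute-force oracles (straight from the definitions, no vectorization)


def oracle_classify_column(column: str):
    counts = Counter(c for c in column if c in "ACGT")
    k = len(counts)
    if k == 0:
        return SiteClass.ALL_GAP.value, 0
    if k == 1:
        return SiteClass.INVARIANT.value, 1
    if sum(1 for v in counts.values() if v >= 2) >= 2:
        return SiteClass.PARSIMONY_INFORMATIVE.value, k
    return SiteClass.SINGLETON.value, k


def oracle_indel_events(m: AlignedMatrix):
    patterns = []
    for col in range(m.length):
        patterns.append(frozenset(m.ids[i] for i in range(m.n)
                                  if m.seqs[i][col] == "-"))
    events = []
    start = 0
    for col in range(1, m.length + 1):
        if col == m.length or patterns[col] != patterns[start]:
            if patterns[start]:
                events.append((start, col, patterns[start]))
            start = col
    return events


# ---------------------------------------------------------------------------
# classify_sites


@pytest.mark.parametrize("column,expected,k", [
    ("AACC", SiteClass.PARSIMONY_INFORMATIVE.value, 2),
    ("AAAC", SiteClass.SINGLETON.value, 2),
    ("AACCG", SiteClass.PARSIMONY_INFORMATIVE.value, 3),
    ("AACG", SiteClass.SINGLETON.value, 3),     # counts (2,1,1): no 2nd pair
    ("AAAA", SiteClass.INVARIANT.value, 1),
    ("--NN", SiteClass.ALL_GAP.value, 0),
    ("AA-N", SiteClass.INVARIANT.value, 1),
])
def test_column_classification_definitions(column, expected, k):
    m = AlignedMatrix([f"s{i}" for i in range(len(column))],
                      [c for c in column])
    cls = classify_sites(m)
    assert cls.classes[0] == expected
    assert cls.k_variants[0] == k


def test_eta_counts_states_minus_one_per_variable_column():
    m = AlignedMatrix(list("abcde"), ["A", "A", "C", "C", "G"])
    cls = classify_sites(m)
    assert cls.S == 1 and cls.Eta == 2


def test_classify_matches_bruteforce_on_random_alignments():
    rng = np.random.default_rng(42)
    for _ in range(500):
        m = random_alignment(rng, 6, 20, alphabet="ACGT-N")
        cls = classify_sites(m)
        s = eta = 0
        for col in range(m.length):
            colstr = "".join(seq[col] for seq in m.seqs)
            exp_cls, exp_k = oracle_classify_column(colstr)
            assert cls.classes[col] == exp_cls, colstr
            assert cls.k_variants[col] == exp_k
            if exp_k >= 2:
                s += 1
                eta += exp_k - 1
        assert cls.S == s and cls.Eta == eta and cls.Eta >= cls.S
        assert cls.S == cls.n_singleton + cls.n_pi


# ---------------------------------------------------------------------------
# filter_gap_columns


def test_gap_filter_examples():
    m = AlignedMatrix(list("abcd"), ["A-CT", "A-CT", "A--T", "A-GT"])
    out, col_map = filter_gap_columns(m, 0.996)  # col 1 fully gapped
    assert out.length == 3
    assert list(col_map) == [0, -1, 1, 2]
    out2, _ = filter_gap_columns(m, 1.0)
    assert out2.length == 3  # only the 100%-gap column removed at 1.0
    # a column gapped in 1 of 4 rows is retained at the default threshold
    assert out.seqs[2] == "A-T"


def test_gap_filter_monotone_in_threshold():
    rng = np.random.default_rng(3)
    m = random_alignment(rng, 8, 60, alphabet="AC--")
    kept_by_thr = {}
    for thr in (0.3, 0.6, 0.9, 1.0):
        _, col_map = filter_gap_columns(m, thr)
        kept_by_thr[thr] = {i for i, v in enumerate(col_map) if v >= 0}
    assert kept_by_thr[0.3] <= kept_by_thr[0.6] <= kept_by_thr[0.9] <= kept_by_thr[1.0]


def test_gap_filter_rejects_empty_result():
    m = AlignedMatrix(["a", "b"], ["--", "--"])
    with pytest.raises(ValueError):
        filter_gap_columns(m, 0.5)


# ---------------------------------------------------------------------------
# InDel events


def test_indel_event_examples():
    seqs = {"s1": "AAAAAAAAAA-----AAAAA",
            "s2": "AAAAAAAAAAAAAAAAAAAA"}
    m = AlignedMatrix(list(seqs), list(seqs.values()))
    ev = detect_indel_events(m)
    assert len(ev) == 1 and (ev[0].start, ev[0].end) == (10, 15)
    assert ev[0].pattern == frozenset({"s1"}) and ev[0].length == 5


def test_pattern_change_splits_events():
    m = AlignedMatrix(["s1", "s2"], ["AAA--" + "---AA", "AAAAA" + "---AA"])
    ev = detect_indel_events(m)
    assert [(e.start, e.end, set(e.pattern)) for e in ev] == [
        (3, 5, {"s1"}), (5, 8, {"s1", "s2"})]


def test_indel_events_match_bruteforce_and_row_permutation():
    rng = np.random.default_rng(11)
    for _ in range(200):
        m = random_alignment(rng, 5, 30, alphabet="AC-")
        got = [(e.start, e.end, e.pattern) for e in detect_indel_events(m)]
        assert got == oracle_indel_events(m)
        # union of event ranges == gap-containing columns
        cols = set()
        for s, e, _ in got:
            cols.update(range(s, e))
        gap_cols = {c for c in range(m.length)
                    if any(seq[c] == "-" for seq in m.seqs)}
        assert cols == gap_cols
        # invariant under row permutation
        perm = list(rng.permutation(m.n))
        m2 = AlignedMatrix([m.ids[i] for i in perm], [m.seqs[i] for i in perm])
        assert len(detect_indel_events(m2)) == len(got)


# ---------------------------------------------------------------------------
# haplotype collapsing


def test_identical_sequences_collapse_to_one():
    m = AlignedMatrix(list("abcd"), ["ACGT"] * 4)
    haps = collapse_haplotypes(m)
    assert len(haps) == 1 and haps[0].count == 4
    assert haps[0].members == list("abcd")


def test_gap_mode_semantics():
    m = AlignedMatrix(["x", "y"], ["AC-T", "ACGT"])
    assert len(collapse_haplotypes(m, "gaps_as_state")) == 2
    assert len(collapse_haplotypes(m, "gaps_ignored")) == 1


def test_n_is_wildcard_in_both_modes():
    m = AlignedMatrix(["x", "y"], ["ACNT", "ACGT"])
    assert len(collapse_haplotypes(m, "gaps_as_state")) == 1
    assert len(collapse_haplotypes(m, "gaps_ignored")) == 1


def test_gaps_ignored_intransitivity_closed_by_single_linkage():
    # a~b (gap masks the difference), b~c, but a and c differ at column 0
    m = AlignedMatrix(["a", "b", "c"], ["ACGT", "-CGT", "TCGT"])
    haps = collapse_haplotypes(m, "gaps_ignored")
    assert len(haps) == 1 and haps[0].count == 3


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_gaps_ignored_never_more_haplotypes_than_gaps_as_state(seed):
    rng = np.random.default_rng(seed)
    m = random_alignment(rng, 6, 12, alphabet="AC-")
    n_state = len(collapse_haplotypes(m, "gaps_as_state"))
    n_ign = len(collapse_haplotypes(m, "gaps_ignored"))
    assert n_ign <= n_state


def test_planted_haplotype_partition_recovered(preset):
    m, _, truth = preset
    planted = truth.haplotype_partition()
    for mode in ("gaps_as_state", "gaps_ignored"):
        got = {frozenset(h.members) for h in collapse_haplotypes(m, mode)}
        assert got == planted
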