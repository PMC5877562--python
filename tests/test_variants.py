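"""Alignment, consensus, variant census, windows, indels, identity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import plastomics as pk
from plastomics.errors import AlignmentSizeError, PlastomicsError
from plastomics.io import MultipleAlignment
from plastomics.variants import build_consensus


# ---------------------------------------------------------------------------
# Needleman-Wunsch vs exhaustive oracle
# ---------------------------------------------------------------------------

def brute_force_best_score(a, b, gap_open=10.0, gap_extend=1.0,
                           match=1.0, mismatch=-1.0):
    """Enumerate every global alignment of two short strings.

    Gap convention: a run of g gapped residues costs open + g*extend; end
    gaps cost the same as internal ones.
    """
    best = [-np.inf]

    def rec(i, j, score, last):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, "M")
        if i < len(a):
            cost = gap_extend if last == "X" else gap_open + gap_extend
            rec(i + 1, j, score - cost, "X")
        if j < len(b):
            cost = gap_extend if last == "Y" else gap_open + gap_extend
            rec(i, j + 1, score - cost, "Y")

    rec(0, 0, 0.0, None)
    return best[0]


_PAIRS = [
    ("ACGT", "ACGT"),
    ("ACGT", "AGT"),
    ("A", "TTTTTTTT"),
    ("ACGTACGT", "TGCA"),
    ("GATTACA", "GCATGC"),
    ("CCCC", "GGGG"),
    ("ACACACAC", "CACACACA"),
]


@pytest.mark.parametrize("a,b", _PAIRS)
def test_nw_score_matches_exhaustive_enumeration(a, b):
    aln, score = pk.pairwise_align(a, b)
    assert score == pytest.approx(brute_force_best_score(a, b), abs=1e-9)
    assert aln.degapped(aln.ids[0]) == a
    assert aln.degapped(aln.ids[1]) == b


def test_nw_random_pairs_match_oracle_and_are_symmetric():
    rng = np.random.default_rng(12)
    for _ in range(40):
        a = "".join(rng.choice(list("ACGT"), rng.integers(1, 9)))
        b = "".join(rng.choice(list("ACGT"), rng.integers(1, 9)))
        _, s_ab = pk.pairwise_align(a, b)
        _, s_ba = pk.pairwise_align(b, a)
        assert s_ab == pytest.approx(s_ba, abs=1e-9)
        assert s_ab == pytest.approx(brute_force_best_score(a, b), abs=1e-9)


def test_align_empty_rejected():
    with pytest.raises(PlastomicsError):
        pk.pairwise_align("", "ACGT")


# ---------------------------------------------------------------------------
# Progressive alignment
# ---------------------------------------------------------------------------

def test_progressive_identical_sequences_no_gaps():
    aln = pk.progressive_align([("a", "ACGTAC"), ("b", "ACGTAC"), ("c", "ACGTAC")])
    assert aln.rows == ["ACGTAC"] * 3


def test_progressive_round_trips_inputs_and_finds_planted_snp():
    seqs = [
        ("a", "ACGTACGTACGTACGTACGT"),
        ("b", "ACGTACGTACGTACGTACGT"),
        ("c", "ACGTACGTCCGTACGTACGT"),  # single SNP at position 9
    ]
    aln = pk.progressive_align(seqs)
    for sid, seq in seqs:
        assert aln.degapped(sid) == seq
    variants = pk.call_variants(aln)
    assert len(variants) == 1
    assert variants[0].kind == "SNP"
    assert variants[0].alleles["c"] == "C"


def test_progressive_alignment_quality_on_simulated_genes():
    # ten gene-length sequences at shallow divergence: the aligner should
    # recover the (gap-free) true homology essentially exactly
    import dendropy

    rng = np.random.default_rng(21)
    root = "".join(rng.choice(list("ACGT"), 1_500))
    tree = dendropy.Tree.get(
        data="(" + ",".join(f"s{i}:0.02" for i in range(10)) + ");",
        schema="newick", preserve_underscores=True,
    )
    leaves = pk.evolve_clade(root, tree, seed=22)
    aln = pk.progressive_align(sorted(leaves.items()))
    assert aln.n_cols == 1_500  # no spurious gap columns at this divergence


def test_progressive_size_guard():
    with pytest.raises(AlignmentSizeError):
        pk.progressive_align([("a", "A" * 6_000), ("b", "A" * 6_000)])


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def test_consensus_majority_and_tie_break():
    aln = MultipleAlignment(["a", "b", "c"], ["AAT", "AAT", "TAT"])
    cons = build_consensus(aln)
    assert cons.sequence == "AAT"
    # two-row tie: alphabetical
    cons2 = build_consensus(MultipleAlignment(["a", "b"], ["A", "T"]))
    assert cons2.sequence == "A"


def test_consensus_excludes_gap_majority_columns():
    aln = MultipleAlignment(
        ["a", "b", "c"], ["AC-GT", "AC--T", "ACA-T"]
    ).mask_terminal_gaps()
    cons = build_consensus(aln)
    # column 4 is gap-majority (3/3 gaps beat nothing); column 3 is 2 gaps
    # vs 1 A -> also gap-majority
    assert cons.sequence == "ACT"
    assert cons.col_to_pos == [1, 2, None, None, 3]
    assert len(cons.sequence) == sum(p is not None for p in cons.col_to_pos)


# ---------------------------------------------------------------------------
# Variant calling vs naive per-column oracle
# ---------------------------------------------------------------------------

def naive_column_scan(aln):
    """Independent re-derivation of the census from first principles."""
    masked = aln.mask_terminal_gaps()
    counts = []
    pos = 0
    expected = []
    for c in range(masked.n_cols):
        col = [r[c] for r in masked.rows]
        base_counts = {b: col.count(b) for b in "ACGT"}
        top = max(base_counts.values())
        gaps = col.count("-")
        if top == 0 or gaps > top:
            continue
        pos += 1
        consensus = min(b for b, n in base_counts.items() if n == top)
        diff = [
            ch for ch in col
            if ch not in ("N", "?") and ch != consensus
        ]
        if diff:
            expected.append((pos, "indel" if "-" in diff else "SNP", consensus))
    return expected


def test_identical_rows_yield_no_variants():
    aln = MultipleAlignment(["a", "b"], ["ACGTACGT"] * 2)
    assert pk.call_variants(aln) == []


def test_hand_built_alignment_census():
    # 5 x 20 with 2 SNPs and one 3-column deletion in one sample
    base = "ACGTACGTACGTACGTACGT"
    rows = [base, base, base, base, base]
    rows[1] = base[:4] + "T" + base[5:]          # SNP at column 5
    rows[2] = base[:10] + "---" + base[13:]      # deletion columns 11-13
    rows[3] = base[:17] + "A" + base[18:]        # SNP at column 18 (C -> A)
    aln = MultipleAlignment(list("abcde"), rows)
    variants = pk.call_variants(aln)
    assert len(variants) == 5  # 2 SNP + 3 indel columns
    kinds = sorted(v.kind for v in variants)
    assert kinds == ["SNP", "SNP", "indel", "indel", "indel"]
    got = [(v.position, v.kind, v.consensus_allele) for v in variants]
    assert got == naive_column_scan(aln)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.data())
def test_call_variants_equals_naive_scan_on_random_alignments(data):
    n_rows = data.draw(st.integers(2, 10))
    n_cols = data.draw(st.integers(1, 200))
    rows = [
        data.draw(
            st.text(alphabet="ACGT-N", min_size=n_cols, max_size=n_cols)
        )
        for _ in range(n_rows)
    ]
    aln = MultipleAlignment([f"s{i}" for i in range(n_rows)], rows)
    got = [(v.position, v.kind, v.consensus_allele) for v in pk.call_variants(aln)]
    assert got == naive_column_scan(aln)


def test_variant_positions_map_to_disagreeing_columns(small_study):
    masked = small_study.target_alignment.mask_terminal_gaps()
    cons = build_consensus(masked)
    for v in pk.call_variants(masked, cons):
        col = [r[v.column - 1] for r in masked.rows]
        assert any(
            ch != v.consensus_allele and ch not in ("N", "?") for ch in col
        )


# ---------------------------------------------------------------------------
# Coordinate maps
# ---------------------------------------------------------------------------

def test_gap_free_alignment_is_identity_map():
    aln = MultipleAlignment(["a", "b"], ["ACGTAC", "ACCTAC"])
    for pos in range(1, 7):
        assert pk.map_position(aln, "a", pos) == pos
        assert pk.map_sample_position(aln, "a", pos) == pos


def test_map_round_trip_through_gaps(small_study):
    aln = small_study.target_alignment.mask_terminal_gaps()
    cons = build_consensus(aln)
    sid = aln.ids[0]
    rng = np.random.default_rng(5)
    n = len(aln.degapped(sid))
    for pos in rng.integers(1, n + 1, size=200):
        cpos = pk.map_sample_position(aln, sid, int(pos), cons)
        if cpos is None:
            continue
        assert pk.map_position(aln, sid, cpos, cons) == pos


def test_map_position_gap_gives_explicit_none():
    aln = MultipleAlignment(["a", "b", "c"], ["AC-T", "ACGT", "ACGT"])
    assert pk.map_position(aln, "a", 3) is None


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def _variants_at(positions):
    return [
        pk.VariantRecord(p, "SNP", "A", {}, p) for p in positions
    ]


def test_window_counts_zero_and_conservation():
    profile = pk.window_counts([], 25, window=10)
    assert [c for _, _, c in profile.windows] == [0, 0, 0]
    vs = _variants_at([1, 5, 9, 10, 11, 21, 25])
    profile = pk.window_counts(vs, 25, window=5)
    assert [c for _, _, c in profile.windows] == [2, 2, 1, 0, 2]
    assert profile.total() == len(vs)
    assert profile.windows[-1] == (21, 25, 2)
    assert profile.top[0] == (1, 5, 2)  # ties broken by start coordinate


# ---------------------------------------------------------------------------
# Indel events
# ---------------------------------------------------------------------------

def test_planted_deletion_recovered_with_length_and_carriers(small_study):
    events = pk.find_indel_events(small_study.alignment, min_len=50)
    truth = {}
    for sample, start, length in small_study.truth.indel_events:
        truth.setdefault((start, length), set()).add(sample)
    assert len(events) == len(truth)
    by_length = {e.length: set(e.samples) for e in events}
    for (start, length), samples in truth.items():
        assert by_length[length] == samples


def test_min_len_above_all_gaps_gives_empty(small_study):
    assert pk.find_indel_events(small_study.alignment, min_len=5_000) == []


def test_events_never_overlap_within_one_sample(small_study):
    events = pk.find_indel_events(small_study.alignment, min_len=1)
    per_sample = {}
    for e in events:
        for s in e.samples:
            per_sample.setdefault(s, []).append((e.start, e.length))
    for spans in per_sample.values():
        spans.sort()
        for (s1, l1), (s2, _) in zip(spans, spans[1:]):
            assert s1 + l1 <= s2 + 1  # maximal runs cannot touch


def test_terminal_gaps_are_missing_data_not_indels():
    rows = ["-----ACGTACGTACGT", "ACGTAACGTACGTACGT"]
    aln = MultipleAlignment(["a", "b"], rows)
    assert pk.find_indel_events(aln, min_len=3) == []


# ---------------------------------------------------------------------------
# Identity profile
# ---------------------------------------------------------------------------

def test_identity_profile_bounds_and_dip():
    a = "ACGT" * 50
    aln_same = MultipleAlignment(["a", "b"], [a, a])
    profile = pk.identity_profile(aln_same, window=20, step=10)
    assert all(v == 100.0 for _, v in profile)
    # plant a 40-column deletion in b
    b = a[:80] + "-" * 40 + a[120:]
    profile = pk.identity_profile(
        MultipleAlignment(["a", "b"], [a, b]), window=20, step=20
    )
    assert all(0.0 <= v <= 100.0 for _, v in profile)
    dips = [mid for mid, v in profile if v < 100.0]
    assert dips and all(60 < mid < 140 for mid in dips)
    with pytest.raises(PlastomicsError):
        pk.identity_profile(aln_same, window=10_000)
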