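"""Alignment-based variant census, windowed diversity, and indel events.

The variable-position census is defined against a strict-majority consensus
of the multiple alignment: every consensus position where at least one
sample differs from the consensus base is a variable position (a gap in a
sample at such a position is an indel-type state).  Terminal gap runs are
end-trimming artifacts, flagged as missing data, and never counted as
variation.  Windowed counts over consensus coordinates locate diversity
hotspots; maximal per-sample gap runs above a length cutoff are reported as
large indel events (grouped across carriers sharing identical breakpoints).

Pairwise global alignment uses affine gap costs (defaults: gap open 10,
gap extension 1, match +1, mismatch -1); a gap of length g costs
open + g*extend, and end gaps cost the same as internal ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align

from .errors import PlastomicsError, AlignmentSizeError
from .io import GAP, MISSING, MultipleAlignment, PlastomeRecord

_BASES = (b"A", b"C", b"G", b"T")
PROGRESSIVE_MAX_LEN = 5_000


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """One variable consensus position."""

    position: int  # 1-based consensus coordinate
    kind: str  # "SNP" | "indel"
    consensus_allele: str
    alleles: dict[str, str]  # per-sample base, '-', 'N' or '?'
    column: int  # 1-based alignment column


@dataclass
class IndelEvent:
    """A maximal gap run of >= min_len in one or more samples."""

    samples: list[str]
    start: int  # 1-based consensus coordinate of the first deleted position
    length: int  # alignment columns spanned by the run
    flanking: tuple[str, str] | None = None


@dataclass
class WindowProfile:
    windows: list[tuple[int, int, int]]  # (start, end, variable-position count)
    top: list[tuple[int, int, int]] = field(default_factory=list)

    def total(self) -> int:
        return sum(c for _, _, c in self.windows)


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # Biopython charges open_gap_score for the first gapped residue; our
    # convention prices a length-g gap at open + g*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def pairwise_align(
    a: tuple[str, str] | str,
    b: tuple[str, str] | str,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    match: float = 1.0,
    mismatch: float = -1.0,
) -> tuple[MultipleAlignment, float]:
    """Optimal global alignment of two sequences under affine gap costs.

    Accepts plain sequences or (id, sequence) pairs; returns the two-row
    alignment and its score.  Tie-breaking among co-optimal alignments is
    deterministic (the aligner's first reported path).
    """
    id_a, seq_a = a if isinstance(a, tuple) else ("seq1", a)
    id_b, seq_b = b if isinstance(b, tuple) else ("seq2", b)
    if not seq_a or not seq_b:
        raise PlastomicsError("cannot align an empty sequence")
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    alignments = aligner.align(seq_a.upper(), seq_b.upper())
    best = alignments[0]
    return MultipleAlignment([id_a, id_b], [str(best[0]), str(best[1])]), best.score


# ---------------------------------------------------------------------------
# Progressive (gene-scale) alignment
# ---------------------------------------------------------------------------

def _kmer_distance(a: str, b: str, k: int = 6) -> float:
    sa = {a[i : i + k] for i in range(len(a) - k + 1)}
    sb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not sa or not sb:
        return 1.0
    return 1.0 - len(sa & sb) / len(sa | sb)


def _profile_columns(rows: list[str]) -> np.ndarray:
    """(n_cols, 4) base frequencies; gaps contribute nothing."""
    arr = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(len(rows), -1)
    freqs = np.stack([(arr == b).sum(axis=0) for b in _BASES], axis=1).astype(float)
    return freqs


def _profile_align(
    rows_a: list[str], rows_b: list[str],
    match: float, mismatch: float, gap_open: float, gap_extend: float,
) -> tuple[list[str], list[str]]:
    """Affine-gap Gotoh DP between two profiles (sum-of-pairs, averaged).

    Row-wise vectorized: the horizontal gap state is resolved with a
    prefix-max scan so each DP row is O(m) numpy work.
    """
    fa = _profile_columns(rows_a)
    fb = _profile_columns(rows_b)
    n, m = fa.shape[0], fb.shape[0]
    na, nb = fa.sum(axis=1), fb.sum(axis=1)
    # substitution score between columns: average over base pairs
    agree = fa @ fb.T
    tot = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        sub = np.where(tot > 0, (agree * match + (tot - agree) * mismatch) / tot, 0.0)

    NEG = -1e18
    first = gap_open + gap_extend  # price of the first gapped column
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in profile B (vertical move)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in profile A (horizontal move)
    M[0, 0] = 0.0
    Iy[0, 1:] = -(gap_open + gap_extend * np.arange(1, m + 1))
    Ix[1:, 0] = -(gap_open + gap_extend * np.arange(1, n + 1))
    for i in range(1, n + 1):
        prev_best = np.maximum.reduce([M[i - 1], Ix[i - 1], Iy[i - 1]])
        M[i, 1:] = prev_best[:-1] + sub[i - 1]
        Ix[i] = np.maximum(M[i - 1] - first, Ix[i - 1] - gap_extend)
        Ix[i, 0] = -(gap_open + gap_extend * i)
        # Iy[i, j] = max over j' < j of best(i, j') - open - (j - j') * extend
        best_row = np.maximum(M[i], Ix[i])
        aux = best_row + gap_extend * np.arange(m + 1)
        run = np.maximum.accumulate(aux)
        Iy[i, 1:] = run[:-1] - gap_open - gap_extend * np.arange(1, m + 1)
        Iy[i, 0] = NEG
    # traceback
    i, j = n, m
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    out_a: list[str] = []
    out_b: list[str] = []
    gap_a = GAP * len(rows_a)
    gap_b = GAP * len(rows_b)
    cols_a = ["".join(r[c] for r in rows_a) for c in range(n)]
    cols_b = ["".join(r[c] for r in rows_b) for c in range(m)]
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            out_a.append(cols_a[i - 1])
            out_b.append(cols_b[j - 1])
            prev = np.array([M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]])
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1 and i > 0:  # column from A, gap in B
            out_a.append(cols_a[i - 1])
            out_b.append(gap_b)
            from_m = M[i - 1, j] - first
            i -= 1
            state = 0 if from_m >= Ix[i, j] - gap_extend + 1e-12 else 1
        elif state == 2 and j > 0:
            out_a.append(gap_a)
            out_b.append(cols_b[j - 1])
            from_m = max(M[i, j - 1], Ix[i, j - 1]) - first
            j -= 1
            state = 0 if from_m >= Iy[i, j] - gap_extend + 1e-12 else 2
            if state == 0 and Ix[i, j] > M[i, j]:
                state = 1
        else:  # boundary
            state = 1 if i > 0 else 2
            continue
    out_a.reverse()
    out_b.reverse()
    new_a = ["".join(col[r] for col in out_a) for r in range(len(rows_a))]
    new_b = ["".join(col[r] for col in out_b) for r in range(len(rows_b))]
    return new_a, new_b


def progressive_align(
    seqs: Sequence[tuple[str, str]],
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    match: float = 1.0,
    mismatch: float = -1.0,
    max_len: int = PROGRESSIVE_MAX_LEN,
) -> MultipleAlignment:
    """Guide-tree progressive alignment for gene-scale sequences.

    The guide order comes from k-mer (Jaccard) distances with greedy
    nearest-pair agglomeration; profiles are merged with the affine-gap
    scorer.  Whole-plastome alignments are deliberately out of range: supply
    a precomputed alignment instead (``max_len`` guards the quadratic DP).
    """
    if len(seqs) < 2:
        raise PlastomicsError("progressive alignment needs >= 2 sequences")
    too_long = [sid for sid, s in seqs if len(s) > max_len]
    if too_long:
        raise AlignmentSizeError(
            f"sequences exceed the {max_len} bp gene-scale limit: {too_long}; "
            "supply a precomputed alignment for genome-scale input"
        )
    ids = [sid for sid, _ in seqs]
    data = {sid: s.upper() for sid, s in seqs}
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _kmer_distance(data[ids[i]], data[ids[j]])

    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [data[ids[i]]]) for i in range(n)
    }
    cdist = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    nxt = n
    while len(clusters) > 1:
        (i, j) = min(cdist, key=lambda k: (cdist[k], k))
        ids_i, rows_i = clusters.pop(i)
        ids_j, rows_j = clusters.pop(j)
        new_i, new_j = _profile_align(
            rows_i, rows_j, match, mismatch, gap_open, gap_extend
        )
        merged = (ids_i + ids_j, new_i + new_j)
        cdist = {k: v for k, v in cdist.items() if i not in k and j not in k}
        for k in clusters:
            pair = (min(k, nxt), max(k, nxt))
            cdist[pair] = _cluster_distance(dist, ids, ids_i + ids_j, clusters[k][0])
        clusters[nxt] = merged
        nxt += 1
    member_ids, rows = next(iter(clusters.values()))
    order = [member_ids.index(sid) for sid in ids]
    return MultipleAlignment(ids, [rows[k] for k in order])


def _cluster_distance(dist, ids, members_a, members_b) -> float:
    ia = [ids.index(a) for a in members_a]
    ib = [ids.index(b) for b in members_b]
    return float(np.mean([[dist[x][y] for y in ib] for x in ia]))


# ---------------------------------------------------------------------------
# Consensus and variant calling
# ---------------------------------------------------------------------------

@dataclass
class Consensus:
    sequence: str
    col_to_pos: list[int | None]  # per alignment column, consensus position
    pos_to_col: list[int]  # per consensus position (0-indexed), column (1-based)


def build_consensus(aln: MultipleAlignment) -> Consensus:
    """Strict-majority consensus.

    Per column the consensus is the most frequent base among non-gap,
    non-missing characters (alphabetical tie-break); columns where the gap
    outnumbers every base are excluded from consensus coordinates but kept
    in the column map.
    """
    if aln.n_rows < 2:
        raise PlastomicsError("consensus needs >= 2 rows")
    arr = aln.to_array()
    counts = np.stack([(arr == b).sum(axis=0) for b in _BASES], axis=1)
    gaps = (arr == GAP.encode()).sum(axis=0)
    best = counts.argmax(axis=1)  # argmax is the alphabetical tie-break
    best_count = counts.max(axis=1)
    is_consensus = (best_count > 0) & (gaps <= best_count)
    consensus_chars = np.where(
        is_consensus, np.array([b"A", b"C", b"G", b"T"])[best], b"-"
    )
    col_to_pos: list[int | None] = []
    pos_to_col: list[int] = []
    pos = 0
    for col, keep in enumerate(is_consensus):
        if keep:
            pos += 1
            col_to_pos.append(pos)
            pos_to_col.append(col + 1)
        else:
            col_to_pos.append(None)
    sequence = b"".join(
        consensus_chars[i] for i in range(aln.n_cols) if is_consensus[i]
    ).decode()
    return Consensus(sequence, col_to_pos, pos_to_col)


def call_variants(
    aln: MultipleAlignment, consensus: Consensus | None = None
) -> list[VariantRecord]:
    """All consensus positions where >= 1 sample differs from the consensus.

    A sample gap at a consensus position is an indel-type state; N and
    missing data never trigger a variant; other IUPAC ambiguity codes count
    as mismatches.  Terminal gap runs are masked as missing first.
    """
    masked = aln.mask_terminal_gaps()
    if consensus is None:
        consensus = build_consensus(masked)
    arr = masked.to_array()
    out = []
    neutral = (b"N", MISSING.encode())
    for pos0, col1 in enumerate(consensus.pos_to_col):
        col = arr[:, col1 - 1]
        cons = consensus.sequence[pos0].encode()
        differs = (col != cons) & ~np.isin(col, neutral)
        if not differs.any():
            continue
        kind = "indel" if (col[differs] == GAP.encode()).any() else "SNP"
        alleles = {
            sid: col[i].decode() for i, sid in enumerate(masked.ids)
        }
        out.append(
            VariantRecord(
                position=pos0 + 1,
                kind=kind,
                consensus_allele=cons.decode(),
                alleles=alleles,
                column=col1,
            )
        )
    return out


def map_position(
    aln: MultipleAlignment,
    sample_id: str,
    consensus_pos: int,
    consensus: Consensus | None = None,
) -> int | None:
    """Consensus coordinate -> 1-based ungapped coordinate in a sample.

    Returns None (the explicit gap result) when the sample has a gap at
    that consensus position.
    """
    if consensus is None:
        consensus = build_consensus(aln.mask_terminal_gaps())
    if not 1 <= consensus_pos <= len(consensus.pos_to_col):
        raise IndexError(f"consensus position {consensus_pos} out of range")
    col = consensus.pos_to_col[consensus_pos - 1]
    pos = aln.sample_positions(sample_id)[col - 1]
    return int(pos) if pos > 0 else None


def map_sample_position(
    aln: MultipleAlignment,
    sample_id: str,
    sample_pos: int,
    consensus: Consensus | None = None,
) -> int | None:
    """Inverse of :func:`map_position`; None when the sample base falls in a
    column without a consensus coordinate."""
    if consensus is None:
        consensus = build_consensus(aln.mask_terminal_gaps())
    col = aln.column_of(sample_id, sample_pos)
    return consensus.col_to_pos[col - 1]


# ---------------------------------------------------------------------------
# Windows, indel events, identity profile
# ---------------------------------------------------------------------------

def window_counts(
    variants: Sequence[VariantRecord],
    consensus_len: int,
    window: int = 10_000,
    n_top: int = 3,
) -> WindowProfile:
    """Variable-position counts in non-overlapping tiling windows.

    Windows tile the consensus (last window short); ``top`` ranks windows
    by count (ties by start coordinate).
    """
    if window < 1:
        raise PlastomicsError("window must be >= 1")
    edges = list(range(1, consensus_len + 1, window))
    counts = [0] * len(edges)
    for v in variants:
        counts[(v.position - 1) // window] += 1
    windows = [
        (start, min(start + window - 1, consensus_len), counts[i])
        for i, start in enumerate(edges)
    ]
    top = sorted(windows, key=lambda w: (-w[2], w[0]))[:n_top]
    return WindowProfile(windows=windows, top=top)


def find_indel_events(
    aln: MultipleAlignment,
    min_len: int = 50,
    consensus: Consensus | None = None,
    reference: PlastomeRecord | None = None,
    reference_id: str | None = None,
) -> list[IndelEvent]:
    """Maximal per-sample gap runs of >= ``min_len`` alignment columns.

    Events are reported at the consensus coordinate of the first deleted
    column (runs sharing identical breakpoints across samples are grouped).
    Terminal gap runs are missing data, not deletions.  When a reference
    record and its alignment id are supplied, each event is annotated with
    the nearest flanking features of that reference.
    """
    masked = aln.mask_terminal_gaps()
    if consensus is None:
        consensus = build_consensus(masked)
    groups: dict[tuple[int, int], list[str]] = {}
    for sid, row in zip(masked.ids, masked.rows):
        col = 0
        n = len(row)
        while col < n:
            if row[col] == GAP:
                run_start = col
                while col < n and row[col] == GAP:
                    col += 1
                run_len = col - run_start
                if run_len >= min_len:
                    # consensus coordinate of the first deleted column:
                    # nearest preceding consensus position + 1
                    start_pos = None
                    for c in range(run_start, -1, -1):
                        if consensus.col_to_pos[c] is not None:
                            start_pos = consensus.col_to_pos[c]
                            break
                    if start_pos is None:
                        start_pos = 0
                    if consensus.col_to_pos[run_start] is None:
                        start_pos += 1
                    groups.setdefault((start_pos, run_len), []).append(sid)
            else:
                col += 1
    events = [
        IndelEvent(samples=sorted(sids), start=start, length=length)
        for (start, length), sids in sorted(groups.items())
    ]
    if reference is not None and reference_id is not None:
        for ev in events:
            ev.flanking = _flanking_features(
                aln, consensus, reference, reference_id, ev
            )
    return events


def _flanking_features(aln, consensus, record, reference_id, event):
    ref_pos = map_position(aln, reference_id, max(event.start - 1, 1), consensus)
    if ref_pos is None:
        return None
    before = [f for f in record.features if f.kind == "gene" and f.end <= ref_pos]
    after = [f for f in record.features if f.kind == "gene" and f.start > ref_pos]
    left = max(before, key=lambda f: f.end).gene if before else ""
    right = min(after, key=lambda f: f.start).gene if after else ""
    return (left, right)


def identity_profile(
    pairwise_aln: MultipleAlignment, window: int = 100, step: int = 25
) -> list[tuple[float, float]]:
    """Sliding-window percent identity over a two-row alignment.

    Gaps count as mismatches; returns (window midpoint in alignment
    columns, % identity) pairs.
    """
    if pairwise_aln.n_rows != 2:
        raise PlastomicsError("identity profile needs exactly two rows")
    n = pairwise_aln.n_cols
    if window > n:
        raise PlastomicsError(f"window {window} exceeds alignment length {n}")
    a = np.frombuffer(pairwise_aln.rows[0].encode(), dtype="S1")
    b = np.frombuffer(pairwise_aln.rows[1].encode(), dtype="S1")
    same = (a == b) & np.isin(a, _BASES)
    cum = np.concatenate([[0], np.cumsum(same)])
    out = []
    for start in range(0, n - window + 1, step):
        ident = (cum[start + window] - cum[start]) / window * 100.0
        out.append((start + (window + 1) / 2.0, float(ident)))
    return out
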