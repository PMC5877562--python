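"""Quadripartite structure of circular plastomes.

Land-plant chloroplast genomes carry two large inverted repeats (IRa, IRb;
typically ~25-27 kb) separating a large and a small single-copy region
(LSC, SSC).  This module finds the maximal pair of reverse-complement
intervals, partitions the circle into LSC / IRb / SSC / IRa, and classifies
genes at the IR borders (complete vs. partial duplication — the rps19
situation at the IR/LSC junction).

Detection is k-mer seeded: matches between the sequence and its reverse
complement fall on a common anti-diagonal (the sum of the two copy start
coordinates is constant for one repeat pair), so seeds are grouped by
anti-diagonal, the dominant group is chosen, and the anchor is extended
outward, absorbing internal mismatch/indel gaps up to ``bridge`` bp.
Circularity is handled by repeating the scan on the sequence rotated by
half its length and keeping the longer repeat.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .errors import PlastomicsError
from .io import PlastomeRecord, revcomp

_SEED_K = 25


@dataclass(frozen=True)
class Interval:
    """1-based inclusive interval on the circular genome.

    ``start > end`` means the interval wraps past the origin.
    """

    start: int
    end: int
    genome_length: int

    @property
    def length(self) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return self.genome_length - self.start + 1 + self.end

    def contains(self, pos: int) -> bool:
        if self.start <= self.end:
            return self.start <= pos <= self.end
        return pos >= self.start or pos <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return any(
            self.contains(p)
            for p in (other.start, other.end)
        ) or any(other.contains(p) for p in (self.start, self.end))


@dataclass
class QuadripartitePartition:
    """The four region intervals, plus canonical lengths.

    ``regions`` maps LSC/IRb/SSC/IRa to intervals in the *input* coordinate
    frame; ``canonical_offset`` is the leftward rotation (0-based) that
    places the LSC start at position 1, giving the canonical order
    LSC -> IRb -> SSC -> IRa.
    """

    regions: dict[str, Interval]
    lsc_len: int
    ssc_len: int
    ir_len: int
    genome_length: int
    canonical_offset: int = 0

    def __post_init__(self) -> None:
        total = sum(iv.length for iv in self.regions.values())
        if total != self.genome_length:
            raise PlastomicsError(
                f"region lengths sum to {total}, genome is {self.genome_length}"
            )

    def region_of(self, pos: int) -> str:
        for label, iv in self.regions.items():
            if iv.contains(pos):
                return label
        raise PlastomicsError(f"position {pos} outside the genome")

    def canonical_regions(self) -> dict[str, tuple[int, int]]:
        """Region intervals after the canonical rotation (LSC starts at 1)."""
        out = {}
        pos = 1
        for label in ("LSC", "IRb", "SSC", "IRa"):
            length = self.regions[label].length
            out[label] = (pos, pos + length - 1)
            pos += length
        return out


@dataclass
class BorderGeneStatus:
    gene: str
    status: str  # duplicated_complete | duplicated_partial | single_copy | absent
    n_copies: int = 0
    copy_lengths: tuple[int, ...] = ()


# ---------------------------------------------------------------------------
# Inverted-repeat detection
# ---------------------------------------------------------------------------

def _comp(base: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A"}.get(base, "N")


def _seed_antidiagonals(seq: str, k: int) -> dict[int, list[int]]:
    """Map anti-diagonal D = i + j to sorted first-copy seed starts i.

    A seed is a k-mer at 0-based position i of ``seq`` equal to the reverse
    complement of the k-mer at position j; both copies of one inverted
    repeat contribute seeds with the same i + j.
    """
    n = len(seq)
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        index[seq[i : i + k]].append(i)
    diags: dict[int, list[int]] = defaultdict(list)
    rc = revcomp(seq)
    for p in range(n - k + 1):
        kmer = rc[p : p + k]
        hits = index.get(kmer)
        if not hits:
            continue
        j = n - p - k  # start, in seq coordinates, of the reverse-complemented block
        for i in hits:
            if i < j:  # count each pair once
                diags[i + j].append(i)
    return diags


def _extend_pair(seq: str, i0: int, j0: int, k: int, bridge: int) -> tuple[int, int, int]:
    """Ungapped extension of an anchored seed pair.

    Position x of copy 1 pairs with position (i0 + j0 + k - 1) - x of copy 2.
    Mismatch runs of <= ``bridge`` bp are absorbed when followed by at least
    k matching bases.  Returns 0-based (copy1_start, copy1_end_inclusive,
    anti-diagonal); the paired copy 2 follows from the mirror relation.
    """
    n = len(seq)
    mirror = i0 + j0 + k - 1

    def match(x: int) -> bool:
        y = mirror - x
        if x < 0 or y >= n or x >= y:
            return False
        return seq[x] == _comp(seq[y]) and seq[x] in "ACGT"

    # extend right from the end of the anchor
    hi = i0 + k - 1
    x = hi + 1
    while True:
        run_start = x
        while match(x):
            x += 1
        hi = x - 1
        # try to bridge a short mismatch run
        gap_end = x
        while gap_end - x < bridge and gap_end < n and not match(gap_end):
            gap_end += 1
        if gap_end == x or gap_end - x >= bridge:
            break
        if all(match(g) for g in range(gap_end, gap_end + k)):
            x = gap_end
        else:
            break
        if run_start == x:  # no progress
            break
    # extend left from the start of the anchor
    lo = i0
    x = lo - 1
    while True:
        while match(x):
            x -= 1
        lo = x + 1
        gap_start = x
        while x - gap_start < bridge and gap_start >= 0 and not match(gap_start):
            gap_start -= 1
        if gap_start == x or x - gap_start >= bridge:
            break
        if all(match(g) for g in range(gap_start, gap_start - k, -1)):
            x = gap_start
        else:
            break
    return lo, hi, mirror


def _detect_linear(seq: str, min_len: int, bridge: int, k: int):
    """Best reverse-complement repeat pair without wrapping the origin."""
    diags = _seed_antidiagonals(seq, k)
    if not diags:
        return None
    best = None
    # examine the few densest anti-diagonals only
    ranked = sorted(diags.items(), key=lambda kv: -len(kv[1]))[:5]
    for mirror_sum, starts in ranked:
        i0 = min(starts)
        j0 = mirror_sum - i0
        lo, hi, mirror = _extend_pair(seq, i0, j0, k, bridge)
        # the extension covers both copies when they are adjacent; clip copy 1
        # to the half that precedes its mirror image
        half = (mirror - 1) // 2
        hi1 = min(hi, half)
        length = hi1 - lo + 1
        if length < min_len:
            continue
        c2_start = mirror - hi1
        c2_end = mirror - lo
        if best is None or length > best[0]:
            best = (length, lo, hi1, c2_start, c2_end)
    return best


def detect_inverted_repeats(
    sequence: str, min_len: int = 1000, bridge: int = 10
) -> tuple[Interval, Interval] | None:
    """Find the two inverted-repeat intervals of a circular sequence.

    Returns the maximal pair of disjoint intervals where one equals the
    reverse complement of the other after bridging internal mismatch/indel
    gaps of <= ``bridge`` bp, or None when no repeat of at least ``min_len``
    bp exists (a genuine biological outcome: some lineages have lost the IR).
    """
    if min_len < 100:
        raise PlastomicsError("min_len must be >= 100")
    seq = sequence.upper()
    n = len(seq)
    if n < 2 * min_len:
        return None

    candidates = []
    best = _detect_linear(seq, min_len, bridge, _SEED_K)
    if best is not None:
        candidates.append((best, 0))
    shift = n // 2
    rotated = seq[shift:] + seq[:shift]
    best_rot = _detect_linear(rotated, min_len, bridge, _SEED_K)
    if best_rot is not None:
        candidates.append((best_rot, shift))
    if not candidates:
        return None

    # prefer the longer repeat; on ties, the unrotated frame
    (length, lo, hi, c2s, c2e), shift = max(
        candidates, key=lambda c: (c[0][0], -c[1])
    )

    def to_circular(p0: int) -> int:  # 0-based in rotated frame -> 1-based circular
        return (p0 + shift) % n + 1

    iv1 = Interval(to_circular(lo), to_circular(hi), n)
    iv2 = Interval(to_circular(c2s), to_circular(c2e), n)
    if iv1.overlaps(iv2):
        return None
    # order by circular start for determinism
    first, second = sorted((iv1, iv2), key=lambda iv: iv.start)
    return first, second


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

def partition_plastome(
    sequence: str, ir_intervals: tuple[Interval, Interval]
) -> QuadripartitePartition:
    """Label the two inter-IR arcs LSC (longer) and SSC (shorter).

    The canonical rotation places the LSC start at position 1 so the genome
    reads LSC -> IRb -> SSC -> IRa; IRb is the copy adjacent to the LSC end.
    """
    n = len(sequence)
    ir1, ir2 = ir_intervals
    if ir1.overlaps(ir2):
        raise PlastomicsError("IR intervals overlap after circular normalization")

    def arc(after: Interval, before: Interval) -> Interval:
        start = after.end % n + 1
        end = (before.start - 2) % n + 1
        return Interval(start, end, n)

    arc_a = arc(ir1, ir2)  # between ir1 end and ir2 start
    arc_b = arc(ir2, ir1)
    if arc_a.length >= arc_b.length:
        lsc, ssc = arc_a, arc_b
        irb, ira = ir2, ir1  # LSC precedes ir2 in circular order
    else:
        lsc, ssc = arc_b, arc_a
        irb, ira = ir1, ir2
    regions = {"LSC": lsc, "IRb": irb, "SSC": ssc, "IRa": ira}
    return QuadripartitePartition(
        regions=regions,
        lsc_len=lsc.length,
        ssc_len=ssc.length,
        ir_len=irb.length,
        genome_length=n,
        canonical_offset=(lsc.start - 1) % n,
    )


# ---------------------------------------------------------------------------
# Border genes
# ---------------------------------------------------------------------------

def classify_border_genes(
    record: PlastomeRecord,
    partition: QuadripartitePartition,
    gene_names: list[str] | None = None,
    full_length_fraction: float = 0.95,
) -> list[BorderGeneStatus]:
    """Duplication status of genes with respect to the inverted repeats.

    A gene is ``duplicated_complete`` when at least two copies within
    ``full_length_fraction`` of the longest copy exist and at least one lies
    (partly) inside an IR; a truncated second copy gives
    ``duplicated_partial``; one copy gives ``single_copy``; a queried name
    with no feature gives ``absent``.
    """
    if gene_names is None:
        gene_names = sorted(
            {f.gene for f in record.features if f.kind == "gene"},
            key=str.casefold,
        )
    ir_regions = [partition.regions["IRb"], partition.regions["IRa"]]
    out = []
    for name in gene_names:
        copies = [f for f in record.features if f.kind == "gene"
                  and f.gene.casefold() == name.casefold()]
        if not copies:
            out.append(BorderGeneStatus(name, "absent"))
            continue
        lengths = tuple(sorted((c.length for c in copies), reverse=True))
        if len(copies) == 1:
            out.append(BorderGeneStatus(name, "single_copy", 1, lengths))
            continue
        longest = lengths[0]
        full = [c for c in copies if c.length >= full_length_fraction * longest]
        in_ir = any(
            ir.contains(c.start) or ir.contains(c.end)
            for c in copies
            for ir in ir_regions
        )
        if len(full) >= 2 and in_ir:
            status = "duplicated_complete"
        else:
            status = "duplicated_partial"
        out.append(BorderGeneStatus(name, status, len(copies), lengths))
    return out
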