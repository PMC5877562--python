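"""Synthetic plastomes with known ground truth.

Builds quadripartite chloroplast-like genomes (LSC + IRb + SSC + IRa, the
IRa being the reverse complement of the IRb), evolves them down a clade
tree under Jukes-Cantor substitution, plants clade-fixed diagnostic SNPs
and large deletions, and records everything planted so downstream stages
(structure detection, variant census, diagnostic-SNP scan, phylogeny) can
be scored against truth without any downloaded data.

Default dimensions emulate the Meliaceae study system: a ~158 kb genome
(LSC 86 kb, IR 27 kb, SSC 18 kb), a five-taxon target clade with three
successively deeper outgroup tiers of five taxa each, 16 planted
clade-diagnostic sites, and shared large deletions (50-250 bp, including a
199 bp deletion carried by four of the five target taxa).

Randomness protocol: one integer seed expands into independent per-stage
streams (structure, evolution, site planting, indel planting), so adding a
stage never perturbs the output of an earlier one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .errors import SimulationError
from .io import FeatureAnnotation, MultipleAlignment, PlastomeRecord, revcomp
from .structure import Interval, QuadripartitePartition

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
# transversion partner used for planted diagnostic alleles (unambiguous recovery)
_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}


def _encode(seq: str) -> np.ndarray:
    codes = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise SimulationError("sequence contains non-ACGT characters")
    return codes


def _decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndelSpec:
    """One planted deletion: the carrier samples, its length, its region."""

    samples: tuple[str, ...]
    length: int
    region: str = "LSC"
    start: int | None = None  # explicit 1-based root coordinate, optional


@dataclass
class SimulationConfig:
    seed: int
    lsc_len: int = 86_000
    irb_len: int = 27_000
    ssc_len: int = 18_000
    n_target: int = 5
    tier_sizes: tuple[int, ...] = (5, 5, 5)
    crown_length: float = 0.005
    tier_depths: tuple[float, ...] = (0.02, 0.04, 0.08)
    n_diagnostic: int = 16
    indel_spec: tuple[IndelSpec, ...] | None = None
    n_extended: int = 100
    extended_length: float = 0.002
    trnk_intron_len: int = 2535

    def __post_init__(self) -> None:
        if min(self.lsc_len, self.irb_len, self.ssc_len) <= 0:
            raise SimulationError("region lengths must be positive")
        if self.crown_length < 0 or any(d < 0 for d in self.tier_depths):
            raise SimulationError("branch lengths must be >= 0")
        if len(self.tier_depths) < len(self.tier_sizes):
            raise SimulationError("need one depth per outgroup tier")
        if self.n_diagnostic > self.genome_length:
            raise SimulationError("n_diagnostic exceeds sequence length")

    @property
    def genome_length(self) -> int:
        return self.lsc_len + 2 * self.irb_len + self.ssc_len

    def target_ids(self) -> list[str]:
        return [f"target_{i+1}" for i in range(self.n_target)]

    def tier_ids(self) -> list[list[str]]:
        return [
            [f"tier{t+1}_{i+1}" for i in range(n)]
            for t, n in enumerate(self.tier_sizes)
        ]

    def default_indels(self) -> tuple[IndelSpec, ...]:
        """Study-like deletions relative to the clade ancestor.

        A 199 bp deletion shared by all but one target taxon (the
        psbE-petL-linker analogue), plus two exclusive deletions.
        """
        tgt = self.target_ids()
        specs = [IndelSpec(tuple(tgt[:-1]), 199, "LSC")]
        if len(tgt) >= 2:
            specs.append(IndelSpec((tgt[0],), 120, "LSC"))
            specs.append(IndelSpec((tgt[-2],), 60, "LSC"))
        return tuple(specs)


@dataclass
class PlantedTruth:
    """Everything the generator planted, for downstream scoring."""

    partition: QuadripartitePartition
    diagnostic_sites: list[tuple[int, str, str]] = field(default_factory=list)
    indel_events: list[tuple[str, int, int]] = field(default_factory=list)
    tree: dendropy.Tree | None = None

    def diagnostic_positions(self) -> list[int]:
        return [p for p, _, _ in self.diagnostic_sites]


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def _plant_features(config: SimulationConfig) -> list[FeatureAnnotation]:
    """Synthetic gene set exercising every annotation shape downstream code
    must handle: an IR/LSC-junction straddler with a truncated second copy
    (rps19-like), a gene fully duplicated in both IRs (rpl2-like), an
    intron-containing tRNA whose intron hosts a CDS (trnK/matK-like), a
    plain CDS (rbcL-like), and a pseudogene at the IRa/SSC border
    (ycf1-like)."""
    lsc, ir, ssc = config.lsc_len, config.irb_len, config.ssc_len
    L = config.genome_length
    feats: list[FeatureAnnotation] = []

    # rps19-like: straddles the LSC/IRb junction; its in-IR portion is
    # mirrored at the end of IRa, annotated as a truncated second copy.
    in_lsc = min(150, lsc // 4)
    in_ir = min(130, ir // 3)
    feats.append(FeatureAnnotation(
        "rps19", "gene", [(lsc - in_lsc + 1, lsc + in_ir, 1)]))
    feats.append(FeatureAnnotation(
        "rps19", "gene", [(L - in_ir + 1, L, -1)]))

    # rpl2-like: complete copies inside both IRs.
    g_len = min(900, ir // 2)
    b_start = lsc + ir // 4
    feats.append(FeatureAnnotation(
        "rpl2", "gene", [(b_start, b_start + g_len - 1, -1)]))
    # mirrored position inside IRa
    a_end = 2 * lsc + 2 * ir + ssc - b_start + 1  # mirror of b_start
    feats.append(FeatureAnnotation(
        "rpl2", "gene", [(a_end - g_len + 1, a_end, 1)]))

    # trnK-like tRNA with one intron hosting a matK-like CDS.
    intron = min(config.trnk_intron_len, max(200, lsc // 4))
    exon1, exon2 = 37, 35
    t_start = max(1, lsc // 10)
    t_mid1 = t_start + exon1 - 1
    t_mid2 = t_mid1 + intron + 1
    t_end = t_mid2 + exon2 - 1
    if t_end < lsc:
        feats.append(FeatureAnnotation(
            "trnK-UUU", "tRNA", [(t_start, t_mid1, -1), (t_mid2, t_end, -1)]))
        feats.append(FeatureAnnotation(
            "trnK-UUU", "gene", [(t_start, t_end, -1)]))
        cds_len = 3 * ((intron - 60) // 3)
        if cds_len >= 300:
            c_start = t_mid1 + 30
            feats.append(FeatureAnnotation(
                "matK", "gene", [(c_start, c_start + cds_len - 1, -1)]))
            feats.append(FeatureAnnotation(
                "matK", "CDS", [(c_start, c_start + cds_len - 1, -1)]))

    # rbcL-like plain CDS in the LSC.
    r_len = min(1428, 3 * (lsc // 6) // 3)
    r_start = lsc // 2
    if r_start + r_len - 1 < lsc:
        feats.append(FeatureAnnotation(
            "rbcL", "gene", [(r_start, r_start + r_len - 1, 1)]))
        feats.append(FeatureAnnotation(
            "rbcL", "CDS", [(r_start, r_start + r_len - 1, 1)]))

    # ycf1-like pseudogene fragment at the IRa/SSC border.
    y_len = min(1000, ssc // 3)
    y_start = lsc + ir + ssc - y_len // 2
    feats.append(FeatureAnnotation(
        "ycf1", "gene", [(y_start, y_start + y_len - 1, -1)], pseudo=True))
    return feats


def _break_palindrome_ends(segment: str) -> str:
    """Ensure the first base of a single-copy segment does not complement
    its last base (deterministic edit: advance the first base cyclically)."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    if len(segment) < 2 or segment[0] != comp[segment[-1]]:
        return segment
    order = "ACGT"
    first = order[(order.index(segment[0]) + 1) % 4]
    if first == comp[segment[-1]]:
        first = order[(order.index(first) + 1) % 4]
    return first + segment[1:]


def build_synthetic_plastome(
    config: SimulationConfig,
) -> tuple[PlastomeRecord, PlantedTruth]:
    """Generate the clade-ancestor genome and its planted truth.

    The sequence is LSC + IRb + SSC + IRa with IRa = revcomp(IRb); the
    planted partition is in canonical orientation (LSC starts at 1).
    """
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng = _rng(streams[0])
    lsc = _random_seq(rng, config.lsc_len)
    irb = _random_seq(rng, config.irb_len)
    ssc = _random_seq(rng, config.ssc_len)
    # break chance complementarity at the single-copy ends so the planted
    # repeat pair is exactly the maximal one: without this a repeat could
    # extend one or two bases into the SSC (or around the circle into the
    # LSC) whenever flanking bases happen to pair
    ssc = _break_palindrome_ends(ssc)
    lsc = _break_palindrome_ends(lsc)
    sequence = lsc + irb + ssc + revcomp(irb)
    L = config.genome_length
    regions = {
        "LSC": Interval(1, config.lsc_len, L),
        "IRb": Interval(config.lsc_len + 1, config.lsc_len + config.irb_len, L),
        "SSC": Interval(
            config.lsc_len + config.irb_len + 1,
            config.lsc_len + config.irb_len + config.ssc_len, L),
        "IRa": Interval(L - config.irb_len + 1, L, L),
    }
    partition = QuadripartitePartition(
        regions=regions,
        lsc_len=config.lsc_len,
        ssc_len=config.ssc_len,
        ir_len=config.irb_len,
        genome_length=L,
        canonical_offset=0,
    )
    record = PlastomeRecord(
        id="ancestor", sequence=sequence, features=_plant_features(config)
    )
    return record, PlantedTruth(partition=partition)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def clade_tree(config: SimulationConfig) -> dendropy.Tree:
    """Ladderized target clade nested inside successively deeper outgroup
    tiers, every edge length in expected substitutions/site."""

    def ladder(names: Sequence[str], bl: float) -> str:
        if len(names) == 1:
            return f"{names[0]}:{bl}"
        inner = ladder(names[:-1], bl)
        return f"({inner},{names[-1]}:{bl}):{bl}"

    sub = ladder(config.target_ids(), config.crown_length)
    for tier_names, depth in zip(config.tier_ids(), config.tier_depths):
        out = ladder(tier_names, config.crown_length)
        sub = f"({sub}:{depth},{out}:{depth})"
    return dendropy.Tree.get(data=sub + ";", schema="newick", preserve_underscores=True)


def evolve_clade(
    root_seq: str, tree: dendropy.Tree, seed
) -> dict[str, str]:
    """Evolve a root sequence down a tree under Jukes-Cantor substitution.

    Each edge of length d substitutes every site independently with
    probability p = (3/4)(1 - exp(-4 d / 3)), the replacement drawn
    uniformly from the three alternative bases.  Deterministic for a fixed
    seed (edges are visited in preorder).
    """
    if not root_seq:
        raise SimulationError("empty root sequence")
    root_codes = _encode(root_seq)
    rng = _rng(seed)
    leaves: dict[str, str] = {}
    stack = [(tree.seed_node, root_codes)]
    while stack:
        node, codes = stack.pop()
        length = node.edge.length
        if length is None:
            length = 0.0
        if length < 0:
            raise SimulationError(f"negative branch length {length}")
        if length > 0:
            p = 0.75 * (1.0 - np.exp(-4.0 * length / 3.0))
            hit = rng.random(codes.size) < p
            n_hit = int(hit.sum())
            if n_hit:
                codes = codes.copy()
                codes[hit] = (
                    codes[hit] + rng.integers(1, 4, size=n_hit, dtype=np.uint8)
                ) % 4
        children = node.child_nodes()
        if not children:
            leaves[node.taxon.label if node.taxon else node.label] = _decode(codes)
        else:
            # reversed so streams are drawn in left-to-right preorder
            for child in reversed(children):
                stack.append((child, codes))
    return leaves


def impose_concerted_ir(
    seq: str, partition: QuadripartitePartition
) -> str:
    """Overwrite the IRa with the reverse complement of the IRb.

    Plastome inverted repeats evolve in concert (gene conversion keeps the
    two copies near-identical within a genome), so after independent
    per-site substitution the mirror is re-imposed.  Coordinates are the
    ancestor frame, so this must run before any deletions are applied.
    """
    irb = partition.regions["IRb"]
    ira = partition.regions["IRa"]
    copy_b = seq[irb.start - 1 : irb.end]
    return seq[: ira.start - 1] + revcomp(copy_b) + seq[ira.end :]


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

def plant_diagnostic_sites(
    seqs: Mapping[str, str],
    target_ids: Sequence[str],
    n_sites: int,
    seed,
) -> tuple[dict[str, str], list[tuple[int, str, str]]]:
    """Plant clade-fixed diagnostic SNPs at currently monomorphic sites.

    At each planted site every target-clade sample receives a transversion
    of the shared background allele, so the target allele is absent from
    every non-target sample.  Returns the edited sequences and the truth
    list of (1-based position, target allele, background allele).
    """
    ids = list(seqs)
    missing = [t for t in target_ids if t not in seqs]
    if missing:
        raise SimulationError(f"target ids absent from sequences: {missing}")
    if n_sites == 0:
        return {k: v for k, v in seqs.items()}, []
    mat = np.stack([_encode(seqs[i]) for i in ids])
    mono = np.nonzero((mat == mat[0]).all(axis=0))[0]
    if n_sites > mono.size:
        raise SimulationError(
            f"requested {n_sites} sites but only {mono.size} monomorphic"
        )
    rng = _rng(seed)
    chosen = np.sort(rng.choice(mono, size=n_sites, replace=False))
    out = {k: list(v) for k, v in seqs.items()}
    truth = []
    for pos0 in chosen:
        background = seqs[ids[0]][pos0]
        allele = _TRANSVERSION[background]
        for t in target_ids:
            out[t][pos0] = allele
        truth.append((int(pos0) + 1, allele, background))
    return {k: "".join(v) for k, v in out.items()}, truth


def plant_indels(
    seqs: Mapping[str, str],
    indel_spec: Sequence[IndelSpec],
    seed,
    partition: QuadripartitePartition | None = None,
    avoid: Sequence[int] = (),
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Delete the specified intervals from the specified samples.

    Interval starts are drawn inside the requested region (or taken from
    ``spec.start``), never overlapping an ``avoid`` position (planted
    diagnostic sites) nor another deletion in any carrier.  Deletions are
    relative to the ancestor coordinate frame shared by all ``seqs``.
    Returns edited sequences plus truth triples (sample, start, length).
    """
    rng = _rng(seed)
    length0 = len(next(iter(seqs.values())))
    taken: dict[str, list[tuple[int, int]]] = {k: [] for k in seqs}
    events: list[tuple[str, int, int]] = []
    avoid_set = set(avoid)

    def clashes(sample: str, start: int, length: int) -> bool:
        end = start + length - 1
        if any(start <= p <= end for p in avoid_set):
            return True
        return any(s <= end and start <= e for s, e in taken[sample])

    for spec in indel_spec:
        if spec.length < 1:
            raise SimulationError("deletion length must be >= 1")
        if partition is not None and spec.start is None:
            region = partition.regions[spec.region]
            lo, hi = region.start, region.end - spec.length
        else:
            lo, hi = 1, length0 - spec.length
        if spec.start is not None:
            start = spec.start
            if any(clashes(s, start, spec.length) for s in spec.samples):
                raise SimulationError(
                    f"deletion at {start} overlaps an earlier deletion"
                )
        else:
            if hi < lo:
                raise SimulationError(
                    f"region {spec.region} too short for a {spec.length} bp deletion"
                )
            for _ in range(1000):
                start = int(rng.integers(lo, hi + 1))
                if not any(clashes(s, start, spec.length) for s in spec.samples):
                    break
            else:
                raise SimulationError("could not place deletion without overlap")
        end = start + spec.length - 1
        if end > length0:
            raise SimulationError("deletion extends past the sequence end")
        for sample in spec.samples:
            if sample not in seqs:
                raise SimulationError(f"unknown sample {sample!r}")
            taken[sample].append((start, end))
            events.append((sample, start, spec.length))

    out = {}
    for sample, seq in seqs.items():
        cuts = sorted(taken[sample], reverse=True)
        s = seq
        for start, end in cuts:
            s = s[: start - 1] + s[end:]
        out[sample] = s
    return out, events


def true_alignment(
    seqs: Mapping[str, str],
    events: Sequence[tuple[str, int, int]],
    ancestor_length: int,
) -> MultipleAlignment:
    """The alignment implied by the known homology: ancestor coordinates as
    columns, deletions rendered as gap runs."""
    ids, rows = [], []
    for sample, seq in seqs.items():
        cuts = sorted(
            [(start, length) for s, start, length in events if s == sample]
        )
        row = []
        cursor = 0  # consumed chars of the deleted sequence
        pos = 1
        for start, length in cuts:
            n_keep = start - pos
            row.append(seq[cursor : cursor + n_keep])
            row.append("-" * length)
            cursor += n_keep
            pos = start + length
        row.append(seq[cursor:])
        row = "".join(row)
        if len(row) != ancestor_length:
            raise SimulationError(
                f"{sample}: reconstructed row is {len(row)} bp, "
                f"expected {ancestor_length}"
            )
        ids.append(sample)
        rows.append(row)
    return MultipleAlignment(ids, rows)


# ---------------------------------------------------------------------------
# Whole-study bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    config: SimulationConfig
    ancestor: PlastomeRecord
    truth: PlantedTruth
    sequences: dict[str, str]
    alignment: MultipleAlignment
    target_alignment: MultipleAlignment
    extended_target: dict[str, str]
    grouping: "object"


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Run the full generator: genome, clade, planted SNPs and deletions.

    ``alignment`` covers the target clade plus all outgroup tiers in
    ancestor coordinates; ``target_alignment`` is the target-clade subset
    (the whole-plastome diversity analysis operates on the target clade
    only).  ``extended_target`` holds additional conspecific-scale target
    sequences for the validation stage of the diagnostic-SNP scan.
    """
    from .diagnostics import TaxonGrouping

    streams = np.random.SeedSequence(config.seed).spawn(5)
    ancestor, truth = build_synthetic_plastome(config)
    tree = clade_tree(config)
    truth.tree = tree
    seqs = evolve_clade(ancestor.sequence, tree, streams[1])
    # concerted IR evolution: every genome keeps IRa = revcomp(IRb)
    seqs = {
        sid: impose_concerted_ir(s, truth.partition) for sid, s in seqs.items()
    }

    target_ids = config.target_ids()
    seqs, sites = plant_diagnostic_sites(
        seqs, target_ids, config.n_diagnostic, streams[2]
    )
    truth.diagnostic_sites = sites

    indel_spec = config.indel_spec
    if indel_spec is None:
        indel_spec = config.default_indels()
    seqs, events = plant_indels(
        seqs, indel_spec, streams[3],
        partition=truth.partition,
        avoid=truth.diagnostic_positions(),
    )
    truth.indel_events = events

    alignment = true_alignment(seqs, events, config.genome_length)
    target_alignment = MultipleAlignment(
        target_ids, [alignment.row(t) for t in target_ids]
    )

    # extended target-clade individuals: shallow divergence from the first
    # target taxon, diagnostic alleles therefore retained
    ext_tree = dendropy.Tree.get(
        data="(" + ",".join(
            f"ext_{i+1}:{config.extended_length}"
            for i in range(config.n_extended)
        ) + ");",
        schema="newick", preserve_underscores=True,
    )
    extended = evolve_clade(seqs[target_ids[0]], ext_tree, streams[4])

    tiers = {"target": target_ids}
    for t, ids in enumerate(config.tier_ids()):
        tiers[f"tier{t+1}"] = ids
    assignments = {s: label for label, ids in tiers.items() for s in ids}
    grouping = TaxonGrouping(
        assignments=assignments, tier_order=list(tiers)
    )
    return SyntheticStudy(
        config=config,
        ancestor=ancestor,
        truth=truth,
        sequences=seqs,
        alignment=alignment,
        target_alignment=target_alignment,
        extended_target=extended,
        grouping=grouping,
    )
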