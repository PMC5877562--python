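"""Readers and writers for the standard formats the pipeline touches.

No science lives here: FASTA, GenBank flat files, gapped-FASTA alignments,
Newick trees, tab-separated variant/grouping tables.  Parsing is delegated
to Biopython / dendropy; this layer adds the validation contracts the rest
of the package relies on (uppercase sequences, equal-length alignment rows,
1-based inclusive coordinates everywhere).

Readers reject malformed input with a distinct error (:mod:`plastomics.errors`)
rather than silently truncating.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import (
    DuplicateIdError,
    EmptyRecordError,
    FormatError,
    GroupingError,
    LocationError,
    RaggedAlignmentError,
)

GAP = "-"
MISSING = "?"
_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

FEATURE_KINDS = ("gene", "CDS", "tRNA", "rRNA")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FeatureAnnotation:
    """One annotated feature on a plastome.

    ``parts`` are 1-based inclusive ``(start, end, strand)`` tuples in
    genome coordinates, ordered along the feature; a feature with k parts
    has k - 1 introns (unless it is trans-spliced, in which case the parts
    are transcribed from separate loci).
    """

    gene: str
    kind: str
    parts: list[tuple[int, int, int]]
    pseudo: bool = False
    trans_spliced: bool = False

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise LocationError(f"unsupported feature kind {self.kind!r}")
        for start, end, strand in self.parts:
            if start > end:
                raise LocationError(
                    f"{self.gene}: part start {start} > end {end}"
                )
            if strand not in (1, -1):
                raise LocationError(f"{self.gene}: strand must be +1/-1")

    @property
    def n_introns(self) -> int:
        return len(self.parts) - 1

    def intron_lengths(self) -> list[int]:
        """Gap between consecutive parts, in genome order."""
        parts = sorted(self.parts)
        return [parts[i + 1][0] - parts[i][1] - 1 for i in range(len(parts) - 1)]

    @property
    def start(self) -> int:
        return min(p[0] for p in self.parts)

    @property
    def end(self) -> int:
        return max(p[1] for p in self.parts)

    @property
    def length(self) -> int:
        return sum(end - start + 1 for start, end, _ in self.parts)


@dataclass
class PlastomeRecord:
    """One circular plastome: identifier, uppercase sequence, features."""

    id: str
    sequence: str
    features: list[FeatureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise EmptyRecordError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - set("ACGTNRYSWKMBDHV")
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )
        for feat in self.features:
            if feat.end > len(self.sequence):
                raise LocationError(
                    f"{feat.gene}: location end {feat.end} outside sequence "
                    f"of length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def genes(self) -> list[FeatureAnnotation]:
        return [f for f in self.features if f.kind == "gene"]

    def features_named(self, gene: str) -> list[FeatureAnnotation]:
        name = gene.casefold()
        return [f for f in self.features if f.gene.casefold() == name]


@dataclass
class MultipleAlignment:
    """Ordered, equal-length gapped sequences.

    Gap character is ``-``; ``?`` marks missing data (used for terminal
    alignment gaps, which are end-trimming artifacts rather than indels).
    Degapping row *i* returns input sequence *i*.
    """

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise RaggedAlignmentError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise DuplicateIdError("duplicate ids in alignment")
        self.rows = [r.upper() for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise RaggedAlignmentError(
                f"alignment rows have unequal lengths {sorted(lengths)}"
            )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, sample_id: str) -> str:
        try:
            return self.rows[self.ids.index(sample_id)]
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in alignment") from None

    def column(self, col: int) -> str:
        """Column ``col`` (1-based) as a string, one char per row."""
        return "".join(r[col - 1] for r in self.rows)

    def degapped(self, sample_id: str) -> str:
        return self.row(sample_id).replace(GAP, "").replace(MISSING, "")

    def to_array(self) -> np.ndarray:
        """(n_rows, n_cols) array of single-byte characters."""
        return np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype="S1"
        ).reshape(self.n_rows, self.n_cols)

    def sample_positions(self, sample_id: str) -> np.ndarray:
        """Per-column 1-based ungapped position in ``sample_id`` (0 at gaps)."""
        row = np.frombuffer(self.row(sample_id).encode("ascii"), dtype="S1")
        isbase = (row != GAP.encode()) & (row != MISSING.encode())
        pos = np.cumsum(isbase)
        pos[~isbase] = 0
        return pos

    def column_of(self, sample_id: str, sample_pos: int) -> int:
        """1-based alignment column holding base ``sample_pos`` of a sample."""
        pos = self.sample_positions(sample_id)
        hits = np.nonzero(pos == sample_pos)[0]
        if hits.size == 0:
            raise IndexError(
                f"position {sample_pos} beyond sequence {sample_id!r}"
            )
        return int(hits[0]) + 1

    def mask_terminal_gaps(self) -> "MultipleAlignment":
        """Replace leading/trailing gap runs with ``?`` (missing data)."""
        rows = []
        for row in self.rows:
            stripped = row.lstrip(GAP)
            lead = len(row) - len(stripped)
            stripped = stripped.rstrip(GAP)
            trail = len(row) - lead - len(stripped)
            rows.append(MISSING * lead + stripped + MISSING * trail)
        return MultipleAlignment(list(self.ids), rows)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA into ``(id, uppercase sequence)`` pairs."""
    records = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FormatError(f"{path}: not parseable as FASTA: {exc}") from exc
    for rec in parsed:
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise EmptyRecordError(f"empty FASTA record {rec.id!r} in {path}")
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, width: int = 70
) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignments and groupings
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path) -> MultipleAlignment:
    """Read a gapped FASTA alignment; rows must be equally long."""
    records = read_fasta(path)
    ids = [r[0] for r in records]
    rows = [r[1] for r in records]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise RaggedAlignmentError(
            f"{path}: alignment rows have unequal lengths {sorted(lengths)}"
        )
    return MultipleAlignment(ids, rows)


def write_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    write_fasta(zip(aln.ids, aln.rows), path)


def read_grouping(path: str | Path, alignment_ids: Sequence[str] | None = None):
    """Read a two-column TSV (sample id, tier label) into a TaxonGrouping.

    Tier order follows first appearance; the first tier listed is the
    target clade.  When ``alignment_ids`` is given, every id must be
    covered or a GroupingError is raised.
    """
    from .diagnostics import TaxonGrouping  # local import: io must not depend on science modules at import time

    assignments: dict[str, str] = {}
    tier_order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GroupingError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            sample, tier = parts
            if sample in assignments:
                raise GroupingError(f"{path}: duplicate sample {sample!r}")
            assignments[sample] = tier
            if tier not in tier_order:
                tier_order.append(tier)
    if not tier_order:
        raise GroupingError(f"{path}: empty grouping file")
    grouping = TaxonGrouping(assignments=assignments, tier_order=tier_order)
    if alignment_ids is not None:
        missing = [i for i in alignment_ids if i not in assignments]
        if missing:
            raise GroupingError(
                f"{path}: alignment ids without a tier: {missing}"
            )
    return grouping


def write_grouping(grouping, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tier in grouping.tier_order:
            for sample in grouping.samples_in(tier):
                fh.write(f"{sample}\t{tier}\n")


# ---------------------------------------------------------------------------
# GenBank flat files
# ---------------------------------------------------------------------------

def _feature_from_biopython(feat: SeqFeature, seq_len: int) -> FeatureAnnotation:
    name = feat.qualifiers.get("gene", feat.qualifiers.get("locus_tag", ["?"]))[0]
    parts = []
    for loc in feat.location.parts:
        start = int(loc.start) + 1  # Biopython is 0-based half-open
        end = int(loc.end)
        if end > seq_len or start < 1:
            raise LocationError(
                f"{name}: location {start}..{end} outside sequence ({seq_len} bp)"
            )
        parts.append((start, end, int(loc.strand or 1)))
    return FeatureAnnotation(
        gene=name,
        kind=feat.type,
        parts=parts,
        pseudo="pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers,
        trans_spliced="trans_splicing" in feat.qualifiers,
    )


def read_genbank_features(path: str | Path) -> PlastomeRecord:
    """Parse a GenBank flat file (features + ORIGIN) into a PlastomeRecord.

    Handles simple, ``join(...)`` and ``complement(...)`` locations; only
    gene/CDS/tRNA/rRNA features are retained.
    """
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise FormatError(f"{path}: not a parseable GenBank file: {exc}") from exc
    seq = str(rec.seq).upper()
    features = [
        _feature_from_biopython(f, len(seq))
        for f in rec.features
        if f.type in FEATURE_KINDS
    ]
    return PlastomeRecord(id=rec.id or rec.name, sequence=seq, features=features)


def write_genbank(record: PlastomeRecord, path: str | Path) -> None:
    """Emit a minimal GenBank flat file (round-trips through the reader)."""
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id[:16].replace(" ", "_"),
        description="synthetic plastome",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    for feat in record.features:
        locs = [
            SimpleLocation(start - 1, end, strand) for start, end, strand in feat.parts
        ]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        qualifiers = {"gene": [feat.gene]}
        if feat.pseudo:
            qualifiers["pseudo"] = [""]
        if feat.trans_spliced:
            qualifiers["trans_splicing"] = [""]
        rec.features.append(
            SeqFeature(location, type=feat.kind, qualifiers=qualifiers)
        )
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# Gene census
# ---------------------------------------------------------------------------

@dataclass
class GeneCensus:
    """Counts of annotated genes (paper-style accounting).

    ``unique`` counts distinct gene names after case normalization, so a
    gene duplicated in the inverted repeats (or a trans-spliced gene
    annotated in parts) contributes once; ``total`` counts gene features.
    """

    total: int
    unique: int
    duplicated: int
    protein_unique: int
    trna_unique: int
    rrna_unique: int
    protein_total: int
    trna_total: int
    rrna_total: int
    genes_with_introns: int
    intron_lengths: dict[str, list[int]]

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        return d


def gene_census(record: PlastomeRecord) -> GeneCensus:
    """Census of a parsed record; an empty record yields zero counts."""

    def names(kind: str) -> list[str]:
        return [f.gene.casefold() for f in record.features if f.kind == kind]

    gene_names = names("gene")
    unique_names = sorted(set(gene_names))
    duplicated = sum(1 for n in unique_names if gene_names.count(n) >= 2)

    intron_lengths: dict[str, list[int]] = {}
    for feat in record.features:
        if feat.n_introns >= 1 and not feat.trans_spliced:
            lengths = feat.intron_lengths()
            prev = intron_lengths.get(feat.gene.casefold())
            if prev is None or len(lengths) > len(prev):
                intron_lengths[feat.gene.casefold()] = lengths

    return GeneCensus(
        total=len(gene_names),
        unique=len(unique_names),
        duplicated=duplicated,
        protein_unique=len(set(names("CDS"))),
        trna_unique=len(set(names("tRNA"))),
        rrna_unique=len(set(names("rRNA"))),
        protein_total=len(names("CDS")),
        trna_total=len(names("tRNA")),
        rrna_total=len(names("rRNA")),
        genes_with_introns=len(intron_lengths),
        intron_lengths=intron_lengths,
    )


# ---------------------------------------------------------------------------
# Newick and tables
# ---------------------------------------------------------------------------

def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse a Newick tree from a path or a literal string."""
    text = None
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    text = tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def write_variant_table(
    variants,
    sample_ids: Sequence[str],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    """TSV: consensus_pos, type, ref_allele, then one column per sample."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("consensus_pos\ttype\tref_allele\t" + "\t".join(sample_ids) + "\n")
        for v in variants:
            alleles = "\t".join(v.alleles[s] for s in sample_ids)
            fh.write(f"{v.position}\t{v.kind}\t{v.consensus_allele}\t{alleles}\n")


def write_tsv(frame, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """Write a pandas DataFrame as TSV, preceded by '#' comment lines."""
    buf = _io.StringIO()
    frame.to_csv(buf, sep="\t", index=False)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(buf.getvalue())
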