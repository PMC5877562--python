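"""Hierarchical clade-diagnostic SNP discovery in barcode genes.

The procedure mirrors classical two-locus plant barcoding practice
(matK/rbcL): in a grouped gene alignment, find every column where all
target-clade samples share one base that no first-tier outgroup sample
carries; confirm each candidate against an extended set of target-clade
sequences (any discordant base demotes it to ``dropped_polymorphic``);
then test the target allele against the allele sets of successively
broader outgroup tiers (e.g. rest-of-order, rest-of-rosids, rest-of-land-
plants).  A candidate is ``specific`` only when its target allele is
absent from every tier's allele set.  Finally, specific sites inside a CDS
are annotated with their codon position and amino-acid effect under the
plastid/bacterial genetic code (translation table 11).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .errors import GroupingError, PlastomicsError
from .io import GAP, MISSING, MultipleAlignment
from .variants import Consensus, build_consensus, map_position

_BASES = set("ACGT")
# characters that contribute no allele: gaps, missing data, total ambiguity
_SILENT = {GAP, MISSING, "N"}


@dataclass
class TaxonGrouping:
    """Sample-to-tier assignment with an ordered tier list.

    The first tier is the target clade; later tiers are successively
    broader outgroups.
    """

    assignments: dict[str, str]
    tier_order: list[str]

    def __post_init__(self) -> None:
        if not self.tier_order:
            raise GroupingError("no tiers defined")
        unknown = set(self.assignments.values()) - set(self.tier_order)
        if unknown:
            raise GroupingError(f"tiers not in tier_order: {sorted(unknown)}")
        if not self.samples_in(self.target_tier):
            raise GroupingError("target tier has no samples")

    @property
    def target_tier(self) -> str:
        return self.tier_order[0]

    @property
    def outgroup_tiers(self) -> list[str]:
        return self.tier_order[1:]

    def samples_in(self, tier: str) -> list[str]:
        return [s for s, t in self.assignments.items() if t == tier]


@dataclass
class DiagnosticCandidate:
    """One candidate clade-diagnostic alignment column."""

    consensus_pos: int
    ref_pos: int | None
    target_allele: str
    tier_alleles: dict[str, Counter] = field(default_factory=dict)
    status: str = "candidate"  # candidate | dropped_polymorphic | specific | not_specific
    extended_alleles: Counter | None = None
    uninformative_tiers: list[str] = field(default_factory=list)
    codon: "CodonEffect | None" = None


@dataclass
class CodonEffect:
    codon_index: int
    codon_position: int
    reference_aa: str
    alternative_aas: set[str]
    synonymous: bool


# ---------------------------------------------------------------------------
# Candidate discovery
# ---------------------------------------------------------------------------

def find_candidate_positions(
    aln: MultipleAlignment,
    grouping: TaxonGrouping,
    reference_id: str | None = None,
    consensus: Consensus | None = None,
) -> list[DiagnosticCandidate]:
    """Columns where the target clade is fixed for a base absent from every
    first-tier outgroup sample.

    A gap, N or ambiguity code in any target sample disqualifies the
    column; outgroup gaps and ambiguity codes contribute no allele but do
    not disqualify.  Positions are reported in consensus coordinates and,
    when ``reference_id`` is given (default: first target sample present),
    in that sample's ungapped coordinates.
    """
    masked = aln.mask_terminal_gaps()
    target_ids = [s for s in grouping.samples_in(grouping.target_tier)
                  if s in masked.ids]
    if not target_ids:
        raise GroupingError("no target-tier sample present in the alignment")
    if reference_id is None:
        reference_id = target_ids[0]
    tier1 = grouping.outgroup_tiers[0] if grouping.outgroup_tiers else None
    tier1_ids = (
        [s for s in grouping.samples_in(tier1) if s in masked.ids]
        if tier1 else []
    )
    if consensus is None:
        consensus = build_consensus(masked)

    target_rows = [masked.row(s) for s in target_ids]
    tier_rows = {
        tier: [(s, masked.row(s)) for s in grouping.samples_in(tier)
               if s in masked.ids]
        for tier in grouping.outgroup_tiers
    }
    candidates = []
    for pos0, col1 in enumerate(consensus.pos_to_col):
        c = col1 - 1
        chars = {row[c] for row in target_rows}
        if len(chars) != 1:
            continue
        allele = next(iter(chars))
        if allele not in _BASES:
            continue
        if tier1_ids and any(masked.row(s)[c] == allele for s in tier1_ids):
            continue
        if not tier1_ids:
            # with no outgroup tier there is no contrast to call
            continue
        tier_alleles = {
            tier: Counter(
                row[c] for _, row in rows if row[c] in _BASES
            )
            for tier, rows in tier_rows.items()
        }
        candidates.append(
            DiagnosticCandidate(
                consensus_pos=pos0 + 1,
                ref_pos=map_position(masked, reference_id, pos0 + 1, consensus),
                target_allele=allele,
                tier_alleles=tier_alleles,
            )
        )
    return candidates


# ---------------------------------------------------------------------------
# Validation against an extended target set
# ---------------------------------------------------------------------------

def validate_in_extended_set(
    candidates: Sequence[DiagnosticCandidate],
    extended_aln: MultipleAlignment,
    reference_id: str,
) -> list[DiagnosticCandidate]:
    """Demote candidates that are polymorphic in the extended target set.

    Columns are transferred via the reference sample's ungapped
    coordinates (it must be present in both alignments).  Partial
    sequences contribute no allele at columns they do not cover; a single
    discordant base demotes the candidate to ``dropped_polymorphic`` (the
    observed allele counts are retained as its evidence trail).
    """
    if reference_id not in extended_aln.ids:
        raise PlastomicsError(
            f"reference {reference_id!r} absent from the extended alignment"
        )
    masked = extended_aln.mask_terminal_gaps()
    for cand in candidates:
        if cand.ref_pos is None:
            raise PlastomicsError(
                f"candidate at consensus {cand.consensus_pos} has no "
                f"reference coordinate to map with"
            )
        try:
            col = masked.column_of(reference_id, cand.ref_pos)
        except IndexError as exc:
            raise PlastomicsError(
                f"candidate position {cand.ref_pos} unmappable into the "
                f"extended alignment"
            ) from exc
        observed = Counter(
            row[col - 1]
            for sid, row in zip(masked.ids, masked.rows)
            if row[col - 1] in _BASES
        )
        cand.extended_alleles = observed
        if set(observed) - {cand.target_allele}:
            cand.status = "dropped_polymorphic"
    return list(candidates)


# ---------------------------------------------------------------------------
# Tiered specificity
# ---------------------------------------------------------------------------

def classify_specificity(
    candidate: DiagnosticCandidate,
    tier_allele_sets: Mapping[str, Counter | set] | None = None,
) -> str:
    """Specific iff the target allele is absent from every outgroup tier.

    An empty tier allele set is uninformative: it is recorded on the
    candidate and the verdict is withheld (status stays ``candidate``)
    rather than silently counting as specific.  Candidates already dropped
    as polymorphic keep their status.
    """
    if candidate.status == "dropped_polymorphic":
        return candidate.status
    sets = tier_allele_sets if tier_allele_sets is not None else candidate.tier_alleles
    if not sets:
        candidate.uninformative_tiers = ["<none>"]
        return candidate.status
    empty = [tier for tier, alleles in sets.items() if not alleles]
    if empty:
        candidate.uninformative_tiers = empty
        return candidate.status
    union = set().union(*(set(a) for a in sets.values()))
    candidate.status = (
        "not_specific" if candidate.target_allele in union else "specific"
    )
    return candidate.status


# ---------------------------------------------------------------------------
# Codon effect
# ---------------------------------------------------------------------------

def annotate_codon_effect(
    cds_pos: int,
    cds_seq: str,
    target_allele: str,
    outgroup_alleles: Sequence[str],
) -> CodonEffect:
    """Codon arithmetic and amino-acid effect of a CDS substitution.

    ``cds_pos`` is 1-based within the strand-resolved CDS; translation is
    under the plastid/bacterial code (table 11).  The reference amino acid
    is read with the target allele substituted in; the alternative set
    substitutes each outgroup allele.
    """
    cds = cds_seq.upper()
    if not 1 <= cds_pos <= len(cds):
        raise PlastomicsError(
            f"CDS position {cds_pos} outside the {len(cds)} bp CDS"
        )
    if len(cds) % 3 != 0:
        warnings.warn(
            "CDS length is not a multiple of 3; translating the truncated frame",
            stacklevel=2,
        )
    codon_index = (cds_pos - 1) // 3 + 1
    codon_position = (cds_pos - 1) % 3 + 1
    start = 3 * (codon_index - 1)
    codon = list(cds[start : start + 3])
    if len(codon) < 3:
        raise PlastomicsError("position falls in an incomplete terminal codon")
    offset = codon_position - 1

    def translate(base: str) -> str:
        c = codon.copy()
        c[offset] = base
        return str(Seq("".join(c)).translate(table=11))

    ref_aa = translate(target_allele)
    alt_aas = {translate(b) for b in outgroup_alleles}
    return CodonEffect(
        codon_index=codon_index,
        codon_position=codon_position,
        reference_aa=ref_aa,
        alternative_aas=alt_aas,
        synonymous=alt_aas == {ref_aa},
    )


# ---------------------------------------------------------------------------
# Orientation of user-supplied gene FASTAs
# ---------------------------------------------------------------------------

def orient_sequences(
    seqs: Sequence[tuple[str, str]], reference: str, k: int = 12
) -> list[tuple[str, str]]:
    """Reverse-complement sequences whose k-mer similarity to the reference
    is higher in the reverse frame (GenBank gene pulls mix strands)."""
    from .io import revcomp

    ref_kmers = {reference[i : i + k] for i in range(len(reference) - k + 1)}
    out = []
    for sid, seq in seqs:
        fwd = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        rc = revcomp(seq)
        rev = {rc[i : i + k] for i in range(len(rc) - k + 1)}
        out.append((sid, rc if len(rev & ref_kmers) > len(fwd & ref_kmers) else seq))
    return out


# ---------------------------------------------------------------------------
# End-to-end barcode scan
# ---------------------------------------------------------------------------

@dataclass
class BarcodeReport:
    candidates: list[DiagnosticCandidate]
    reference_id: str

    def specific(self) -> list[DiagnosticCandidate]:
        return [c for c in self.candidates if c.status == "specific"]

    def to_frame(self) -> pd.DataFrame:
        """Tabular report: one row per candidate, allele evidence with
        minority counts rendered like 'A or C(1)'."""

        def render(counter: Counter | None) -> str:
            if not counter:
                return ""
            total = sum(counter.values())
            parts = []
            for base, n in counter.most_common():
                parts.append(base if n == max(counter.values()) and n > total / 2
                             else f"{base}({n})")
            return " or ".join(parts)

        rows = []
        for c in self.candidates:
            row = {
                "consensus_pos": c.consensus_pos,
                f"pos_{self.reference_id}": c.ref_pos,
                "target_allele": c.target_allele,
                "extended": render(c.extended_alleles),
                "status": c.status,
                "specific": c.status == "specific",
            }
            for tier, alleles in c.tier_alleles.items():
                row[tier] = render(alleles)
            if c.codon is not None:
                row["codon"] = c.codon.codon_index
                row["codon_pos"] = c.codon.codon_position
                row["aa_change"] = (
                    f"{c.codon.reference_aa}->"
                    + "/".join(sorted(c.codon.alternative_aas))
                )
            rows.append(row)
        return pd.DataFrame(rows)


def run_barcode_scan(
    target_aln: MultipleAlignment,
    grouping: TaxonGrouping,
    extended_target_aln: MultipleAlignment | None = None,
    tier_alignments: Mapping[str, MultipleAlignment] | None = None,
    cds_seq: str | None = None,
    cds_offset: int = 0,
    reference_id: str | None = None,
) -> BarcodeReport:
    """The full hierarchical scan over one barcode gene.

    1. candidate discovery in the grouped core alignment;
    2. optional validation in an extended target-clade alignment;
    3. optional allele collection from per-tier alignments (columns mapped
       through the reference sample), merged into each candidate's tiers;
    4. tiered specificity classification;
    5. codon-effect annotation of specific candidates when the reference
       CDS is supplied (``cds_offset``: reference bases preceding the CDS).
    """
    target_ids = [s for s in grouping.samples_in(grouping.target_tier)
                  if s in target_aln.ids]
    if reference_id is None:
        reference_id = target_ids[0] if target_ids else target_aln.ids[0]
    candidates = find_candidate_positions(target_aln, grouping, reference_id)
    if extended_target_aln is not None:
        candidates = validate_in_extended_set(
            candidates, extended_target_aln, reference_id
        )
    if tier_alignments:
        for tier, aln in tier_alignments.items():
            masked = aln.mask_terminal_gaps()
            for cand in candidates:
                if cand.status == "dropped_polymorphic" or cand.ref_pos is None:
                    continue
                col = masked.column_of(reference_id, cand.ref_pos)
                observed = Counter(
                    row[col - 1]
                    for sid, row in zip(masked.ids, masked.rows)
                    if sid != reference_id and row[col - 1] in _BASES
                )
                cand.tier_alleles.setdefault(tier, Counter()).update(observed)
    for cand in candidates:
        classify_specificity(cand)
    if cds_seq is not None:
        for cand in candidates:
            if cand.status != "specific" or cand.ref_pos is None:
                continue
            pos_in_cds = cand.ref_pos - cds_offset
            if 1 <= pos_in_cds <= len(cds_seq):
                outgroups = sorted(
                    set().union(*(set(a) for a in cand.tier_alleles.values()))
                ) if cand.tier_alleles else []
                cand.codon = annotate_codon_effect(
                    pos_in_cds, cds_seq, cand.target_allele, outgroups
                )
    return BarcodeReport(candidates=candidates, reference_id=reference_id)
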