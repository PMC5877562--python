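"""Worked example: a published-style family-level matK allele survey.

A compact dataset in the shape produced by :func:`plastomics.diagnostics.
run_barcode_scan`: 16 candidate positions in the matK barcode gene where
five Meliaceae plastomes are fixed for one base that differs from five
Sapindales outgroups, each position then screened against ~100 further
Meliaceae matK sequences (minority alleles recorded with their carrier
counts) and, where still monomorphic, against allele sets from three
successively broader outgroup tiers (other Sapindales, other rosids,
other land plants).  Positions are 1-based, given both on the ten-taxon
alignment consensus and on the Cedrela odorata matK gene sequence.

Seven positions are polymorphic within the extended Meliaceae set and
drop out; of the nine remaining, exactly four carry a Meliaceae allele
absent from every outgroup tier.  The example is small enough to verify
by eye and exercises the whole classification path.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .diagnostics import DiagnosticCandidate, classify_specificity

TIER_LABELS = ("sapindales", "rosids", "land_plants")

# number of extended target-clade sequences screened per position
_EXTENDED_N = 100


@dataclass(frozen=True)
class MatkSurveyRow:
    consensus_pos: int
    ref_pos: int  # position on the Cedrela odorata matK gene
    target_alleles: tuple[tuple[str, int], ...]  # (base, carriers), majority first
    tiers: tuple[tuple[str, ...], ...] | None  # allele sets per TIER_LABELS


def _row(cpos, rpos, target, tiers=None):
    return MatkSurveyRow(cpos, rpos, tuple(target), tiers)


#: minority counts are the surveyed carrier numbers; the majority count is
#: the remainder of the ~100-sequence extended set
MATK_FAMILY_SURVEY: tuple[MatkSurveyRow, ...] = (
    _row(208, 208, [("T", 100)], (("A", "C", "T"), ("C", "A"), ("C", "A"))),
    _row(280, 262, [("T", 99), ("C", 1)]),
    _row(346, 328, [("G", 100)], (("C", "T"), ("C", "A"), ("C", "A"))),
    _row(402, 378, [("A", 100)], (("C", "T", "A", "G"), ("A", "C"), ("A", "C"))),
    _row(574, 550, [("C", 97), ("T", 3)]),
    _row(618, 588, [("C", 99), ("A", 1)]),
    _row(639, 609, [("G", 100)],
         (("T", "G", "A", "C"), ("T", "G", "A", "C"), ("G", "A", "T"))),
    _row(861, 819, [("T", 100)], (("C",), ("C", "T", "G"), ("C",))),
    _row(995, 953, [("C", 96), ("T", 4)]),
    _row(1194, 1146, [("T", 100)], (("C", "T"), ("C", "T"), ("C",))),
    _row(1237, 1189, [("G", 97), ("A", 2), ("C", 1)]),
    _row(1239, 1191, [("G", 97), ("A", 3)]),
    _row(1318, 1270, [("G", 100)], (("A",), ("A",), ("A",))),
    _row(1389, 1341, [("C", 99), ("T", 1)]),
    _row(1478, 1430, [("C", 100)], (("G", "A"), ("G", "A", "T"), ("A", "G"))),
    _row(1494, 1446, [("T", 100)], (("A", "G"), ("G", "A"), ("G", "C"))),
)


def matk_survey_candidates() -> list[DiagnosticCandidate]:
    """The survey rows as classified DiagnosticCandidate objects.

    Rows polymorphic in the extended target set become
    ``dropped_polymorphic``; the rest are classified against their tier
    allele sets, yielding the four family-specific positions.
    """
    out = []
    for row in MATK_FAMILY_SURVEY:
        majority = row.target_alleles[0][0]
        cand = DiagnosticCandidate(
            consensus_pos=row.consensus_pos,
            ref_pos=row.ref_pos,
            target_allele=majority,
            extended_alleles=Counter(dict(row.target_alleles)),
            tier_alleles=(
                {
                    label: Counter({b: 1 for b in alleles})
                    for label, alleles in zip(TIER_LABELS, row.tiers)
                }
                if row.tiers is not None
                else {}
            ),
        )
        if len(row.target_alleles) > 1:
            cand.status = "dropped_polymorphic"
        else:
            classify_specificity(cand)
        out.append(cand)
    return out
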