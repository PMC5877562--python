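"""Orchestration of the three analyses: structure report, diversity report,
barcode scan.

Each runner is a plain function over in-memory objects; file emission is
optional and every emitted table starts with a provenance header (tool
version, config hash, seed).  Per-record failures in multi-genome reports
are isolated and logged so one broken input does not abort the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .errors import PlastomicsError
from .io import (
    MultipleAlignment,
    PlastomeRecord,
    gene_census,
    write_tsv,
    write_variant_table,
)
from .phylogeny import bootstrap_support
from .structure import (
    classify_border_genes,
    detect_inverted_repeats,
    partition_plastome,
)
from .variants import (
    build_consensus,
    call_variants,
    find_indel_events,
    window_counts,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    window: int = 10_000
    min_indel: int = 50
    min_ir: int = 1_000
    bridge: int = 10
    replicates: int = 100
    seed: int = 0
    out_dir: Path | None = None

    def hash(self) -> str:
        # analysis parameters only: the output location must not change the
        # provenance of identical runs
        payload = json.dumps(
            {
                k: str(v)
                for k, v in self.__dict__.items()
                if k != "out_dir"
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def provenance(config: RunConfig) -> list[str]:
    return [
        f"plastomics {__version__}",
        f"config_hash={config.hash()}",
        f"seed={config.seed}",
    ]


# ---------------------------------------------------------------------------
# Structure report
# ---------------------------------------------------------------------------

def run_structure_report(
    records: Sequence[PlastomeRecord],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-genome summary: size, LSC/SSC/IR lengths, gene counts, border
    genes.  Records without annotation get lengths only; a record that
    fails outright is logged and reported with an error column."""
    config = config or RunConfig()
    rows = []
    for record in records:
        t0 = time.perf_counter()
        row: dict = {"id": record.id, "genome_size": len(record)}
        try:
            ir = detect_inverted_repeats(
                record.sequence, min_len=config.min_ir, bridge=config.bridge
            )
            if ir is None:
                row.update(lsc=None, ssc=None, ir_len=None, note="no IR found")
            else:
                part = partition_plastome(record.sequence, ir)
                row.update(
                    lsc=part.lsc_len, ssc=part.ssc_len, ir_len=part.ir_len
                )
                if record.features:
                    census = gene_census(record)
                    row.update(
                        n_genes=census.total,
                        n_unique=census.unique,
                        n_intron_genes=census.genes_with_introns,
                    )
                    statuses = classify_border_genes(record, part)
                    dup = [
                        s.gene for s in statuses
                        if s.status == "duplicated_complete"
                    ]
                    partial = [
                        s.gene for s in statuses
                        if s.status == "duplicated_partial"
                    ]
                    row.update(
                        duplicated_complete=",".join(dup),
                        duplicated_partial=",".join(partial),
                    )
        except PlastomicsError as exc:
            log.error("structure report failed for %s: %s", record.id, exc)
            row["error"] = str(exc)
        log.info(
            "structure %s: %.2f s", record.id, time.perf_counter() - t0
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Diversity report
# ---------------------------------------------------------------------------

@dataclass
class DiversityResult:
    variants: list
    windows: object
    indels: list
    support_newick: str
    consensus_length: int
    files: dict[str, Path] = field(default_factory=dict)

    def window_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.windows.windows, columns=["start", "end", "n_variable"]
        )

    def indel_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "consensus_start": e.start,
                    "length": e.length,
                    "n_carriers": len(e.samples),
                    "carriers": ",".join(e.samples),
                    "flanking": "-".join(e.flanking) if e.flanking else "",
                }
                for e in self.indels
            ]
        )


def run_diversity_report(
    aln: MultipleAlignment,
    config: RunConfig | None = None,
    reference: PlastomeRecord | None = None,
    reference_id: str | None = None,
) -> DiversityResult:
    """Variant census, window profile, indel events and bootstrap NJ tree
    from one whole-set alignment, all in shared consensus coordinates."""
    config = config or RunConfig()
    if aln.n_rows < 2:
        raise PlastomicsError(
            "diversity report needs an alignment of >= 2 sequences"
        )
    masked = aln.mask_terminal_gaps()
    consensus = build_consensus(masked)
    variants = call_variants(masked, consensus)
    windows = window_counts(
        variants, len(consensus.sequence), window=config.window
    )
    indels = find_indel_events(
        masked,
        min_len=config.min_indel,
        consensus=consensus,
        reference=reference,
        reference_id=reference_id,
    )
    support = bootstrap_support(
        masked, replicates=config.replicates, seed=config.seed
    )
    result = DiversityResult(
        variants=variants,
        windows=windows,
        indels=indels,
        support_newick=support.newick(),
        consensus_length=len(consensus.sequence),
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = provenance(config)
        write_variant_table(
            variants, masked.ids, out / "variants.tsv", header
        )
        write_tsv(result.window_frame(), out / "windows.tsv", header)
        write_tsv(result.indel_frame(), out / "indels.tsv", header)
        (out / "tree.nwk").write_text(result.support_newick)
        result.files = {
            "variants": out / "variants.tsv",
            "windows": out / "windows.tsv",
            "indels": out / "indels.tsv",
            "tree": out / "tree.nwk",
        }
    return result


# ---------------------------------------------------------------------------
# Barcode scan
# ---------------------------------------------------------------------------

def run_barcode_scan(
    target_aln: MultipleAlignment,
    grouping,
    extended_target_aln: MultipleAlignment | None = None,
    tier_alignments: Mapping[str, MultipleAlignment] | None = None,
    cds_seq: str | None = None,
    cds_offset: int = 0,
    reference_id: str | None = None,
    config: RunConfig | None = None,
):
    """Delegates to :func:`plastomics.diagnostics.run_barcode_scan`,
    optionally writing the tabular report."""
    from .diagnostics import run_barcode_scan as _scan

    config = config or RunConfig()
    report = _scan(
        target_aln,
        grouping,
        extended_target_aln=extended_target_aln,
        tier_alignments=tier_alignments,
        cds_seq=cds_seq,
        cds_offset=cds_offset,
        reference_id=reference_id,
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_tsv(report.to_frame(), out / "barcode_scan.tsv", provenance(config))
    return report
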