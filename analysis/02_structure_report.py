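"""Quadripartite structure and gene census of the simulated genomes.

Reads the annotated ancestor and the evolved taxa from
results/synthetic/, detects the inverted repeats in each, partitions the
circles into LSC/IRb/SSC/IRa, censuses the annotation, classifies genes
at the IR borders, and writes the per-genome summary table (the analogue
of a genome-features table in a plastome paper) to
results/02_structure.tsv.

Run after 01_simulate_study.py:  python analysis/02_structure_report.py
"""

from pathlib import Path

from plastomics import PlastomeRecord, read_fasta, read_genbank_features
from plastomics.io import write_tsv
from plastomics.pipeline import RunConfig, provenance, run_structure_report

IN = Path("scratch/synthetic")
OUT = Path("results/02_structure.tsv")


def main() -> None:
    records = [read_genbank_features(IN / "ancestor.gb")]
    records += [
        PlastomeRecord(id=name, sequence=seq)
        for name, seq in read_fasta(IN / "taxa.fasta")
    ]
    config = RunConfig()
    frame = run_structure_report(records, config)
    write_tsv(frame, OUT, provenance(config))
    cols = ["id", "genome_size", "lsc", "ssc", "ir_len"]
    print(frame[cols].to_string(index=False))
    anc = frame.iloc[0]
    print(
        f"\nancestor: {anc['n_genes']:.0f} gene copies over "
        f"{anc['n_unique']:.0f} distinct genes, "
        f"{anc['n_intron_genes']:.0f} with introns; "
        f"complete IR duplicates: {anc['duplicated_complete']}; "
        f"partial: {anc['duplicated_partial']}"
    )
    print(f"table written to {OUT}")


if __name__ == "__main__":
    main()
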