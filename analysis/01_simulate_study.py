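"""Generate the synthetic comparative-plastome study.

Builds the default study system — a ~158 kb quadripartite plastome
(LSC 86 kb / IR 27 kb / SSC 18 kb), a five-taxon target clade inside
three outgroup tiers of five taxa each, 16 planted clade-diagnostic
sites, three planted large deletions (199/120/60 bp), and 100 shallow
extended target individuals — and writes every input the later analysis
stages consume under results/synthetic/.

Run from the repository root:  python analysis/01_simulate_study.py
"""

import argparse
import time
from pathlib import Path

from plastomics import SimulationConfig, simulate_study, write_alignment, write_fasta, write_genbank
from plastomics.io import write_grouping

RESULTS = Path("scratch/synthetic")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=20180301)
    args = parser.parse_args()

    t0 = time.perf_counter()
    study = simulate_study(SimulationConfig(seed=args.seed % 2**31))
    RESULTS.mkdir(parents=True, exist_ok=True)

    write_fasta(study.sequences.items(), RESULTS / "taxa.fasta")
    write_alignment(study.alignment, RESULTS / "alignment.fasta")
    write_alignment(study.target_alignment, RESULTS / "target_alignment.fasta")
    write_genbank(study.ancestor, RESULTS / "ancestor.gb")
    write_grouping(study.grouping, RESULTS / "grouping.tsv")
    write_fasta(
        [("target_1", study.sequences["target_1"])]
        + sorted(study.extended_target.items()),
        RESULTS / "extended_target.fasta",
    )
    (RESULTS / "tree.nwk").write_text(
        study.truth.tree.as_string(schema="newick", unquoted_underscores=True)
    )
    with open(RESULTS / "truth_sites.tsv", "w") as fh:
        fh.write("position\ttarget_allele\tbackground_allele\n")
        for pos, allele, background in study.truth.diagnostic_sites:
            fh.write(f"{pos}\t{allele}\t{background}\n")
    with open(RESULTS / "truth_indels.tsv", "w") as fh:
        fh.write("sample\tstart\tlength\n")
        for sample, start, length in study.truth.indel_events:
            fh.write(f"{sample}\t{start}\t{length}\n")

    part = study.truth.partition
    print(
        f"generated {len(study.sequences)} taxa of "
        f"{part.genome_length:,} bp (LSC {part.lsc_len:,} / IR {part.ir_len:,}"
        f" / SSC {part.ssc_len:,}); planted "
        f"{len(study.truth.diagnostic_sites)} diagnostic sites and "
        f"{len(set((s, l) for _, s, l in study.truth.indel_events))} deletions"
    )
    print(f"inputs written to {RESULTS}/ in {time.perf_counter() - t0:.1f} s")


if __name__ == "__main__":
    main()
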