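"""Deconvolve the simulated FASTQ files into the count matrix.

Reads the four sample FASTQs from scratch/screen/, anchors each read on the
6-nt vector flanks, assigns the 21-nt core to the library at up to two
mismatches, and writes results/screen/counts.tsv plus per-sample extraction
stats.  On error-free reads the recovered counts must equal the simulator's
true counts exactly — the script verifies that and says so.
"""

import sys

import pandas as pd

from shdrop.extract import count_fastq, write_stats
from shdrop.model import SAMPLES, CountMatrix, PipelineConfig, read_counts, read_library, write_counts
from _paths import RESULTS, SCRATCH


def main() -> None:
    out = RESULTS / "screen"
    fastq_dir = SCRATCH / "screen"
    if not (out / "library.tsv").exists():
        sys.exit("run analysis/01_simulate_screen.py first")

    library = read_library(out / "library.tsv")
    config = PipelineConfig()
    data = {}
    for sid in SAMPLES:
        counts, stats = count_fastq(fastq_dir / f"{sid.column}.fastq", library, config)
        data[sid.column] = counts
        write_stats(stats, out / f"extraction_{sid.column}.tsv")
        print(
            f"{sid.column}: {stats.n_reads} reads, {stats.n_assigned} assigned, "
            f"{stats.n_flank_fail} flank-fail, {stats.n_unassigned} unassigned, "
            f"{stats.n_ambiguous} ambiguous"
        )
    idx = pd.Index(library.shrna_ids, name="shrna_id")
    matrix = CountMatrix(
        pd.DataFrame(data), pd.Series(library.gene_ids, index=idx, name="gene_id")
    )
    write_counts(matrix, out / "counts.tsv")

    truth_counts = read_counts(out / "true_counts.tsv")
    exact = matrix.counts.equals(truth_counts.counts)
    print(f"recovered counts identical to simulator truth: {exact}")
    if not exact:
        sys.exit("extraction did not reproduce the true counts")


if __name__ == "__main__":
    main()
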