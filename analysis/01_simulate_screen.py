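"""Simulate the reference dropout screen.

Generates a 200-gene x 2-shRNA library (5% of genes synthetic-lethal with
the p53 deletion, 5% essential in both lines, fitness penalty s = 0.8),
runs the growth/passaging/sequencing model at depth 200,000 reads per
sample, and writes:

  results/screen/library.tsv, truth.tsv, true_counts.tsv   (small tables)
  scratch/screen/<sample>.fastq                            (4 x ~200k reads)
"""

import numpy as np

from shdrop.model import SAMPLES, write_counts, write_library
from shdrop.simulate import SimConfig, emit_fastq, make_library, simulate_counts, write_truth
from _paths import RESULTS, SCRATCH

SEED = 1


def main() -> None:
    out = RESULTS / "screen"
    fastq_dir = SCRATCH / "screen"
    out.mkdir(parents=True, exist_ok=True)
    fastq_dir.mkdir(parents=True, exist_ok=True)

    config = SimConfig(rng_seed=SEED)
    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(SEED).spawn(3)]
    library, truth = make_library(config, rngs[0])
    counts = simulate_counts(library, truth, config, rngs[1])

    write_library(library, out / "library.tsv")
    write_truth(truth, out / "truth.tsv")
    write_counts(counts, out / "true_counts.tsv")
    for sid in SAMPLES:
        emit_fastq(
            counts.sample(sid), library, config, rngs[2],
            fastq_dir / f"{sid.column}.fastq", sample_name=sid.column,
        )

    classes = truth.gene_classes().value_counts()
    print(f"library: {len(library)} shRNAs / {config.n_genes} genes")
    print(f"gene classes: {classes.to_dict()}")
    print(f"depth per sample: {config.depth_per_sample}")
    print(f"wrote tables to {out} and FASTQ to {fastq_dir}")


if __name__ == "__main__":
    main()
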