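"""Per-shRNA differential-depletion statistics for both genotypes.

For every shRNA and cell line, tests T0-vs-T10 depletion with the two-sided
Fisher exact test on the shRNA-vs-rest 2x2 table, estimates the conditional-
MLE odds ratio with its exact 95% CI, computes the frequency fold depletion,
and BH-adjusts p-values within each genotype.  Writes
results/screen/stats_p53plus.tsv and stats_p53minus.tsv.
"""

import sys

from shdrop.model import Genotype, PipelineConfig, read_counts
from shdrop.stats import run_stats, write_stats_table
from _paths import RESULTS


def main() -> None:
    out = RESULTS / "screen"
    if not (out / "counts.tsv").exists():
        sys.exit("run analysis/02_extract_counts.py first")
    matrix = read_counts(out / "counts.tsv")
    config = PipelineConfig()
    stats = run_stats(matrix, config)
    for genotype in Genotype:
        df = stats[genotype]
        write_stats_table(df, out / f"stats_{genotype.value}.tsv")
        n_sig = int((df["p_adj"] < config.alpha_adj).sum())
        n_dep = int(((df["p_adj"] < config.alpha_adj) & (df["fold_depletion"] >= 4)).sum())
        print(
            f"{genotype.value}: {n_sig} shRNAs at adjusted p < {config.alpha_adj}, "
            f"{n_dep} of them depleted >= 4-fold"
        )


if __name__ == "__main__":
    main()
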