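"""Call synthetic-lethality hits, aggregate to genes, score against truth.

Applies the compound rule (adjusted p < 0.01 and >= 4-fold depletion in
p53- cells, with <= 2-fold depletion or non-significance in p53+ cells),
writes hits/genes/volcano tables, and reports gene-level sensitivity and
observed FDR against the planted simulation truth.
"""

import sys

from shdrop.hits import (
    call_hits,
    evaluate_against_truth,
    evaluate_genes_against_truth,
    genes_from_hits,
    volcano_table,
)
from shdrop.model import Genotype, PipelineConfig, read_library
from shdrop.simulate import ShRNAClass, read_truth
from shdrop.stats import read_stats_table
from _paths import RESULTS


def main() -> None:
    out = RESULTS / "screen"
    if not (out / "stats_p53minus.tsv").exists():
        sys.exit("run analysis/03_depletion_stats.py first")
    config = PipelineConfig()
    library = read_library(out / "library.tsv")
    truth = read_truth(out / "truth.tsv")
    stats_minus = read_stats_table(out / "stats_p53minus.tsv")
    stats_plus = read_stats_table(out / "stats_p53plus.tsv")

    records = call_hits(stats_minus, stats_plus, config)
    records.to_csv(out / "hits.tsv", sep="\t", lineterminator="\n", float_format="%.10g")
    genes = genes_from_hits(records, library)
    genes.to_csv(out / "genes.tsv", sep="\t", index=False, lineterminator="\n")
    volcano = volcano_table(stats_minus, stats_plus, config)
    volcano.to_csv(out / "volcano.tsv", sep="\t", lineterminator="\n", float_format="%.10g")

    print(f"hit shRNAs: {int(records['is_hit'].sum())} of {len(records)}")
    print(f"hit genes: {len(genes)}")
    print(f"volcano categories: {records['category'].value_counts().to_dict()}")

    shrna_ev = evaluate_against_truth(records, truth)
    gene_ev = evaluate_genes_against_truth(genes, truth)
    gene_classes = truth.gene_classes()
    essential = set(gene_classes[gene_classes == ShRNAClass.ESSENTIAL_BOTH.value].index)
    print(
        f"shRNA level: sensitivity {shrna_ev.sensitivity:.3f}, "
        f"observed FDR {shrna_ev.observed_fdr:.3f}"
    )
    print(
        f"gene level:  sensitivity {gene_ev.sensitivity:.3f}, "
        f"observed FDR {gene_ev.observed_fdr:.3f}, "
        f"essential-both genes called: {len(essential & set(genes['gene_id']))}"
    )


if __name__ == "__main__":
    main()
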