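#!/usr/bin/env python
"""Partition queries against the reference gene set and measure coverage.

Reads the synthetic study from results/synthetic_study/, splits queries
into clustered/unclustered at E <= 1e-20, assigns best-hit annotations
and reports how much of the reference gene set the assembly covers.
Writes results/coverage.tsv.
"""

from pathlib import Path

from txome454.annotation import annotate, partition_queries, reference_coverage
from txome454.formats import read_gene_list, read_hits

IN = Path("results/synthetic_study")
OUT = Path("results/coverage.tsv")


def main() -> None:
    with open(IN / "hits.tsv") as fh:
        hits = read_hits(fh)
    with open(IN / "reference_genes.txt") as fh:
        reference = read_gene_list(fh)

    queries = {h.query_id for h in hits}
    clustered, unclustered = partition_queries(hits, queries)
    annotations = annotate(hits)
    cov = reference_coverage(annotations, reference)

    OUT.parent.mkdir(exist_ok=True)
    OUT.write_text(
        "n_reference_genes\tn_covered_genes\tpercent_covered\t"
        "n_queries\tn_matched_queries\tpercent_matched_queries\n"
        f"{cov.n_reference_genes}\t{cov.n_covered_genes}\t{cov.percent_covered:.2f}\t"
        f"{cov.n_queries}\t{cov.n_matched_queries}\t{cov.percent_matched_queries:.2f}\n"
    )
    print(
        f"{len(clustered)} of {len(queries)} queries clustered at E<=1e-20 "
        f"({len(unclustered)} unclustered)"
    )
    print(
        f"reference coverage: {cov.n_covered_genes}/{cov.n_reference_genes} genes "
        f"({cov.percent_covered:.2f}%); matched queries "
        f"{cov.n_matched_queries}/{cov.n_queries} ({cov.percent_matched_queries:.2f}%)"
    )
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
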