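"""Pathway over-representation arithmetic from a counts table.

Given k target genes hitting a pathway out of a recognized background of N
genes (and, when known, the pathway size K within an annotation universe of
M genes), the module reports the printed-table quantities: gene percentage
(half-up rounding), fold enrichment (k/N)/(K/M), and the upper-tail
hypergeometric p-value.
"""

import pandas as pd

from mirqpcr import gene_percentage, summarize_counts

# A pathway with 9 of 1613 recognized target genes:
print("gene percentage for 9/1613:", gene_percentage(9, 1613), "%")

counts = pd.DataFrame({
    "pathway_label": ["endothelial barrier", "VEGF receptor signaling"],
    "k": [9, 19],
    "N": [1613, 1613],
    "K": [60, 160],        # pathway sizes in the annotation universe
    "M": [18000, 18000],   # annotation universe
})
table = summarize_counts(counts)
print(table.to_string(index=False))
# genes_pct is 100*k/N rounded half-up to one decimal; fold_enrichment > 1
# means the pathway is hit more often than a random draw of N genes would;
# p_hypergeom is P(X >= k); p_bh is an informational multiple-testing column.
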