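"""Support-evidence percentages at the published tables' precision.

Recomputes ortholog/expression support percentages from count pairs the
way the genome-wide annotation tables report them (half-up, two
decimals; genome fractions at one decimal).
"""

from tfannot.report import support_summary

cases = [
    ("maize TF genes with orthologs", 2538, 2392),
    ("maize TC genes with orthologs", 149, 143),
    ("maize TF genes expressed", 2538, 2341),
]
for label, n_genes, n_support in cases:
    s = support_summary(n_genes, n_with_ortholog=n_support)
    print(f"{label}: {n_support}/{n_genes} = {s.pct_with_ortholog}%")

s = support_summary(1979, n_genome_genes=35471)
print(f"TF+TC genes as a fraction of the genome: 1979/35471 = {s.pct_of_genome}%")
print("\nPercentages are rounded half-up at the precision the tables print.")
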