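"""The worked example: one binding-site polymorphism, one miRNA seed family.

rs28457673 sits in the 3'-UTR binding site of IGF1R shared by five members of
the miR-15/16/195/497 family.  From the packaged fixture (consensus targets,
three risk pathways containing IGF1R, database-confirmed SNP records) the
axis enumerator must return exactly one axis linking the SNP, the family, the
gene, and the three pathways.
"""

from pmsnet import (
    axis_report,
    build_consensus,
    extract_axes,
    filter_mirsnps,
    igf1r_axis_fixture,
    mirna_pathway_enrichment,
    records_from_table,
    split_by_class,
)

fixture = igf1r_axis_fixture()
consensus = build_consensus(fixture.predictions, k=4)          # >= 4 of 10 tools
pairs = mirna_pathway_enrichment(
    consensus, fixture.pathways.subset(["hsa04010", "hsa04151", "hsa01521"])
)
kept = filter_mirsnps(records_from_table(fixture.mirsnps), min_dbs=2)
target_site, _ = split_by_class(kept)

axes = extract_axes(target_site, consensus, fixture.risk_genes, pairs, fixture.pathways)
for axis in axes:
    print(f"{axis.rsid} -> {{{', '.join(axis.mirnas)}}} -> {axis.gene}")
    for pathway in axis.pathways:
        print(f"    -> {pathway}: {fixture.pathways.entries[pathway].name}")
print(f"\nvalidated miRNA-gene interactions at this site: {axes[0].n_validated}")
print("\nreport (one row per axis-pathway):")
print(axis_report(axes).to_string(index=False))
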