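# pmsnet

Pathway-level integration of miRNA-associated polymorphism (miRSNP) evidence,
built around the question: *which single-nucleotide polymorphisms could act as
regulatory "switches" on the miRNA control of disease risk pathways?*  The
package was written for the post-stroke-depression setting — a curated risk-gene
list, KEGG/GO-style gene-set collections, multi-tool miRNA target predictions,
and multi-database miRSNP tables — but every stage is generic over those four
inputs.

It is a library first: `import pmsnet`, or start from the narrative scripts in
`examples/`.  A thin `pmsnet` command-line wrapper exposes each stage and a
`run-all` driver for shell use.

## The method

All significance testing reduces to the cumulative hypergeometric
distribution.  For a universe of *m* genes, a reference set of *j* genes, a
query set of *n* genes and an observed overlap *x*, the enrichment p-value is
the upper tail

P(X ≥ x) = Σ<sub>i=x</sub><sup>min(j,n)</sup> C(j,i) · C(m−j, n−i) / C(m,n),

with Benjamini–Hochberg step-up correction across each test family and
significance at adjusted p < 0.01.  (The lower-tail sum from i = 0 is also
exposed, behind `tail="printed-lower"`, for literal reproduction of
formulations that write the cumulative sum from zero; it is not a sensible
over-representation statistic.)

The pipeline chains five applications of that statistic plus two evidence
filters:

1. **Risk-pathway enrichment** — the risk-gene list against every pathway in a
   GMT collection (query = risk genes, reference = pathway).
2. **Pathway crosstalk** — every unordered pair of significant risk pathways,
   scored on shared genes; kept edges form an undirected crosstalk network
   weighted by −log₁₀(adjusted p).
3. **Consensus miRNA targets** — a (miRNA, gene) prediction survives only if
   ≥ k of N independent tools report it (default 4 of 10).
4. **miRNA → pathway enrichment** — each surviving miRNA's target set against
   each risk pathway, one global BH family over all combinations.
5. **miRSNP filtering** — a record (one per rsID–miRNA–gene binding site)
   survives if experimentally validated OR confirmed by ≥ 2 databases; records
   are classed as target-site (in a 3′-UTR binding site) or miRNA-gene (in the
   miRNA-producing gene).
6. **PMSN assembly** — the retained miRNA–pathway pairs form a bipartite
   network; target-site miRSNPs annotate edges (the SNP's gene must belong to
   the edge's pathway), miRNA-gene miRSNPs annotate miRNA nodes.  Topology
   analysis reports exact degrees, normalized betweenness centrality, and a
   log-log least-squares power-law fit of the degree histogram.
7. **Axis enumeration** — retained target-site SNPs grouped by (rsID, gene)
   yield `miRSNP → {miRNA family} → risk gene → {pathways}` axes; family
   membership is emergent from sharing the binding site.

A seeded synthetic-data generator (`pmsnet.synthetic`) emulates all four
inputs with planted enrichment, crosstalk blocks, hub miRNAs, and axes, so the
whole chain is testable without any database downloads.

## Worked example

`examples/03_igf1r_axis.py` runs the packaged fixture for the binding-site
polymorphism rs28457673, shared by five members of the miR-15/16/195/497 seed
family on the IGF1R 3′-UTR:

```
rs28457673 -> {hsa-mir-15a, hsa-mir-15b, hsa-mir-16, hsa-mir-195, hsa-mir-497} -> IGF1R
    -> hsa01521: EGFR tyrosine kinase inhibitor resistance
    -> hsa04010: MAPK signaling pathway
    -> hsa04151: PI3K-Akt signaling pathway

validated miRNA-gene interactions at this site: 1
```

One axis, and only one: the five family members all pass the 4-of-10 target
consensus for IGF1R, the SNP is confirmed by two databases, IGF1R is a risk
gene, and each listed pathway both contains IGF1R and is significantly
targeted by at least one family member.  A sixth miRNA in the fixture reported
by only three tools is (correctly) dropped before it can join the axis.

`examples/02_synthetic_pipeline.py` runs the full synthetic pipeline (20,000
genes, 300 pathways, 500 miRNAs, seed 1) and prints the recovery of planted
structure:

```
significant pathways: ['PW0001', 'PW0002', 'PW0003', 'PW0004', 'PW0005']
planted pathways:     ['PW0001', 'PW0002', 'PW0003', 'PW0004', 'PW0005']
risk-gene coverage by significant pathways: 59.3%

retained miRNA-pathway pairs: 20 (planted recalled 20/20, decoys 0)
```

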