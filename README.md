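# plastidkit

Analysis toolkit for chloroplast (plastome) genomics in conifer breeding,
built around a loblolly pine (*Pinus taeda*) case study whose three data
tables ship with the package. It covers five connected analyses:

1. **Composition and codon usage** — GC content, AT skew
   ((A−T)/(A+T)) with sliding windows over a circular genome, and relative
   synonymous codon usage (RSCU): for codon *c* in a synonymous family *F*,
   RSCU(*c*) = n(*c*) / mean(n(*F*)), so RSCU = 1 means no bias. Cross-species
   RSCU matrices are clustered by UPGMA on Euclidean distances.
2. **Selection screening** — pairwise Ka/Ks (dN/dS) by the Nei–Gojobori
   (1986) counting method with Jukes–Cantor correction, implemented from
   scratch and verified against exhaustive neighbour/pathway enumeration;
   ratios are classified as positive / neutral / purifying selection.
3. **cpSNP discovery** — variant calling from pooled read counts against a
   reference plastome, gene/intergenic-spacer annotation, and mutation-table
   summaries (counts by kind, gene and pooled-rate bin).
4. **Genotyping** — SNP-profile discrimination of breeding individuals
   (unique profiles vs duplicate groups, with ambiguous 'N' calls as literal
   symbols), greedy panel selection, and PCR primer arithmetic.
5. **Tree congruence** — Robinson–Foulds distances (normalized by 2(n−3))
   between unrooted topologies, neighbour joining on p-distances, and a
   whole-genome vs single-gene congruence experiment on simulated alignments.

A seedable `synthetic_data` module generates every input (plastomes,
pooled populations, ω-controlled CDS divergence, trees + alignments), so
the full pipeline is testable offline.

## Worked example

```python
>>> from plastidkit import datasets, genotyping, snp_discovery
>>> summary = snp_discovery.summarize_variants(datasets.load_mutation_table())
>>> summary.n_snps, summary.n_indels
(71, 4)
>>> summary.per_gene["ycf1"], summary.max_rate, summary.max_rate_annotation
(17, 0.48, 'ycf2')
>>> report = genotyping.discriminate(datasets.load_genotype_table())
>>> report.n_distinguished, [len(g) for g in report.duplicate_groups]
(23, [3, 3, 2, 2])
```

Of 75 packaged mutation records, 71 are SNPs and 4 are indels; the gene
*ycf1* carries 17 of the 71 SNPs (23.94%) and the single highest pooled
mutation rate (48%) lies in *ycf2*. The 15-locus SNP panel distinguishes
23 of the 33 breeding individuals; the remaining 10 fall into four
duplicate-profile groups (two trios, two pairs) that the panel cannot
separate — candidates for shared paternal lineage.

The same operations are available from a shell:

```
plastidkit reproduce                 # run all packaged-table checks
plastidkit discriminate --genotypes tests.tsv --out report.json
plastidkit kaks --alignment aln.fasta --gene clpP --out kaks.tsv
plastidkit rf --tree1 a.nwk --tree2 b.nwk
plastidkit simulate trees --seed 7 --out-dir sim/
```

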