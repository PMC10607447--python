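# phagecode

Detection of alternative genetic codes in bacteriophage genomes, and
the comparative genomics that follows from getting the code right.

Some tailed phages of the human gut read the amber stop codon TAG as
glutamine (NCBI translation table 15).  Annotated under the standard
bacterial code (table 11), their genomes look broken: terminase,
tail tape measure, portal and capsid genes fragment into short
same-frame ORFs "interrupted" by in-frame TAGs, and the genome often
carries suppressor tRNA genes whose anticodon CTA base-pairs with TAG.
`phagecode` automates the rescue argument used to characterize such
genomes:

1. call ORFs in all six frames under table 11 and under each candidate
   alternative table (15 for TAG→Gln, 4 for TGA→Trp);
2. score each candidate stop codon by **interrupted-gene rescue** —
   the number of gene-scale re-annotated ORFs spanning internal
   reassigned stops (guarded by a self-trained codon-usage model
   against shadow ORFs and start over-extension) — and by the
   **coding-fraction gain** of re-annotation;
3. recommend a reassignment when gain ≥ 0.02 and ≥ 5 rescued genes
   agree, recording suppressor-tRNA support (anticodon CTA/TCA/TTA
   detected by a cloverleaf heuristic, or ingested from tRNAscan-SE
   GFF3) as corroborating evidence;
4. emit the final annotation as GFF3 and GenBank with the proper
   `/transl_table` qualifier and per-CDS positions of reassigned stops;
5. compare genomes: whole-genome nucleotide identity (NI, anchored
   global alignment), normalized translated similarity
   (SG = S(a,b)/min(S(a,a),S(b,b)) from six-frame BLOSUM62 HSPs,
   0 ≤ SG ≤ 1), VIRIDIC-style intergenomic similarity, reciprocal-best-hit
   orthologs, synteny (strand-aware Kendall τ), and threshold clustering
   into putative species (≥ 95%) and genera (≥ 70%).

A fully truth-tracked synthetic-genome generator (gene-dense phage-like
genomes with designed ambers, suppressor tRNAs and dialed divergence)
makes every stage testable without downloads.

## Worked example

Simulate a 60-gene phage-like genome in which 30% of genes carry
internal amber codons, plus two relatives at 8% substitution
divergence, then annotate and compare:

```bash
phagecode simulate --out-dir sim --seed 11 --config conditions.yaml \
    --n-relatives 2 --sub-rate 0.08
# INFO wrote 3 genome(s), 60 genes (18 recoded), 3 tRNAs

phagecode annotate sim/genomes.fasta --out-dir annot
# INFO synth_seed11: verdict=reassigned table=15 orfs=73 recoded_orfs=29 (39.7%) suppressor_trnas=3

phagecode compare sim/genomes.fasta --out-dir cmp --metrics NI
# INFO NI: 1 genus / 3 species clusters
```

The verdict line says the pipeline recommends translation table 15
(TAG→Gln): 29 of 73 annotated ORFs contain at least one internal TAG
read as glutamine, and three suppressor tRNA genes (anticodon CTA)
corroborate.  The per-codon evidence table
(`annot/recoding_report.tsv`) shows why TAG wins and TGA does not:

```
genome_id     stop_codon  n_interruption_candidates  coding_fraction_gain
synth_seed11  TAG         16                         0.0486
synth_seed11  TGA         3                          0.0185
```

`cmp/NI_matrix.tsv` holds the pairwise identities (here 90.5% and
82.3%) and `cmp/NI_clusters.json` the taxonomic partition — the three
genomes fall below the 95% species threshold but above the 70% genus
threshold, i.e. three putative species of one genus:

```
        synth_seed11  synth_seed11_rel1  synth_seed11_rel2
synth_seed11        100.0       90.5        90.5
synth_seed11_rel1    90.5      100.0        82.3
synth_seed11_rel2    90.5       82.3       100.0
```

Genomes with externally produced tRNA annotations can pass them in
with `--trna-gff trnascan.gff3`; library users can drive every step
from Python (`phagecode.analyze_genome`, `phagecode.pairwise_ni`, …).

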