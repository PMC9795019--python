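# peonymir

Integrated miRNAome–transcriptome–degradome analysis for flowering-time
studies in tree peony (*Paeonia suffruticosa*), reimplemented as a tested,
reusable pipeline. It is aimed at plant small-RNA researchers who want the
full chain — miRNA discovery, differential expression, degradome
(PARE) cleavage validation, and regulatory-module inference — as inspectable
library code rather than a stack of opaque vendor tools, and at method
developers who need a synthetic testbed with planted ground truth.

## What it computes

**Five-group miRNA classification.** Collapsed small-RNA tags (18–26 nt)
are mapped to a mature/precursor miRNA reference and to the genome, and
assigned by a decision tree:

| group | mature ref hit | ref precursor on genome | tag on genome | locus folds back |
|-------|----------------|-------------------------|---------------|------------------|
| gp1   | yes            | yes                     | (implied)     | —                |
| gp2a  | yes            | no                      | yes           | yes              |
| gp2b  | yes            | no                      | yes           | no               |
| gp3   | yes            | —                       | no            | —                |
| gp4   | no             | —                       | yes           | yes              |

gp1–gp3 are *known* miRNAs, gp4 are *predicted* (novel); anything else is
UNCLASSIFIED. "Folds back" is a stem-loop test on the locus extended by
120 nt per side: the mature arm must pair (Watson–Crick or G:U) at ≥ 16
positions with a flank duplex, with no bulge > 3 nt and a terminal loop
≥ 3 nt.

**Differential expression.** miRNAs: one-way ANOVA on log2(CPM+1),
significant at *P* ≤ 0.05 (tiers 0.01/0.05/0.1). Genes: FPKM =
fragments / (mapped reads in millions × exon length in kb), with DEGs
called by the joint rule *fold change > 2 or < 0.5 AND P < 0.05* (Welch
t on log2(CPM+1)).

**Degradome validation.** Target sites come from an exhaustive
complementarity scan (mismatch 1.0, G:U 0.5, costs doubled over miRNA
positions 2–13, cutoff 2.5). A site is validated when the degradome shows
a 5′-end peak within ±1 nt of the base paired to miRNA position 10, and
is categorised 0–4 by how dominant the peak is in the transcript's t-plot.

**Module integration.** A miRNA–mRNA pair becomes a regulatory module iff
it is degradome-validated, both members are differentially expressed in a
shared contrast, and their directions are opposite (the silencing
signature). Modules are classed developmental / varietal / dual by the
contrast family, and TF-encoding targets (MYB-related, bHLH, Trihelix,
NAC, GRAS, HD-ZIP, …) extend them to miRNA→mRNA→TF edges.

**2^−ΔΔCT quantification** for qPCR validation tables (EF1-α / U6
references), plus profile correlation against pipeline expression.

## Worked example

The pipeline ships a synthetic-data generator whose defaults emulate the
study design (3 genotypes × 4 stages × 3 replicates, 36 sRNA + 36 mRNA
libraries, 3 pooled degradome libraries) with 50 planted miRNAs (10 per
group) and 12 planted antagonistic modules:

```sh
peonymir run --seed 1 --outdir demo/
```

`demo/group_summary.tsv` then contains (seed 1):

```
group            pre_mirna  unique_mirna
gp1                     10            10
gp2a                    10            10
gp2b                    10            10
gp3                     10            10
gp4                     10            10
known_total             40            40
predicted_total         10            10
total                   50            50
```

i.e. every planted miRNA is recovered in its intended group; the
remaining ~160 decoy tags come out UNCLASSIFIED. `demo/modules.tsv` lists
12 modules — exactly the planted ones — e.g.

```
mirna_id      transcript_id  tf_family    evidence_class
pmir-gp1-05   T0291          GRAS         developmental
pmir-gp2b-04  T0028          NAC          developmental
pmir-gp1-04   T0143                       dual
PC-0004       T0277                       varietal
```

Each row is a degradome-validated pair (category 0: the cleavage peak is
the transcript's unique maximum) whose miRNA and target moved in opposite
directions in the named contrast family. `demo/module_edges.tsv` is a
network-tool-ready edge list; `demo/manifest.json` records sha256 digests
proving re-runs are byte-identical.

All stages are also available as subcommands (`simulate`, `catalog`,
`discover`, `de`, `degradome`, `integrate`, `qpcr`) and as plain library
functions (`peonymir.classify`, `peonymir.deg_call`, …).

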