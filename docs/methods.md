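# Methods

This note documents the models, rules and numerical choices behind
`peonymir`, and what the synthetic testbed does and does not demonstrate.

## Small-RNA catalog

Input is a collapsed tag table (sequence + one raw count column per
library, libraries named `<genotype>_<stage>_<replicate>`, e.g.
`FD_BS_1`). Adapter trimming and contaminant screening are assumed done
upstream. Filtering keeps tags of 18–26 nt over {A,C,G,T,U} (U is
normalised to T internally); duplicates are merged by summing counts.
Mapping is exhaustive ungapped Hamming scanning: every occurrence within
the mismatch budget is reported, on both genome strands but forward-only
against the mature reference. Defaults: 0 mismatches for genome and
precursor-to-genome mapping, ≤ 2 for mature-reference assignment. The
conservative asymmetry reflects that reference assignment is
cross-species (known miRNAs are conserved but not identical) while genome
placement should be exact. Indel-tolerant alignment is deliberately out
of scope for 18–26 nt tags. Multi-mapping tags keep all loci and
classification uses "some locus suffices" semantics.

## Fold-back hairpin criterion

Thermodynamic folding is replaced by a structural duplex test. The locus
is extended by `flank` nt (default 120) per side; the mature arm is
aligned against each flank with a glocal dynamic program (global in the
mature, local in the flank) where a "match" is Watson–Crick or G:U
complementarity in antiparallel orientation (scores: pair +3, mismatch
−2, gap −3). The better flank decides. Acceptance requires:

- ≥ 16 mature positions paired (`min_paired`),
- largest bulge (gap run inside the duplex) ≤ 3 nt (`max_bulge`),
- terminal loop ≥ 3 nt (`min_loop`),
- the mature entirely on one arm (structural, by construction).

These thresholds follow community miRNA-annotation practice for plant
hairpins; all are configurable. The decision is strand-symmetric:
examining the reverse complement of a locus yields the same accept/reject
outcome (the mature arm label 5p/3p flips with orientation, as it
should). Dot-bracket strings are emitted for accepted hairpins and the
reported pairing statistics are recomputable from them.

## Classification tree

Groups are assigned by the first matching rule in the order gp1, gp2a,
gp2b, gp3, gp4 (see README for the truth table); a tag matching no rule
is UNCLASSIFIED, a normal outcome rather than an error.
`precursor_maps_genome` is existential over all mature-reference hits of
the tag. The branch order only matters for determinism — the predicates
are mutually exclusive by the mature-hit condition.

The group summary reports both precursor-level counts (distinct reference
precursor ids for known groups; distinct accepted hairpin loci for gp4)
and mature-level counts (unique mature sequences). The distinction
between the two count layers in the field's summary tables is not fully
standardised; both are reported so either convention can be read off.

## Expression statistics

- **Normalisation** is counts-per-million. CPM is the minimal defensible
  choice for tag counts and is rank-preserving within a library; a
  zero-total library is an error naming the library.
- **FPKM** implements the standard fragments / (mapped reads in millions
  × exon length in kb) formula for the mRNA side.
- **DEM test**: one-way ANOVA F-test per feature on log2(CPM+1),
  vectorised over features; significant at *P* ≤ 0.05 (inclusive
  boundary), with 0.01/0.05/0.1 tier flags that are nested by
  construction. Features that are constant everywhere get F = 0, *P* = 1
  rather than NaN. Pairwise comparisons reuse the same machinery on two
  groups (where F = t²); the direction is the sign of the B-vs-A mean
  difference.
- **DEG test**: fold change (meanB + 1)/(meanA + 1) on the CPM scale
  (pseudocount 1 for stability at zero), Welch t on log2(CPM+1),
  significant iff (FC > 2 or FC < 0.5) AND *P* < 0.05 (strict boundary).
  The boundary semantics differ deliberately between DEM (≤) and DEG (<),
  each taken literally from its stated criterion.
- No multiple-testing correction by default, matching the raw-P criteria;
  Benjamini–Hochberg is available behind a flag.

Contrast labels encode the design: `FD:DEvsBS` (stage pair within
genotype, "developmental") and `BS:LHvsFD` (genotype pair within stage,
"varietal"); the token before `vs` is the fold-change numerator.

## Target prediction and degradome validation

The scan evaluates every transcript window of miRNA length against the
miRNA in antiparallel orientation. Per-position costs: Watson–Crick 0,
G:U 0.5, mismatch 1.0, doubled over miRNA positions 2–13; sites with
total penalty ≤ 2.5 are kept. The cost table mirrors the position-weighted
penalty family used by plant target predictors; the exact numbers are
declared here and fully configurable rather than inherited from any
closed-source tool.

The expected cleavage coordinate is the transcript base paired with
miRNA position 10 (AGO slicing falls between the bases opposite positions
10 and 11). Validation looks for the maximum degradome 5′-count within
±1 nt of that coordinate; zero counts mean no validation. The t-plot
category is:

| category | rule |
|----------|------|
| 0 | peak = transcript maximum, unique |
| 1 | peak = transcript maximum, tied |
| 2 | mean < peak < maximum |
| 3 | 1 < peak ≤ mean |
| 4 | peak = 1 raw count |

with the single-read rule taking precedence; the mean is over all
transcript positions, zeros included. The category is monotone
non-increasing in the peak count. Degradome libraries are per genotype
(stages pooled, three libraries); a pair counts as validated if supported
in ANY genotype, with per-genotype rows retained so differential
degradation between genotypes can be read off.

## Module integration

Developmental and varietal DEG union sets are built by unioning the
significant calls of each contrast family. A module requires (i) a
validated cleavage for the pair, (ii) the miRNA significant as a DEM and
the target inside a DEG union, and (iii) opposite significant directions
in at least one shared contrast. All supporting contrasts are recorded;
the evidence class is developmental, varietal, or dual (= at least one of
each). Target-count conventions: module counts are per unique
(miRNA, target) pair with per-pair detail retained. TF-encoding targets
add a family node to the edge list.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions: 3 genotypes (FD, MU,
LH) × 4 stages (BS, IF, FB, DE) × 3 replicates for both sRNA and mRNA
counts; 3 degradome libraries pooled per genotype; a 48 kb genome
(6 × 8 kb contigs) with 10 planted miRNAs per group; 180 decoy tags (10%
outside the 18–26 nt range) so the classified catalog exceeds 200 tags;
300 transcripts of 0.8–2.4 kb; negative-binomial counts with mean 100 and
dispersion 0.05 (var = μ + 0.05 μ²); planted effects of |log2FC| = 2;
degradome peaks holding ≥ 90% of a cleaved transcript's 60 tags over a
Poisson(2) single-read background; 12 planted modules split 5
developmental / 5 varietal / 2 dual, two thirds TF-annotated across the
six families the integrated analysis highlights. Sequencing depth per
library is not a claim of the model — it is a config knob.

Construction rules: gp1/gp2a/gp4 loci are written as perfect inverted
repeats (mature + 12 nt loop + reverse complement) and re-checked against
the fold-back oracle at generation time; gp2b loci get their ±120 nt
flanks rejection-shuffled (≤ 1000 attempts) until the oracle rejects;
gp3 matures are verified absent from both genome strands. Planted
"developmental" effects act at stage DE in all three genotypes, so
varietal contrasts stay null; "varietal" effects act in genotype LH at
all four stages; "dual" effects act in the single cell (LH, DE). This
orthogonal placement makes the three evidence classes exactly
recoverable, which is the property the recovery tests exercise.

All randomness flows from one seed through named sub-streams (genome,
reference, transcripts, modules, sRNA counts, mRNA counts, degradome), so
identical configs produce byte-identical files and regenerating one
component does not perturb the others.

What passing tests do **not** show: real libraries carry isomiRs,
rRNA/tRNA fragments, multi-mapping repeat-derived tags, length-dependent
biases and far deeper, more dispersed counts; real hairpins are judged
thermodynamically; real degradome background is structured by exonuclease
processivity, not uniform. Recovery rates on this testbed are upper
bounds demonstrating correctness of the logic, not field performance
estimates.

## qPCR quantification

Technical replicates are averaged on the Ct scale, then
ΔCt = Ct(target) − Ct(reference), ΔΔCt against the calibrator sample, and
RQ = 2^−ΔΔCt (calibrator RQ ≡ 1; RQ is invariant to shifting a sample's
target and reference Ct together). The calibrator defaults to the BS
stage of the same genotype and is configurable, since absolute RQ values
depend entirely on that choice. Amplification-efficiency correction is
out of scope. Profile agreement with pipeline expression is Pearson
correlation on log2 values; constant profiles are reported as undefined
(NaN) rather than 0.

## Problem sizes and runtime

The default study (212-tag catalog, 300 transcripts, 30 pairwise
contrasts, 3 degradome libraries) runs end-to-end in under ten seconds on
one CPU; the type-I-error check uses a 2,000-feature null matrix. These
sizes were chosen so the whole suite, including two full end-to-end runs
for the determinism check, stays comfortably interactive while keeping
every statistical check adequately powered (binomial/KS intervals are
computed at the actual n used).

## Known limitations

- The fold-back aligner reports a single best duplex per flank; branched
  or multi-loop precursors are not modelled.
- DEG calling is a specified Welch-t rule, not an NB exact test; with
  n = 3 replicates its power differs from count-model tests, which is why
  planted effects at |log2FC| = 2 (not smaller) define the recovery
  conditions.
- Pairwise DEM comparisons reuse the ANOVA machinery on two groups; the
  upstream "across four stages" screen and the pairwise contrasts are
  therefore consistent but not independent analyses.
- Degradome categories carry no p-values; category 0/1 dominance is a
  heuristic, as in standard t-plot practice.
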