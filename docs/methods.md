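# Methods

## Problem and definitions

A **nullomer** is a k-mer (4 ≤ k ≤ 32) that never occurs in a reference
genome. A **neomer** is a nullomer that a somatic mutation creates in a
tumour genome: a sequence that cannot be read from healthy DNA but appears in
the tumour's mutated sequence. Because a single neomer read is, in principle,
unambiguous evidence of the mutant allele, recurrence-filtered neomer panels
can act as sensitive and specific cancer biomarkers in cell-free DNA/RNA from
liquid biopsies. `neomerkit` implements the full computational chain: k-mer
presence indexing, neomer extraction from mutation tables, germline-variant
subtraction with a probability model, panel assembly, read-set counting, and
a stacked-ensemble classifier.

## k-mer membership and strand convention

k-mers are packed into 2-bit codes (A=0, C=1, G=2, T=3); an index is the
sorted array of distinct codes occurring in the genome, queried by binary
search. Windows containing N (or any non-ACGT letter, all of which normalize
to N at FASTA load) are never indexed and never emitted.

Membership defaults to **canonical** (double-stranded): a k-mer counts as
present if it or its reverse complement occurs, implemented by mapping every
code to min(code, revcomp-code). DNA is double-stranded, so a sequence
present on either strand is not absent from the genome; forward-only
semantics remain available everywhere (`--no-canonical`) for stranded RNA
work. In canonical mode all reported k-mer strings are canonical
representatives (the lexicographically smaller of the pair).

Full nullomer enumeration walks the 4^k space in chunks and is guarded at
k ≤ 14 by default (the space grows fourfold per base; the guard is a memory
bound, overridable with `force`).

## Neomer extraction

For each mutation, a window of the edited region plus **k + 30** bases of
flank on each side is cut from the reference (clipped at contig ends), the
edit is applied (substitution in place; deletion removes the span; insertion
goes between Start and End = Start + 1, with `-` marking the empty allele,
the common MAF convention), and the candidate set is

    kmers(mutated window) \ kmers(reference window)

Candidates absent from the genome index are neomers. Since the flank length
k + 30 exceeds k − 1, every k-mer overlapping the edit lies fully inside both
windows, so the windowed difference equals the whole-genome difference — the
property the oracle tests verify. Mutations are treated as **independent
events**: nearby mutations are never phased onto one haplotype. Reference
alleles are verified against the genome and a mismatch is a hard error
(catching assembly mix-ups) unless `skip_mismatch` drops the row with a log
entry. MAF coordinates are 1-based inclusive at the boundary; all internal
arithmetic is 0-based half-open. The windowing genome and the index genome
may differ (`--index-fasta`), reflecting pipelines that window in the
mutation caller's assembly while testing absence against another assembly.

## Germline variants and the confidence model

Population variants (VCF with `AF` plus per-ancestry `AF_eas`, `AF_afr`,
`AF_fin`, `AF_ami`, `AF_amr`, `AF_nfe`, `AF_sas`, `AF_asj`) are **common**
when any of those frequencies is strictly above the retention threshold
(default 0.05). Multi-allelic rows split per ALT; indel anchor bases are
stripped so the somatic windowing machinery applies unchanged; missing
per-population AFs count as 0 (conservative: leaves that population's
confidence at 1) with a warning counter. cyvcf2 stores INFO floats in single
precision, so AF values are rounded to 6 significant digits on read — this
keeps stated thresholds ("strictly greater than 5%") exact for values
written at ordinary precision.

For a k-mer creatable by variants v1…vn with allele frequencies AF_i, the
probability that it does **not** arise from germline variation is

    p_not_germline = Π (1 − AF_i)

computed per population and overall, assuming independence of germline
variants (linkage disequilibrium is deliberately out of scope). The product
is accumulated as a sum of log1p(−AF) to survive thousands of contributors;
an AF of 1 forces p = 0 and the record is reported, not dropped. A k-mer is
"associated with a common variant" iff any of its composite probabilities is
below 1, i.e. any contributor has nonzero frequency.

## Panels

A panel groups neomer records by k-mer and keeps those seen in at least
`min_recurrence` **distinct patients** (default 2; within-patient
multiplicity is kept in the records but collapsed for recurrence). Optional
selectors restrict to a cancer type / organ / stage before grouping. The
confidence filter keeps entries with p_not_germline ≥ `min_confidence`
(default 0.95) in a chosen population; k-mers absent from the germline
records have confidence 1 and always survive. Panels are compared with the
Jaccard index over their k-mer sets (two empty panels score 0 by convention,
keeping the matrix total), and summarized as per-patient distinct-neomer
counts and a shared-by-exactly-N-patients histogram. Panel TSVs carry their
provenance (k, filters, tool version) in a '#' header and round-trip
losslessly.

## Screening

Panel k-mers are counted in FASTQ read sets by the same 2-bit machinery:
reads are concatenated with single-N separators (so windows never span read
boundaries), window codes are canonicalized when requested, and matched
against the sorted panel codes. **Occurrences** are counted, not per-read
presence. Strand mode defaults to canonical for cfDNA and forward for
stranded (sense-strand) cfRNA, both overridable.

The classifier pipeline, per cross-validation fold and strictly inside the
training split:

1. **Feature filter** on raw counts: a feature is removed when more than 40%
   of training-fold *control* samples have a count strictly above the
   threshold — 20 for RNA, 500 for DNA (consistently control-expressed
   k-mers are background, not tumour signal).
2. **CPM**: each sample's retained counts are scaled to sum to 10^6
   (all-zero samples pass through as zeros with a warning). The denominator
   is the per-sample sum over panel features — the matrix the normalizer
   actually receives — not the raw read total.
3. **SMOTE**: the minority class is balanced by interpolating between
   minority nearest neighbors (neighbor count min(5, minority−1)), applied
   jointly to the concatenated RNA+DNA feature block so each synthetic
   patient stays consistent across modalities. Interpolation commutes with
   the affine per-modality scalers, so ordering relative to scaling only
   affects neighbor selection, not the attainable point set.
4. **Stacked ensemble**: RNA features are max-abs scaled and fed to a
   class-balanced logistic regression and a histogram gradient-boosted tree
   classifier; DNA features are z-scored and fed to a random forest and a
   second gradient-boosted classifier. The four base learners produce
   out-of-fold probabilities via an internal stratified 5-fold split (the
   standard stacking convention, avoiding meta-learner leakage), a logistic
   regression integrates the four probability columns, and the base learners
   are refitted on the full training fold. Base-learner hyperparameters are
   library defaults and are recorded in the metrics JSON.

Evaluation is stratified 5-fold cross-validation reporting per-fold and
mean ± sd ROC-AUC and PR-AUC. Every random element (fold split, SMOTE,
tree learners) derives from one integer seed.

## Synthetic data: what it emulates and what it does not

The generator produces the pipeline's inputs at desk scale: i.i.d. uniform
ACGT contigs; isolated somatic mutations (≥ k+31 from contig ends and ≥
2(k+31)+10 apart, making per-mutation independence exact so the whole-genome
brute-force oracle is unambiguous), each carried by 2 tumour patients so a
recurrence-2 panel is non-empty by construction; gnomAD-like variants with
per-ancestry AFs log-normally jittered (σ = 0.3) around an overall AF drawn
uniformly from [0.01, 0.5]; and read sets of 5000 × 150 bp per sample
(30 cases, 10 controls per modality, matching the scale of a small
liquid-biopsy cohort) drawn uniformly from the genome with substitution
errors at 0.001/base (modern short-read error rates), DNA reads on a random
strand and RNA reads sense-strand. Case samples receive Poisson(50) panel
k-mer occurrences spiked into random read positions; controls receive none
by default. Sequencing errors at mutation loci give controls a realistic
nonzero noise floor.

Not emulated: mutational signatures, fragment-length biology, GC/coverage
bias, indel sequencing errors, UMI structure, or contaminant reads. A green
screening test therefore establishes that the counting, preprocessing,
fold hygiene and ensemble wiring recover a planted signal and stay at chance
under label permutation — not that the classifier's headline performance
transfers to real cohorts.

## Numerical and design choices

- Index representation: one sorted uint64 code array for every k (contract
  over representation; a dense bit array buys nothing at these scales).
- Float comparisons at stated thresholds are strict, exactly as specified
  (AF > 0.05 retains; >40% of controls removes; confidence ≥ threshold
  keeps).
- Probability serialization uses `repr` round-tripping, so TSV round-trips
  are bit-exact.
- Degenerate inputs: zero-total samples CPM to zero rows; a single-sample
  minority class makes SMOTE fail with a pointer to the duplication
  fallback; an empty panel is a parameter error for counting.
- Provenance: tabular outputs begin with '#key=value' headers; FASTA/FASTQ
  cannot carry comment lines, so their provenance lives in the per-run JSON
  manifest the CLI writes next to each output.

## Known limitations

- The germline model ignores linkage disequilibrium and diploid genotypes;
  composite probabilities are upper bounds on "not germline" when variants
  co-occur on haplotypes.
- Canonical panels reject k-mer pairs that collide under reverse complement
  (counting them separately would be ambiguous).
- Whole-genome brute-force oracles and full nullomer enumeration are for
  small inputs; the guards are deliberate.
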