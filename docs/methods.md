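# Methods

## Problem and model

`hrdsense` estimates, per tumor sample, the probability that homologous
recombination (HR) repair is deficient, from three kinds of somatic calls:
single-base substitutions (SBS), small insertions/deletions (ID), and
allele-specific copy-number segments (CN). The model is deliberately
minimal: six engineered features and a linear-kernel SVM, so that the same
feature definitions work at whole-genome and whole-exome resolution and the
fitted weights stay interpretable.

### Channel classification

* **SBS-96.** Each substitution is strand-collapsed to its
  pyrimidine-centric trinucleotide name (`A[C>T]G`, …). A purine reference
  base is reverse-complemented together with both flanking bases, so
  classification is invariant under reverse complement of the record
  (tested exhaustively over all 192 raw contexts).
* **ID-83.** Indels are named by event type, length (1–5+), flanking
  repeat-unit count and, for deletions of ≥2 bp without an adjacent whole
  copy, microhomology length. Repeat counts are whole adjacent copies of
  the event sequence in the 3′ and 5′ flanks, summed and capped at the 5+
  bucket; microhomology is the longer of the deleted sequence's prefix
  match into the 3′ flank and suffix match into the 5′ flank, capped at
  5 bp and structurally below the deletion length; repeat context takes
  precedence over microhomology. Records carry their own flanks (≥25 bp
  recommended), so no reference genome is needed; a flank that ends inside
  a potential repeat copy raises an error asking for longer context rather
  than guessing a bucket. Complex (mixed insertion/deletion) records are
  excluded with a warning; the schema does not cover them.
* **CN-48.** Segments are named TCN class (0, 1, 2, 3–4, 5–8, 9+) ×
  zygosity (HomDel ⇔ TCN 0; LOH ⇔ minor 0 with major ≥1; HET otherwise) ×
  size bin ((0,100 kb], (100 kb,1 Mb], (1,10 Mb], (10,40 Mb], >40 Mb; HomDel
  uses the reduced bins 0–100 kb / 100 kb–1 Mb / >1 Mb). Bins are left-open,
  right-closed: a segment of exactly 40 Mb falls in 10–40 Mb. Segments are
  stored half-open (size = end − start); the ASCAT-style TSV reader converts
  from 1-based inclusive coordinates on input.

Mitochondrial records are dropped with a warning; sex chromosomes are
processed like autosomes.

### The six features

In fixed order (the trained-model contract depends on it):
`n_ct_g`, `n_cg_t`, `del5_mh`, `loh_1_40`, `het3_9_10_40`, `het2_4_gt40`.
Substitution features are within-class proportions; CN features are
proportions of all segments; `del5_mh` is the raw count of `5:Del:M:1–5`
by default (`del5mh_as_count=False` switches to a proportion of all
indels). The count convention is used for both assays: the z-scoring
absorbs scale, and a count preserves the signal at exome resolution where
the per-sample microhomology-deletion proportion becomes a ratio of very
small integers. The channel→feature membership map ships as a versioned
data file (`hrdsense/data/feature_channel_map.tsv`); no channel belongs to
more than one feature. CN proportions are normalized by segment count (not
genome length): the large->40 Mb channels then measure how much of the
genome sits in quiet segments relative to how fragmented it is, which is
the intended contrast with LOH-heavy HRD genomes.

A sample with zero events in a class gets zeros for that class's features
and a `low_confidence` flag rather than a rejection.

### Ground-truth labeling

For training, a sample is labeled HRD when its genomic-scar HRD score
(LOH + telomeric allelic imbalance + large-scale transitions, consumed as
an input annotation, never computed here) reaches 42 for breast or 63 for
ovarian cancer, or when it carries any BRCA1/2 defect (germline, somatic
or epigenetic); otherwise HRP. A score without a cancer type is an error;
a BRCA defect alone suffices.

### Enrichment screen

The feature-engineering diagnostic tests each of the 227 channels for
HRD/HRP differential abundance. Fisher's exact test needs counts, so the
2×2 table pools event counts within each group (channel vs all other
events of its class); the volcano effect axis is the log2 ratio of
group-mean per-sample proportions, with pseudo-proportion ε = half the
smallest nonzero mean in the class guarding zeros (configurable). P-values
are BH-adjusted jointly across all three classes by default
(`joint_fdr=False` gives per-class families; both are supported because the
FDR family convention is a genuine free choice here). Selection requires
|log2FC| strictly above 0.75 (WGS) or 0.25 (WES) *and* −log10(q) strictly
above 3; consensus across assays is plain set intersection per direction.

### Classifier

Per-feature z-scoring (scikit-learn `StandardScaler`) followed by a
linear-kernel SVM with L2 regularization. C is selected from
{0.01, 0.1, 1, 10, 100} by stratified 10-fold cross-validation maximizing
mean ROC AUC (ties go to the smaller C; folds are reduced with a warning
when a class has fewer samples than folds). Probabilities come from a
Platt sigmoid fitted by penalized maximum likelihood (Platt's smoothed
targets, L-BFGS) to cross-validated decision values, which keeps calibrated
probabilities honest on separable training data. Reported feature weights
are the mean of the per-fold weights at the chosen C; the final
weight/bias vector is refit on all training data. No class reweighting is
applied: moderate class imbalance (23–35% HRD in realistic cohorts) does
not materially move the decision boundary of an L2 SVM, and leaving the
loss unweighted keeps probabilities interpretable. The default operating
point is p ≥ 0.50; threshold re-optimization on training data (Youden-J on
the training ROC) is available but the shipped default remains 0.50.

Everything needed for prediction (scaler means/sds, weights, bias,
sigmoid slope/intercept, threshold, feature order, assay, seed) serializes
to versioned JSON; prediction is implemented directly from those
parameters, so save → load → save round-trips byte-for-byte and a stored
model reproduces its recorded training AUC exactly.

## Exome downsampling

Targets are BED-style 0-based half-open intervals, merged per chromosome;
`chr` prefixes are normalized away. A mutation is kept when any affected
base (for deletions, any deleted base) lies on target. A CN segment is
kept — with its original coordinates and genomic size — when it overlaps at
least one target base, because CN-48 size bins describe genomic, not
captured, extent; `clip=True` implements the alternative (truncate to the
on-target bounding range) for comparison. Restriction is idempotent and
commutes with feature derivation (tested byte-for-byte through the file
round-trip).

## Synthetic cohorts

The generator's job is to reproduce the *direction and rough magnitude* of
the HRD/HRP channel enrichments so that every downstream stage — catalogs,
features, screen, classifier, downsampling — can be validated end-to-end.

Per channel class there is a baseline probability vector shaped like a
quiet breast genome: CpG-transition mass elevated 4× among substitutions,
T-homopolymer indel channels elevated 3×, CN mass concentrated in diploid
heterozygous segments with a realistic size profile. For an HRD sample the
HRD-enriched channel groups (N[C>G]T, `5:Del:M:1–5`, LOH 1–40 Mb, HET TCN
3–9 at 10–40 Mb) are multiplied by their effect sizes and renormalized;
for an HRP sample the HRP groups (N[C>T]G, HET TCN 2–4 >40 Mb) are. Each
sample's vector is then jittered with a Dirichlet draw and event counts are
multinomial at the configured burden, so counts sum to the burden exactly.

Defaults (one choice, not revisited): 100 HRD + 100 HRP samples; WGS
burdens of 5000 SBS / 250 ID / 100 segments per sample (typical
breast-genome orders of magnitude), WES preset 80 / 15 / 60; effect sizes
2.0–3.0 so cohort-level log2 fold changes land near 1–1.5, comfortably
above the 0.75 WGS selection bar; Dirichlet concentration 500, sized so
that per-sample channel proportions vary with ~30–50% CV (individual
samples overlap between classes) while 100-sample group means are stable to
a few percent and the null screen (all effects 1, hence exchangeable
classes) stays far below the selection thresholds.

Record emission places events at uniform positions on a toy genome of
three 60 Mb chromosomes and constructs flanks that *realize* the drawn
channel (copies placed 3′ of the event behind a breaker base, 5′ flank
ending in a non-matching base; microhomology built as a partial prefix of
the deleted sequence). Half of all emitted substitutions and indels are
written on the purine/opposite strand to exercise strand collapse.
Classifying emitted records reproduces the intended channel exactly, which
is asserted per channel in the tests.

What the generator does **not** emulate: mutational-signature mixtures and
their correlated channel structure, chromosome-level spatial clustering
(kataegis, chromothripsis), purity/subclonality, sequencing noise, and
inter-feature correlations beyond what the class tilts induce. Passing
tests therefore demonstrate correctness of the machinery and
recoverability of the designed signal, not clinical performance on real
tumors — the synthetic classes are better separated than real HRD/HRP
cohorts, and held-out AUC ≈ 1 here should not be read as an expected
real-data AUC.

## Problem sizes and numerics

The shipped tests and the acceptance script use the default cohort sizes
above (100+100 training, 50+50 or 100+100 held-out) and 100-seed replicate
loops for sign-stability and null controls; these sizes give the replicate
fractions a resolution of 1%. Fisher p-values are validated against
exhaustive hypergeometric enumeration on all 2×2 tables with margins ≤ 30
(canonical representatives under the p-preserving table symmetries, with
symmetry invariance asserted separately), using the standard 1 + 1e−7
relative slack for probability ties. AUC is validated against brute-force
pairwise concordance. Platt fitting starts at slope −1/intercept 0;
sigmoid arguments are clipped at ±500 to avoid overflow. All randomness
flows through `numpy.random.default_rng` seeds; the CLI is single-threaded.

## Known limitations

* Trained models are cohort-specific: a model fit on synthetic data says
  nothing about real tumors, and real-data models require the user's own
  catalogs and scar-score/BRCA annotations.
* The 2×2 count-pooling realization of the enrichment test treats events,
  not samples, as units; with strong per-sample overdispersion its
  p-values are anticonservative, which is why selection also requires the
  fold-change bar and why the screen is a diagnostic, not an inferential
  endpoint.
* ID-83 classification of deletions longer than ~25 bp may request longer
  flanks than callers typically export.
* VCF input requires a FASTA for flanks; the TSV dialect is the
  self-contained path.
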