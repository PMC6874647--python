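# Methods

## Model and procedure

`ontodriver` treats driver-gene prediction as representation learning on
formal background knowledge followed by supervised classification.

**Ontology model.** An ontology is a set of named classes plus subclass
axioms, either plain (`A ⊑ B`) or single existential restrictions
(`A ⊑ r some B`). Reasoning is restricted to transitive closure over the
plain subclass relation: entailed `A ⊑ C` axioms are materialised
(marked *inferred*), reflexive axioms are never added, and existential
restrictions are not propagated. This covers the dominant axiom shape in
annotation ontologies while keeping the closure testable against
brute-force reachability. Full OWL reasoning (equivalence axioms,
property chains) is deliberately out of scope. Both inferred axioms and
class-label metadata sentences can be switched off; both default to on,
since each adds context linking related classes.

**Corpus.** Each axiom becomes one sentence (3 tokens for plain
subclass, 5 for existential), each labelled class one metadata sentence
(`class label <label tokens>`), and each gene–class association one
sentence `gene hasAnnotation class`. A single shared association
relation token is used for all annotation sources so that genes from
different ontologies share context structure. Sentences are emitted in
deterministic sorted order (axioms, metadata, associations) so the
corpus — and everything downstream — is invariant under permutation of
the input annotation records.

**Skip-gram embedding.** Trained by negative sampling (SGNS) in numpy:
unigram^0.75 noise distribution, 5 negatives per positive pair, logistic
loss, linearly decaying learning rate from 0.025. Defaults: dimension
100, window 5, minimum count 5, 60 epochs. Dimension, window, and
minimum count are the parameter combination selected in the study this
package operationalises; the epoch count is not reported there and was
set by a convergence check on the default synthetic corpus (embedding
quality plateaus between 60 and 100 epochs; 30 is under-converged).
Two deliberate deviations from stock word2vec serve determinism: the
context window is fixed rather than randomly shrunk per position, and
training runs single-threaded, so a fixed seed reproduces vectors
bit-for-bit. Gene tokens are exempt from minimum-count pruning — with
min-count 5 a gene with fewer than five annotations would otherwise
receive no vector, contradicting the requirement that the union
representation covers every annotated gene. Gene vectors are read
directly from the trained vocabulary (genes are corpus tokens), not
averaged over class vectors.

**Representations.** Five per-gene feature sets: one per source ontology
(genes annotated in that source), the *intersection* (genes annotated in
all sources; per-source vectors concatenated in a fixed source order),
and the *union* (one embedding trained on the merged ontology with all
annotations; every gene annotated anywhere). Gene counts therefore obey
|intersection| ≤ each single source ≤ |union|.

**Classifier.** One binary feedforward network per cancer type rather
than a single multi-label network: the balanced negative-sampling
scheme (equal numbers of known drivers and genes that are drivers for
*no* type) is defined per type, and a pooled micro-average reproduces a
single headline metric across types; the per-type macro mean is reported
alongside. The network is ReLU hidden layers (default widths 128, 64),
one sigmoid output, binary cross-entropy, RMSprop (lr 1e-3, ρ 0.9,
ε 1e-8), 150 epochs at batch size 16, implemented in numpy with
deterministic seeding. Features are standardised using training-fold
statistics only. Evaluation is stratified k-fold (default k = 10) with
per-fold precision/recall/F/AUC plus pooled metrics over concatenated
held-out scores; F-scores use the 0.5 operating point, since no other
threshold is privileged. ROC-AUC is computed by the rank (Mann–Whitney)
formula with half-credit for ties; curve points for plotting come from
scikit-learn. Novel candidates for a type are genes scoring at or above
threshold that are not already labelled drivers of that type.

## Validation statistics

* **Mutation frequency** — per-gene somatic mutation count divided by
  gene length (the length column is taken as given; whether it is CDS or
  genomic span is up to the data provider). Candidates vs non-drivers
  are compared with a hand-implemented one-tailed Welch *t*-test
  (Welch–Satterthwaite df), cross-checked against scipy in the tests.
* **Network modules** — the observed number of candidate genes with at
  least one edge to a known driver (adjacency, not membership), against
  a null of 10,000 uniform node samples of the same size. The empirical
  permutation p-value `(1 + #{null ≥ obs}) / (1 + N)` is the primary
  result; a one-sample t-style p of the null draws against the observed
  value is reported alongside because the original analysis framed the
  comparison as a one-tailed t-test. Comparison groups for this and the
  other tests follow a three-way split: known drivers, predicted
  candidates, everything else.
* **Pathogenicity enrichment** — after filtering to coding variants
  (records with no coding flag are dropped and counted) and rare
  variants (population allele frequency < 0.01 or absent; absent counts
  as rare, the novel-variant convention), a one-tailed Mann–Whitney U
  test per scoring tool asks whether candidate-gene variants are scored
  more deleterious. Score orientation is explicit configuration: SIFT
  and FATHMM are lower-is-worse, PolyPhen-2, MutationAssessor,
  MutationTaster, CADD and VEST3 higher-is-worse. The U test uses
  midrank ties, exact enumeration when n ≤ 12 without ties, and the
  tie-corrected normal approximation with continuity correction
  otherwise.

## Synthetic data: what it emulates and what it does not

The generator produces every input format the pipeline consumes with a
planted, recoverable driver signature. Defaults define the study
conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 500 | genes in the universe |
| `n_cancer_types` | 3 | driver label columns |
| `driver_fraction` | 0.2 | P(gene is a driver for ≥ 1 type) |
| `n_classes_per_ontology` | 20 | classes per source DAG (branching 2) |
| `annotations_per_gene` | 6 | association records per gene |
| `signal_strength` | 0.9 | P(driver annotation drawn from its type's subtree) |
| `source_presence` | 0.7 | P(gene annotated in a given source) |
| `p_within` / `p_background` | 0.5 / 0.01 | driver–driver vs background edge probability |
| `variant_shift` | 2.0 per tool | pathogenicity score shift (SD units) in driver genes |
| `variants_per_group` | 200 | variants for driver-side and background genes |

Three cancer types (not the twenty of a realistic label table) keep
≥ 10 positives per type at 500 genes so stratified 10-fold
cross-validation is well defined; the per-type count, not the number of
types, is what the classifier machinery is sensitive to. The signal is
planted in annotation space only — each driver's annotations come from a
designated ontology subtree with probability `signal_strength` — so the
classifier can only succeed if the signal survives the corpus →
embedding path; nothing is injected into feature space directly.
`signal_strength = 0` yields an exact null dataset (chance-level AUC),
and `complementary_signal` restricts each type's signal to one ontology,
reproducing the situation where merging ontologies outperforms any
single source. Pathogenicity scores are Normal(0,1) vs Normal(δ,1) with
the sign flipped for lower-is-worse tools: only shift and orientation
matter to a rank test, so tool-realistic score ranges are not modelled.
Mutation counts are Poisson with elevated per-base rate in driver genes;
lengths are log-uniform 500 bp–50 kb.

The generator does **not** emulate: realistic ontology content or depth,
annotation evidence codes, mutational signatures, tumor heterogeneity,
linkage between variants and mutation counts, or degree distributions of
real interaction networks (the background is Erdős–Rényi). Passing tests
therefore demonstrate that the machinery recovers a planted signal of
this simple geometry, not that real-data performance figures transfer.

## Numerical choices and degenerate inputs

* F-score is 0 when there are no true positives (including the all-zero
  corner, which is logged).
* AUC requires both classes; single-class input is an error. Ties get
  half credit.
* Welch test: both groups constant and equal → t = 0, p = 0.5 with a
  warning; constant with unequal means → error.
* Mann–Whitney: all pooled values tied → p = 0.5 with a warning.
* Permutation test with a zero-variance null: p is 0 or 1 by direct
  comparison of observed vs null mean.
* Empirical p-values use the add-one rule, so the minimum attainable p
  is 1/(N+1), never 0.
* OBO/OWL parsing rejects axioms whose endpoints are undeclared classes;
  OWL lines outside the supported functional-syntax subset are skipped
  with a counted warning. Underscore-form identifiers are normalised to
  CURIE colon form in memory.
* All stochastic stages (generation, embedding, fold splits, negative
  sampling of training sets, permutations) derive their generators from
  explicit integer seeds; per-component streams are split off the master
  seed so regenerated artifacts are byte-identical.

## Problem sizes

The test-suite and reproduction-script runs use the default synthetic
conditions above (500 genes; reduced to 120–250 genes and fewer epochs
in tests that only exercise plumbing or monotonicity), 10,000
permutation draws where the permutation test is the object of study and
199 per replicate in the 1,000-replicate calibration checks. These sizes
were chosen so each statistical check retains comfortable power.

## Known limitations

* The OWL reader covers only the functional-syntax subset the corpus
  renderer uses (declarations, named-class subclass axioms, single
  existential fillers, rdfs:label assertions).
* Embedding hyperparameters beyond dimension/window/min-count are not
  searched; the architecture of the classifier is configurable but not
  optimised per dataset.
* Output probabilities are not calibrated; the 0.5 candidate threshold
  is a convention, and candidate counts are sensitive to it.
* The t-style p-value for the network test treats the observed value as
  fixed and the null draws as a sample; the empirical permutation p is
  the statistically preferred quantity and the two are both reported.
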