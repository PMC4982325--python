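# Methods

## Model

Each ITS1-length DNA sequence is mapped to a feature vector: the relative
frequencies of all 4^k words of length k (lexicographic order, sliding
windows of step 1), optionally followed by the sequence length divided by
the training-set average length, and the GC content in percent. Only
A/C/G/T characters participate: windows containing any other IUPAC code are
skipped and the frequency denominator is the number of valid windows (an
all-zero block when none exists), and GC percent is taken over A/C/G/T
characters only. Frequencies rather than counts are used so that sequence
length enters through exactly one feature.

Classification is naive Bayes with one Gaussian per genus and feature:

    log P(c | x) = log pi_c + sum_f log N(x_f; mu_cf, s2_cf) - log Z(x)

* priors `pi_c = n_c / N` (training class frequencies);
* maximum-likelihood (1/n) means and variances per genus and feature. The
  1/(n-1) correction is immaterial at the curation floor of five sequences
  per genus and is not applied;
* a variance floor per feature of `(1e-4 x global training range)^2`, with
  an absolute floor of `1e-12`, preventing zero-variance likelihood spikes
  on features constant within a genus;
* all probability arithmetic in natural-log space with log-sum-exp
  normalization — at 1026 features the product of densities underflows
  double precision otherwise.

The predicted genus is the posterior argmax; exact ties go to the
lexicographically smallest genus name. No minimum-posterior threshold is
imposed: the argmax and its posterior are always reported and thresholding
is left to the user. At prediction time the normalized-length feature uses
the training-set average length frozen in the model, never the query batch
mean, so single sequences are classifiable. Sequences with no valid k-mer
window (shorter than k) are classified from the all-zero block and flagged
`no_valid_kmers`.

## Curation

Raw labeled sequences pass four filters, in this order, each with audit
counts (input, removed, output):

1. **taxonomy** — kept iff the genus is non-empty, no rank value contains
   one of the (case-insensitive) markers `incertae sedis`, `environmental`,
   `uncultured`, `unidentified`, and any annotated species is a binomial
   whose first token equals the genus;
2. **dereplication at 100 % identity** — a sequence equal to, or a
   contiguous substring of, another is removed; the representative of a
   redundancy group is its longest member, ties broken by smallest id;
   survivors keep input order. Only same-strand containment is considered
   (ITS1 amplicons are conventionally same-strand); duplicates carrying a
   different genus than their representative are logged in the audit;
3. **length** — 100–400 nt, bounds inclusive;
4. **abundance floor** — at least `min_per_genus` (default 5) records per
   genus, counted on the input to this step; it runs last because earlier
   steps change counts. A species-keyed variant (`floor_rank="species"`)
   supports dataset reduction at the species level.

The chain is idempotent, and membership of the curated set is invariant
under permutation of the input (representative ids can differ only through
the documented tie rule).

## Evaluation protocol

* **Holdout**: test size = floor(0.2 N), drawn uniformly without
  replacement — deliberately not stratified; genera absent from the
  training side are recorded as unclassifiable (and score as errors), not
  dropped. A stratified draw can be had by splitting per genus externally.
* **Cross-validation**: a global random partition into 10 folds with sizes
  differing by at most one; each record is tested exactly once and the mean
  accuracy pools correct calls over all folds divided by N.
* **k sweep**: cross-validated accuracy for k = 2..6 with one shared fold
  assignment so rows are comparable.
* **Model comparison**: two evaluation reports restricted to their shared
  genera, ordered by the accuracy difference; the "equal performance"
  fraction uses exact equality of accuracies rounded to two decimals.
* **Information gain**: each feature is discretized into 10 (configurable)
  equal-width bins over its observed range; IG = H(class) − Σ_b p(b)
  H(class|b) in bits, ranked descending with ties by feature index.
  Equal-width binning is used deliberately; MDL-style supervised
  discretization adds complexity without affecting anything downstream
  here.
* **Nearest-neighbor baseline**: 1-NN by cosine similarity on the k-mer
  block only (scalar features excluded), ties to the smallest training
  index — an alignment-free stand-in for a best-hit database search.

## Synthetic data

The generator emulates the statistical structure the classifier assumes: a
genus-labeled collection of 100–400 nt sequences in which members of a
genus are more similar to each other than to members of other genera. Each
genus is a star phylogeny: one i.i.d. ancestor (length uniform in 150–350
nt by default, kept inside the curation window so indels cannot push
members out; G/C probability `gc_bias`, default 0.5), and each member an
independent mutant of it — per site, substitution to a uniformly different
base with probability `sub_rate` (default 0.05), deletion with probability
`indel_rate/2` and insertion of a uniform base after the site with
probability `indel_rate/2` (default `indel_rate` 0.01). Defaults: 50 genera
of 20 sequences. Each genus draws from its own generator seeded by
(seed, genus index), so adding genera or resizing one genus never perturbs
the others; a fixed seed reproduces the dataset byte for byte.

What the generator does **not** emulate, and what that means for the
tests: real congeneric ITS1 sequences share nucleotide composition by
common descent across genera, contain conserved flanks and
secondary-structure constraints, and real genera are not star phylogenies
of one ancestor. Because the synthetic ancestors are independent random
sequences, genera are already separable from short-word composition:
cross-validated accuracy is near its ceiling at k = 2–3 and the benchmark
therefore cannot reproduce the empirically observed *rise* of accuracy
from k = 2 up to k = 5 on real data — the low-k side has no room to rise.
Conversely, at k = 4 on ~250 nt sequences the expected count per word is
about one, the worst regime for per-class Gaussian variances (a word absent
in every training member of a genus but present once in a test sequence
incurs an enormous log-penalty), and cross-validated accuracy dips; an
independent Gaussian-NB implementation (scikit-learn) reproduces both
effects on the same vectors. Passing the synthetic benchmarks therefore
shows that the pipeline recovers genus structure of the assumed form at
realistic divergence, not that real-data accuracies or the real k-response
curve are reproduced.

Problem sizes used by the test suite and the acceptance script — 50 genera
x 20 sequences for the study benchmarks, 10 x 8 for unit fixtures — were
chosen as the smallest sets on which the statistics of interest are stable.

## Numerical and design choices

* Degenerate inputs: empty FASTA gives an empty call table; a sequence
  shorter than k is classified from an all-zero k-mer block and flagged; a
  mutation that deletes an entire sequence is retried once and then
  rejected; training requires at least two genera and warns below two
  vectors per genus.
* The length bounds 100 and 400 survive filtering (exclusion is strictly
  "below 100" / "above 400").
* Lineages travel as a flat TSV table (id + phylum..genus[, species])
  rather than a taxonomy-database connection, keeping the package
  self-contained and offline.
* Models serialize as versioned plain-text JSON with full-precision
  floats: diffable, language-portable, exact round-trip.
* The ARFF export writes one numeric attribute per feature and a nominal
  class attribute, for interoperability with the Weka workbench; no ARFF
  reader is provided (training reads FASTA + lineages directly).
* Reverse complements are never collapsed — neither in dereplication nor
  in k-mer counting.

## Known limitations

* Gaussian class-conditionals are a modelling convenience; in the sparse
  k-mer count regime (see above) they are mis-specified, and no
  kernel-density or multinomial variant is provided.
* Genus labels are treated as globally unique strings; homonymous genera
  from different phyla would collide.
* The classifier reports no bootstrap-style confidence, only the naive
  Bayes posterior, which is typically overconfident.
* The curation step is quadratic in the number of sequences (substring
  containment by direct scan); fine at desk scale, not optimized for
  hundreds of thousands of sequences.
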