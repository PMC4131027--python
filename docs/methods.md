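# Methods

## Model

A metagenomic sample contains reads from an unknown mixture of genomes. After
alignment against a reference set, each read *rᵢ* carries a score *sᵢⱼ* for
every genome *gⱼ* it hits. The method treats the assignment of a read as a
probabilistic consequence of genome similarity: a read from genome *j* lands
on genome *j′* with probability *W*[j, j′], the (estimated) chance that *j′*'s
sequence matches the read nearly as well as its true origin does. Writing
*tⱼ* for the number of reads genome *j* receives only due to its own presence
and *bⱼ* for the number observed under the α multi-assignment rule, the
expected counts satisfy

    b = Wᵀ t .

Because every genome has unique regions, off-diagonal entries of *W* are
strictly below 1, the system is invertible, and *t* is recovered by a direct
dense solve. The estimator therefore has three ingredients: an empirical *W*,
a screening step that decides *which* genomes enter the system (elimination),
and the solve itself (correction).

### Similarity estimation

For each reference genome, K₀ error-free reads of the target read length are
simulated at uniform positions and aligned against the full reference set.
A read is assigned to every genome whose score reaches α · (its maximum
score). The similarity is the count ratio

    w[j, j′] = n(j→j′) / n(j→j) ,

normalized by the self-assigned count so the diagonal is exactly 1 (an
alternative normalization by K₀ is available via `normalize_by_k0`; it makes
the diagonal a mapping rate rather than 1 and is not used by the correction
stage). Entries below `threshold` are zeroed: they are at the resolution
limit of K₀ simulated reads and would only perturb the solve. *W* is not
symmetric in general (a short genome contained in a long one maps into it
far more often than the reverse).

Defaults: K₀ = 30,000 reads/genome, α = 0.96, threshold = 0.001. K₀ is fixed
per genome, not per bp. Similarity reads carry no simulated sequencing
errors: *W* is meant to capture sequence identity between references, not a
platform's error profile. A matrix is specific to its read length; with
several matrices on hand, `select_matrix_by_read_length` picks the nearest
(ties to the shorter length), since mis-assignment probabilities grow as
reads shorten.

### Elimination

Top-score assignment gives a binary K×N matrix *A* (ties share the read;
score ties are detected with an absolute tolerance of 1e-9 because bit
scores are computed floats). The greedy pass:

1. select the column with maximal L1-norm (ties: lexicographically smallest
   genome id — the choice is arbitrary but must be deterministic);
2. if that norm is below the minimum count *c*, stop — every unselected
   genome has no uniquely attributable support and is eliminated;
3. otherwise the genome claims its reads (its current norm is recorded as
   the *claimed count*), the claimed rows are zeroed in every other column,
   and the pass repeats.

Each read is claimed at most once, so claimed counts sum to ≤ K, and a
genome holding ≥ *c* reads that hit nothing else can never be eliminated —
no other column can subtract those rows. Two implementations exist: the
while-loop above and a literal matrix recursion (right-multiplication by a
permutation matrix that swaps the max-norm column into place, a subtraction
matrix that subtracts it from all later columns, then an entrywise clamp at
zero). They are required to agree exactly; a 1,000-matrix randomized
cross-check in the test suite enforces the equivalence.

The bootstrap wrapper resamples the K reads (rows) with replacement —
the read is the experiment's sampling unit — and reruns the full greedy pass
per replicate with c = max(1, ceil(cutoff_frac · max column norm)); the max
column norm equals the top genome's claimed count since the greedy pass
selects it first. A genome is *below cutoff* in a replicate if it is
eliminated there or claims fewer than cutoff_frac times the top claim;
genomes below cutoff in more than occurrence_frac of replicates are removed.
Defaults: 100 replicates, cutoff_frac = 0.0005 (0.05 % — half of the 0.001
similarity threshold, because the most abundant genome's claim is inflated
by whatever its undetectably-similar relatives contribute), occurrence_frac
= 0.05. "Abundance" here is the claimed count from the pass within that
replicate; corrected counts do not exist yet at this stage.

### Correction

Counts *b* are recomputed over the retained genomes only, with the max score
per read retaken over the retained set (the read is *re*-assigned among
survivors) and the same α used to build *W* — mixing αs makes *W* describe a
different assignment process than the one that produced *b*, so the pipeline
warns when they differ. The solve is dense LU with a condition-number guard
(bound 1e12); no regularization is applied, since off-diagonal similarities
below 1 already guarantee invertibility in exact arithmetic. Components with
*tⱼ* ≤ 0 are impossible read counts; all such genomes are dropped in one
pass by default (one-at-a-time removal is available for sensitivity
analysis) and the loop terminates in at most m passes. The zero boundary is
dropped too: a genome contributing zero reads is not present.

### Error measures

With eᵢ = (tᵢ − τᵢ)/τᵢ over the N true genomes, RRMSE = 100·√(mean eᵢ²),
AVGRE = 100·mean|eᵢ|, MAXRE = 100·max|eᵢ|. All are scale-invariant; they are
computed on read counts. A true genome missing from the estimate contributes
eᵢ = −1; genomes estimated present but not in the truth are excluded from
the measures and reported as false positives.

## Synthetic data and what it does (not) show

The generator draws i.i.d. uniform random genomes; relatedness is engineered
by per-site substitution of a base genome at a chosen rate, which translates
directly into the off-diagonal mass of *W*. Reads are fixed-length,
forward-strand, from linear (non-circular) genomes, with an optional
substitution-only error model; per-genome counts follow deterministic
largest-remainder allocation of the proportions (ties: larger remainder,
then larger proportion, then index) so the truth τ is exact and error
measures carry no allocation noise (a multinomial mode exists). The built-in
aligner seeds on exact shared 16-mers and scores full-length ungapped
alignments (match +1, mismatch −2; N never matches); scores enter the method
only through ratios, so the absolute scale is immaterial.

Real data differ in ways the generator does not emulate: genomes share
homologous blocks rather than uniform divergence, reads vary in length and
carry indels and platform-specific error profiles, and aligners produce
gapped local alignments. Passing tests therefore demonstrate the estimator's
correctness and its behaviour under controlled similarity, not performance
on any particular sequencing platform.

## Benchmark problem sizes

The reference benchmark (`scripts/acceptance.py`, also run in the test
suite) uses five independent 50 kb genomes, 150,000 error-free reads of
100 bp at ratios 1:2:5:10:20, K₀ = 5,000 and 100 bootstrap replicates —
genome lengths and K₀ chosen so the whole run completes in minutes on one
CPU while keeping per-genome coverage high enough (≥ 8×) that unique regions
are well sampled. The similar-pair experiment uses a 50 kb base genome plus
a 5 % mutant at proportions (2/3, 1/3) with 30,000 reads and K₀ = 3,000.

## Known limitations

- Genomes absent from the reference cannot be detected; their reads inflate
  their closest relatives.
- Genomes below the bootstrap cutoff (0.05 % of the top genome) are
  unrecoverable by construction.
- The aligner is ungapped and single-strand; it is an oracle for synthetic
  data, not a replacement for BLAST on real samples.
- Elimination retains at most one of a set of exactly identical genomes
  (ties are broken lexicographically), and the correction stage cannot
  separate genomes whose similarity approaches 1 — the condition-number
  guard raises instead of returning meaningless counts.
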