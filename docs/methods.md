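# Methods

This note documents the models and procedures implemented in
`qadiscourse`, the defaults and why they were chosen, what the
synthetic generator does and does not emulate, and the numerical
conventions that make every run reproducible.

## Preprocessing funnel

Records flow through keyword filter → answered-only filter → seeded
subsample, with counts recorded at each stage (`CorpusFilterReport`,
weakly decreasing by construction).

- *Keyword matching* is case-insensitive substring matching on raw
  text, applied to the question and (by default, configurable) to the
  answers.  Substring semantics is deliberate: it is what "any
  morphological form of the keyword" means operationally without a
  language-specific stemmer.
- *Top answer*: maximal upvotes; ties broken by earliest answer
  timestamp, then input position.  The tie rule is an artifact
  convention — some rule is needed for reproducibility — and is
  tested.
- *Sampling* is uniform without replacement from a single seeded
  generator (`numpy.random.default_rng`), output sorted by question
  date with record id as the deterministic secondary key.

## Topic categorization

### LDA by collapsed Gibbs

Standard LDA with symmetric Dirichlet priors.  The sampler integrates
out φ and θ and resamples token topics from the usual collapsed
conditional; point estimates come from the final state with Dirichlet
smoothing.  Defaults: α = 50/K, β = 0.01, 1000 sweeps, single
final-state estimate.  These are conventional textbook settings; the
inference method and priors are artifact choices, documented rather
than inherited.  The inner loop is numba-compiled and seeds numpy's
legacy generator inside the kernel, so a (corpus, K, α, β, sweeps,
seed) tuple determines the fit bit for bit.

The sampler can retain the topic assignments of the last *m* sweeps.
That is how it is validated: on a 2-document, 5-token corpus the
label-invariant co-assignment probabilities P(z_i = z_j) from the
sampler are compared against brute-force enumeration of all K^5
configurations of the collapsed joint.  (Per-token marginals are
useless for this check — label symmetry forces them to 1/K.)

Documents empty after tokenization are excluded with a warning and
their positions reported, never a crash.

### Model selection

Mean UMass coherence over topics, candidates scored with the same
seed, argmax with ties to the smallest K.  The pair term is
log[(D(wᵢ,wⱼ)+1)/D(wⱼ)] over ranked keyword pairs i<j, where D counts
co-document occurrences.  A keyword absent from every document
contributes log(1/n_docs) per pair — the smallest value the term can
take at numerator 1 — and is logged.  Note the score is *not* always
≤ 0: when two keywords always co-occur the term is log((D+1)/D) > 0.
No claim is made (or tested) that coherence selection recovers a
planted K; the operation reports a table and a deterministic choice.

### Merge and embedding

The merge of raw topics into interpretable labels is human judgment
and enters as configuration (`MergeMap`), never computed.  A
document's merged label maximizes summed θ mass over the label's raw
topics (ties by label order); merged keyword pools are unions of
member topics' keyword lists.

The embedding is a deterministic stand-in for a learned joint
word/document space: positive PMI over document-level co-occurrence
(C = XᵀX with the within-document self-pair correction c(c−1) on the
diagonal), truncated SVD, word vectors U·S with a sign convention
(largest-magnitude component of each singular vector made positive),
document vectors the L2-normalized mean of their token vectors.
Chosen because it is seed-free and bit-stable while preserving the
property that matters here: words and documents comparable by cosine
in one space.  A learned backend (doc2vec-style) can be plugged in
behind the same contract.  Tokens with no co-occurrence signal get
zero vectors (logged); cosine against an all-zero vector is an error,
and degenerate document vectors fall back to the most frequent label
with a log entry.

Topic vectors are arithmetic means of member document vectors; a
topic's semantic keywords are the pool candidates ranked by cosine to
its topic vector (ties lexicographic).  Final document labels default
to the merged-LDA argmax; re-assignment by nearest topic centroid is
an optional refinement flag, off by default, because either route is
defensible and the default is the one that needs no extra machinery.

Known limitation: at small corpus sizes a fitted topic can collapse
(no document takes its argmax), leaving a merged label with zero
members.  The tables then carry an honest zero row, temporal
statistics for that label are null, and a warning is logged.

## Sentiment

Tokenization is shared with the topic stage (lowercase, split on
whitespace/punctuation, no stemming).  Documents are chunked into
consecutive 128-token pieces (all full except the last; concatenation
reproduces the input).  Chunk scores are averaged unweighted — each
chunk counts equally regardless of length — with a length-weighted
variant behind a flag.  Scorers are bagged by averaging their
document-level probabilities; the label with the higher average wins
and an exact tie goes to positive (an explicit, tested convention).
Questions are scored by the same procedure as answers.

The reference scorer is lexical: s = (n⁺ − n⁻)/(n⁺ + n⁻ + 1),
p_pos = (1+s)/2.  The +1 keeps the score defined and shrinks it
toward neutral on lexicon-sparse chunks.  It is monotone (adding a
positive token never lowers p_pos), deterministic, and exactly
recoverable on the synthetic world — which is why the test suite runs
on it exclusively.  Transformer sentiment heads are optional adapters
satisfying the same (p_pos, p_neg) protocol; their accuracy on real
platforms is backend-dependent and out of scope here.

## Discourse statistics

All percentages are computed from integer counts by exact decimal
arithmetic with half-up rounding: topic proportions to integer
percent, sentiment and pair percentages to two decimals.  Counts are
always retained exactly, and a `marginal_check` asserts that the pair
table's column sums reproduce the answer (and question) sentiment
counts per topic — run automatically in every end-to-end fit.

Temporal series: the month of a record is its calendar month, except
a leading partial month spanning ≤ `merge_threshold_days` (default 7)
days of the window, which folds into the following month — the
analysed window began June 27, so its four June days belong to July;
any threshold ≥ 4 reproduces that behavior.  Months with zero records
carry a null share and are skipped, not imputed.  A crossover is a
strict sign flip of (share − 0.5) between consecutive non-null months;
an exact 0.5 carries the previous sign, a leading 0.5 counts positive.
A dominance streak is the longest run of consecutive months with the
polarity's share strictly above one half (null months break runs, ties
go to the earliest run).  The crossover definition is this package's
own formalization — the phenomenon is usually described qualitatively
— and is documented rather than claimed canonical.

## Synthetic world

The generator states one world and the tests measure it; nothing in
it was tuned against test outcomes.

- Scale and window: 3952 records per platform over
  2020-06-27..2021-06-27, the analysed corpora's size and span.
  Platform presets (`quora_like_config`, `naver_like_config`) carry
  the observed topic proportions (5 and 7 topics), question-positive
  rates per topic taken from the observed pair-table marginals, and
  monthly answer-positivity curves shaped like the observed temporal
  patterns (multiple crossovers on the 5-topic platform; stabilization
  above 0.5 from early 2021 on the 7-topic one).  Two printed topic
  counts are bumped by 2–3 records so the proportion vectors sum
  to one (the printed counts do not quite sum to N).
- Topic structure: each topic owns a private vocabulary (40 tokens by
  default) plus a shared noise vocabulary (30 tokens); non-lexicon
  tokens come from the topic core with probability 0.8.
- Sentiment is purely lexical: polarity tokens injected at rate 0.15
  with 0.03 opposite-polarity noise — strong enough that the lexicon
  scorer can recover planted labels (the identifiability property the
  tests assert at ≥ 0.95), weak enough that chunks are mostly topic
  tokens.
- Document lengths are uniform on 30–400 tokens, so a substantial
  fraction of answers exceed one 128-token chunk and the chunking
  path is genuinely exercised.
- Answers: 1–5 per record; one designated gold answer carries
  strictly maximal upvotes (margin ≥ 1) so the top-answer rule has a
  unique planted winner; filler answers are short and not analysed.
- Temporal structure: when a month → positivity-rate map is given,
  answer sentiment is drawn per month from it (planting crossovers);
  otherwise the answer agrees with the question with probability ρ
  (default 0.7).

What it does **not** emulate: natural language (tokens are abstract
symbols), platform norms, answer-length asymmetries between
platforms, bots, or topic drift within a month.  A green test on this
world establishes that the machinery recovers planted structure under
its stated assumptions — not that any particular real-world corpus
would be classified at the same accuracy.

## Determinism

Every stochastic step takes an explicit integer seed (corpus
sampling, generation, Gibbs); the embedding and all statistics are
deterministic.  Two runs of the full pipeline with the same config
and seed produce byte-identical result tables; writers emit sorted
keys, LF newlines, and fixed float formatting to make that checkable
with a byte compare.

## Source-table arithmetic

The published tables this package's conventions are matched against
contain a number of typeset percentages inconsistent with their own
printed counts (three sentiment-proportion cells and most cells of
one pair table; a second pair table has four cells off by 0.01).  The
acceptance tests pin the *recomputed* exact half-up percentages of
the printed counts, which equal the printed percentages wherever the
print is self-consistent.  The printed counts themselves are fully
consistent: every pair-table row sums to its topic N and every
column-sum reproduces the corresponding sentiment count exactly.
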