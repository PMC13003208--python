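# qadiscourse

Analysis pipeline for public discourse on social question-and-answer
platforms, built for health-communication / infodemiology studies that
compare what users ask about a health topic (e.g. COVID-19 vaccines),
how the community answers, and how answer sentiment drifts over time —
across two platforms at matched sample sizes.

It implements, as a tested and reusable library + CLI:

- **Corpus preprocessing funnel** — keyword filtering (case-insensitive
  substring, so "vaccine" matches "vaccines" and "vaccinated"),
  removal of unanswered questions, selection of the most-upvoted
  answer per question, and seeded subsampling to a fixed N so two
  platforms can be compared head to head.
- **Hybrid topic categorization of questions** — collapsed-Gibbs LDA
  (UMass-coherence model selection over candidate K), a user-supplied
  merge of raw topics into interpretable labels, and a shared
  word/document embedding space (PPMI + truncated SVD) in which each
  merged topic is the *centroid of its member question vectors*;
  keywords are characterized by cosine proximity to that topic vector,
  restricted to the LDA keyword pool acting as a coarse topical filter.
- **Chunked ensemble sentiment for answers** — documents are split
  into 128-token chunks (long posts would otherwise be judged by their
  opening tokens), each chunk scored for positive/negative
  probabilities, chunk scores averaged, and several scorers bagged by
  probability averaging.  Scorers are pluggable; the reference backend
  is a deterministic lexicon scorer, and transformer sentiment heads
  can be adapted to the same two-probability protocol.
- **Discourse statistics** — per-topic proportions, per-topic answer
  sentiment shares, question–answer sentiment pair cross-tabulations
  (does a negative question attract a negative answer?), and monthly
  sentiment series with crossover counts (majority-polarity flips) and
  dominance streaks.
- **Synthetic corpus generator** — a fully seeded world with planted
  topics (private vocabularies), per-topic question sentiment rates,
  question→answer sentiment coupling, month-resolved answer positivity
  rates (to plant crossovers), and multi-answer records with a unique
  most-upvoted "gold" answer, so the entire pipeline is testable
  without scraping anything.

## The statistics at the core

LDA: each question *d* mixes *K* topics, each topic *k* is a
distribution φₖ over the vocabulary; the collapsed Gibbs sampler
resamples each token's topic from

    p(z_i = k | z₋ᵢ, w) ∝ (n_dk + α) (n_kw + β) / (n_k + Vβ)

with symmetric priors α = 50/K, β = 0.01; φ and θ are estimated from
the final state with Dirichlet smoothing.  Topic vectors are centroids
t_ℓ = mean{v_d : d assigned to ℓ} in the PPMI/SVD embedding, and a
topic's semantic keywords are argmaxⱼ cos(t_ℓ, v_w) over its LDA
keyword pool.  The lexicon chunk score is s = (n⁺ − n⁻)/(n⁺ + n⁻ + 1),
p_pos = (1+s)/2; the ensemble averages per-scorer document
probabilities and takes the larger (ties → positive).  A crossover is
a strict sign flip of share − 0.5 between consecutive non-null months
(an exact 0.5 carries the previous sign).

## Worked example

```python
from qadiscourse import DiscourseModel
from qadiscourse.synthetic import GeneratorConfig, generate_corpus

cfg = GeneratorConfig(n_records=300, n_topics=2, shared_vocab_size=0,
                      doc_length_range=(30, 80), seed=5)
records, truth = generate_corpus(cfg)
model = DiscourseModel.with_lexicons(records, cfg.pos_lexicon,
                                     cfg.neg_lexicon, K=2, n_sweeps=150)
print(model.fit(seed=7).summary())
```

prints (abridged):

```
Q&A discourse analysis
============================================================
records: 300   topics: 2   seed: 7

Topic proportions (count, % of N):
  topic0                     151  (50%)
  topic1                     149  (50%)

Answer sentiment per topic (pos / neg, % positive):
  topic0                      79 /    72  (52.32%)
  topic1                      78 /    71  (52.35%)

Question-answer sentiment pairs (PP, PN, NP, NN):
  topic0                      55    21    24    51   (N=151)
  topic1                      57    20    21    51   (N=149)

marginal consistency: OK
```

151 + 149 = 300 questions split across the two planted topics; for
topic0, 79 of 151 top answers (52.32%) were classified positive; the
pair row says 55 positive questions drew positive answers, 51 negative
questions drew negative answers, and the pair counts' marginals
reproduce the sentiment counts exactly ("marginal consistency: OK").

The same analysis runs from the shell over YAML config, either end to
end (`qadiscourse run -c cfg.yaml`) or one composable stage at a time
(`generate`, `ingest`, `topics`, `sentiment`, `pairs`, `temporal`,
`report`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline analysis from scratch: it generates
the two platform-analogue synthetic corpora (a 5-topic and a 7-topic
world, 3952 records each after the sampling funnel), runs the full
topic + sentiment + pair + temporal pipeline on both, writes all
result tables and a platform comparison next to the output file, and
verifies the internal marginal-consistency check before writing the
results JSON.
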