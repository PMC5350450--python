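# Methods

## The analytic model

`depsignal` analyzes corpora of short texts retrieved by depression-related
keywords and annotated against a closed 22-label scheme (9 DSM-5
depressive-symptom parents, 12 DSM-IV-Axis-IV psychosocial-stressor
parents, and *no evidence of clinical depression*, which is mutually
exclusive with the rest). Five statistics make up the pipeline.

**Keyword matching.** Patterns are literal tokens or terminal-wildcard
prefixes, following the LIWC convention. Matching is whole-token over a
normalizing tokenizer (lowercase, whitespace split, URL/@-mention
placeholders, outer punctuation stripped with hashtags preserved).
Literals require exact token equality because the source list enumerates
inflections separately ("lose", "loses", "losing"); wildcards match any
token starting with the stem. Consequences worth knowing: run-together
spellings ("sodepressed") never match, and the list's bare "divorc" entry
is preserved verbatim as a literal that can match nothing — an explicit
`assume_divorc_wildcard` flag upgrades it to `divorc*`.

**Agreement.** Two annotators' label sets are compared as (tweet,
category) assertion sets over co-annotated tweets; `F = 2m/(2m +
mismatches) × 100` with directional mismatch counts. This equals the
harmonic-mean F1 treating either annotator as reference, is symmetric,
and applies no chance correction. The "overall" row is micro-averaged
(counts pooled over all categories, including no-evidence, then one
formula application); per-category counts therefore sum exactly to the
overall counts. A category asserted by neither annotator is NOT_OBSERVED
and rendered "—". An `EVIDENCE` pooling (the 21 evidence categories only)
is provided because deletion-style annotator noise turns dropped
assertions into explicit no-evidence labels, and agreement *on the
evidence signal* is the quantity with a closed-form expectation under
that noise model (F = 100·(1−d) for deletion rate d on single-label
tweets). Adjudication passes agreed label sets through and resolves
disagreements to the third annotator's labels (three-way disagreements
also resolve to the adjudicator and are logged).

**Keyword precision.** Per keyword: distinct matched tweets
(`tweet_hits`), matched tweets whose gold labels contain any evidence
category (`relevant_hits`), precision = 100·relevant/hits. The five
printed bins (0–19, 20–39, 40–59, 60–79, 80–100) are realized as
half-open real intervals cut at 20/40/60/80 with [80, 100] closed, so
fractional precisions are classifiable while integer percentages land in
the printed bins. The hit *distribution* counts a tweet once per distinct
matching keyword ("nonmutually exclusive hits"); a tweet matched by one
keyword at two token positions counts once. Keywords with zero hits are
reported separately, not as zero-precision rows. Recall is out of scope
(it would require exhaustive gold labels on unmatched tweets).

**Co-occurrence.** Pairwise phi over the 21 evidence-category indicator
columns, computed from the 2×2 table (and property-tested to 1e-12
against the product-moment correlation, which it equals algebraically).
A pair with a constant margin is "not observed". Magnitudes are binned by
Cohen effect-size criteria; the printed criteria leave (0.09, 0.1)
uncovered, so the realized partition is [0,0.1), [0.1,0.3), [0.3,0.5),
[0.5,1] on |φ| — a single consistent partition, documented deviation.
Two-sided P values from the t transform are reported but never drive
binning (they conflate effect with sample size). No multiplicity
correction is applied across the 210 pairs, matching the analysis this
package reproduces.

**Word ranking.** Information gain = mutual information in bits between
binary word presence and a one-vs-rest category indicator (0·log 0 ≡ 0).
Presence, not counts: on ~14-token texts a word rarely repeats. The
corpus is split into 5 equal-sized random subsets — membership keyed by a
salted hash of (seed, tweet_id), so results are invariant to tweet order
— a word's rank is its IG position within each subset (absent words take
vocabulary-size + 1), and words are returned by ascending mean rank with
lexicographic tie-breaks. Stopwords are kept deliberately: personal
pronouns are informative in this domain. Categories with fewer than
`min_mentions` (default 3) positive tweets are SKIPPED rather than ranked
on noise.

## The synthetic-data generator

Real keyword-sampled tweet corpora cannot be shared, so the generator is
the package's test bed: it emits corpora whose analyzable parameters are
planted and hence recoverable.

Per tweet, the 21 evidence-category indicators are drawn as Bernoullis:
each pair listed in `phi_targets` is drawn from the exact 2×2 joint with
the requested marginals and phi (p₁₁ = p_a p_b + φ√(p_a q_a p_b q_b) —
the shared-latent-Bernoulli construction), all other categories
independently. Targets are validated against the Fréchet-admissible phi
interval at construction, and a category may appear in at most one pair,
which keeps the joint distribution well-defined without a 21-dimensional
copula. A tweet with no positive indicator is gold-labeled no-evidence.
Text is then assembled: 3 planted marker words per gold category (from a
10-word category vocabulary absent elsewhere), keyword surface tokens
injected so that P(evidence | keyword present) equals the planted
per-keyword relevance (containment is conditioned on the tweet's realized
evidence status, so measured precision is an unbiased estimate of the
planted value), and Zipf-weighted background words up to a token count
drawn from round(N(14.56, 7.40²)) truncated at 1. Background and planted
words are validated never to match a lexicon pattern, and each injected
keyword token matches exactly one unique pattern, so planted precisions
cannot contaminate each other. Simulated annotators independently delete
each gold evidence assertion with a per-annotator rate (an emptied tweet
becomes no-evidence) and add a spurious category with a second rate.
Everything runs off a single `numpy` generator stream: one seed, one
byte-identical corpus.

### Default study conditions, and why

* **Skew**: prevalences sum to ≈0.30 evidence mass per tweet, split 65:35
  between symptoms and stressors, with depressed mood > fatigue >
  disturbed sleep the most prevalent symptoms; the implied no-evidence
  share of gold annotations is ≈72%, the characteristic shape of
  keyword-sampled depression corpora.
* **Phi targets**: (fatigue, disturbed_sleep, 0.50), (depressed_mood,
  worthlessness, 0.40), (social_environment, primary_support, 0.12) —
  echoing the strongest co-occurrences reported for such corpora and
  covering three Cohen bins. The involved categories are kept moderately
  prevalent (2.6–6.2%) by design: a Monte-Carlo power analysis showed the
  sampling SD of an estimated phi at n = 10,000 is ≈0.02 at these
  prevalences but ≥0.03 for rare categories, so only moderately prevalent
  pairs make a ±0.05 recovery check reliable. For the same reason the
  default uses three disjoint pairs rather than overlapping chains:
  with unlisted pairs independent, chained strong targets violate the
  implied joint-distribution constraints.
* **Keywords**: six planted keywords (tired 0.10, sobbing 0.25, depress*
  0.35, fired 0.55, suicid* 0.70, insomnia 0.85) spanning the five
  precision bins, each present in ≈2% of tweets (~200 hits at n=10,000).
* **Annotators**: three, deletion rate 0.15, spurious rate 0.02.

### What the generator does not emulate

* **Multi-label rarity.** Real annotated corpora of this kind have ~2%
  multi-category tweets; the default generator produces ≈6%, because
  faithful marginal prevalences plus independent draws already collide at
  ~3.5% and the planted pairs add their co-occurrence mass. Matching the
  real figure would require global negative dependence among unlisted
  pairs, which the generator deliberately does not model. The
  `multilabel_rate` knob only *adds* extra labels (default 0).
* **Language.** Text is a bag of background words, marker words and
  keyword tokens — no syntax, no creative spelling, no hashtag semantics.
  Tokenizer robustness to real orthography is tested only on hand-written
  fixtures.
* **Annotator behavior.** Noise is independent per assertion; real
  disagreement is correlated with tweet difficulty.

Passing recovery tests therefore demonstrate that the *estimators* are
correct and well-calibrated at realistic sizes and skews — not that the
pipeline is robust to real tweet language.

## Numerical and design choices

* Entropies use base 2 with exact zero-count handling; IG is clipped at 0
  against −1e-16 float round-off and property-tested to 1e-12 against a
  brute-force contingency-table oracle.
* Phi uses integer 2×2 counts (no incremental float accumulation);
  NOT_OBSERVED beats NaN in scalar APIs, while matrices use NaN plus an
  `observed` mask for tabular ergonomics.
* Ties in IG ranking break lexicographically; ties in average rank break
  lexicographically; both make results fully deterministic.
* Subset assignment sorts tweet ids by SHA-256 of "seed:id" and chunks,
  giving equal sizes (±1) and order invariance at once.
* The worked-example fixtures and all seeds used in tests are fixed
  constants; the test suite runs the default study corpus at n = 10,000
  (seed 1) and smaller corpora (600–5,000) elsewhere to keep the suite
  fast.

## Known limitations

* Precision, frequency and phi analyses require gold labels; there is no
  soft-label or per-annotator variant of those statistics.
* The agreement module implements the uncorrected F score by design;
  chance-corrected coefficients (kappa, alpha) are out of scope.
* Wildcards are prefix-only; no fuzzy matching, hashtag segmentation or
  emoji-aware matching.
* The generator's phi construction supports only disjoint target pairs;
  overlapping correlation structures need an explicit multivariate model
  that this package intentionally omits.
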