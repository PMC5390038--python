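# Methods

This note documents the models and procedures implemented in `mwulex`,
the parameter choices that matter, and what the synthetic validation
suite does and does not establish.

## Incremental chunking by backward transitional probability

The chunker processes a corpus strictly incrementally — utterance by
utterance, word by word — and never looks ahead. Its state consists of
per-word exposure counts, left-neighbour transition counts, a running
mean of all transition BTPs scored so far, and the *chunkatory*: the set
of every unit it has ever closed (single words included).

Per transition (w[i−1], w[i]), the update order is fixed:

1. increment count(w[i]) and count(w[i−1] before w[i]);
2. BTP = count(w[i−1] before w[i]) / count(w[i]);
3. threshold = running mean over *prior* transitions (0 when none)
   plus 1/count(w[i]);
4. attach if (w[i−1], w[i]) is an adjacent pair inside any stored unit
   of length ≥ 2 (chunkatory override), else iff BTP > threshold
   (strict; ties close the unit);
5. fold this transition's BTP into the running mean — always, including
   overridden transitions and first exposures.

Counting before scoring gives the *first-exposure property*: a word's
first-ever occurrence has count 1, hence threshold ≥ 1 ≥ BTP, and can
never attach through the probability rule — only through the
chunkatory. The 1/count term decays with exposure, so the noise guard
vanishes for well-attested words. Utterance boundaries always close the
open unit; units never span utterances.

Two readings of "the average BTP" are implemented: the default
`global_mean` (corpus-wide running mean, matching the original
formulation of the learner) and `per_word_mean` (mean BTP over the
current word's distinct attested left neighbours). Both produce valid
partitions; all shipped analyses use the global mean.

The random baseline shares this control flow exactly, replacing only
the threshold comparison with a Bernoulli(0.5) draw (one draw per
non-overridden transition, consumed in processing order). By default
the baseline keeps the chunkatory stage, so early random groupings
become entrenched just as the chunker's do; this can be switched off
(`baseline_use_chunkatory=False`) for sensitivity checks, in which case
every transition consumes a draw.

## Per-word measures

#MWUs counts distinct unit *types* of length ≥ 2 containing a word
(once per type, however often the word repeats inside the unit or the
unit recurs in the corpus); single-word units are excluded by default
because the analyses contrast multi-word structure against raw
frequency, but `min_length=1` is available. #Freq is the raw token
count. Inventory length summaries are type-weighted by default (each
unit type counted once), with a token-weighted variant by flag; IQR is
Q3 − Q1 with linear-interpolation quantiles.

## Age of first production

Transcripts vary widely in length, so per-transcript MLU is estimated
by bootstrap: 1,000 resamples with replacement of the utterance-length
sequence, sample size equal to the transcript's utterance count, point
estimate the mean of the resample means (which converges on the sample
mean; `reps=0` short-circuits to it). Per-transcript seeds derive from
(master seed, transcript index), so extending a transcript set never
perturbs earlier estimates. A word's AoFP is the *minimum* MLU over
transcripts whose child utterances contain it. The minimum, rather than
an average of first uses, avoids inflation from children who already
used a word before their recordings began; it makes AoFP an "earliest
attested developmental stage" measure on the MLU axis (tokens per
utterance), not an age in months.

## Rank statistics and bootstrap inference

τ-b is computed from the explicit pair decomposition: concordant P,
discordant Q, tied-only-in-x X₀, tied-only-in-y Y₀ (pairs tied in both
enter no term), with τ-b = (P − Q)/√((P + Q + X₀)(P + Q + Y₀)). The
implementation sorts lexicographically and counts inversions by
vectorised merge recursion (O(n log n)); the test suite verifies the
four counts exactly against an O(n²) brute-force enumerator and the τ
value against an independent library implementation. Constant rankings
make the denominator zero and raise a dedicated error; the pipeline
reports such cells as undefined and continues.

Partial τ-b controlling F is
(τ_XY − τ_FX·τ_FY)/√((1 − τ_FX²)(1 − τ_FY²)), undefined when a control
correlation is ±1. Note that this coefficient is *not* exactly zero
under conditional independence: when two variables are both strongly
monotonically coupled to the control, a structural residual remains.
This matters when interpreting partial correlations of
frequency-derived predictors — a nonzero partial #baseline correlation
is expected even though baseline sequences carry no signal beyond
frequency — and is precisely why the #MWUs-vs-#baseline *contrast* is
the informative comparison.

Confidence intervals are percentile bootstrap: resample the word index
with replacement (sample size n, 1,000 replicates), take the 2.5th and
97.5th percentiles of the replicate statistics. Replicates on which a
statistic is undefined are redrawn, capped at 10× the replicate count.
Percentile intervals for τ are mildly anticonservative (measured ≈ 89%
coverage at n = 200 against the 95% nominal level, with interval width
matching the true sampling SD); they are retained as the simplest
method consistent with the analysis design, and all inferential use
here is interval-exclusion-of-zero on large effects, not borderline
coverage. Coefficient comparisons use the *paired* bootstrap — one
index resample per replicate, both statistics evaluated on it — and by
convention compare magnitudes (|A| − |B|), the natural direction for
two negative correlations. No p-values are computed anywhere.

## Synthetic study conditions

The generator's defaults define the standard validation conditions:

* vocabulary 1,200 types: a 180-word template pool plus Zipf(s = 1)
  fillers, mirroring natural lexical skew (which keeps filler-transition
  BTPs low and diverse);
* 60 planted templates of length 3–4 drawn from the pool (pool words
  therefore differ in how many templates contain them, 0–4 typically);
  each utterance embeds one template with probability 0.5, padded with
  fillers. Template length defaults to 3–4 because a 2-token template in
  an L-token utterance survives a within-utterance shuffle with
  probability ≈ 1/L (0.5 in a two-word utterance), which would blunt the
  shuffle control; bigram templates remain available via configuration;
* 9,000 utterances per register; utterance lengths uniform on 1–8
  (child-directed-like) vs 1–12 (adult-directed-like), giving the
  shorter-CDS median contrast seen in real registers;
* latent facilitation score per word: 0.7·log(1 + freq) +
  1.2·n_templates + N(0, 0.6). Words with higher scores are introduced
  in earlier (lower-MLU) transcripts, and get faster RTs
  (750 ms − 30·score ms, truncated at 200 ms). Effects are additive on
  log frequency; since all analyses are rank-based, only monotonicity
  matters;
* 60 transcripts on an MLU axis from 1.5 to 6.0 tokens/utterance, with
  lognormal-skewed utterance counts (median 40–80) mimicking the uneven
  per-child data volumes of real acquisition corpora. Transcript tokens
  are drawn frequency-weighted from the words introduced so far, so
  rare words are attested late or never — a realistic detection
  confound that the partial correlations must cope with.

Under these conditions a study has ≈ 850–900 target words (the
four-way intersection of both corpora, the AoFP table and the RT
table). The null-calibration suite zeroes *both* effect coefficients
and runs at reduced scale (300-word vocabulary, 2,500 utterances, 40
transcripts, 50 replications) so that fifty full pipeline passes remain
fast; each pass still exercises corpus generation, chunking, AoFP
assignment and the bootstrapped partial correlation.

What passing these simulations shows: the chunker recovers planted
cohesive sequences and not order-destroyed ones; the measure/AoFP/
correlation pipeline recovers planted facilitatory effects with correct
signs, separates them from frequency, distinguishes structured from
random groupings, and does not invent effects under the null. What it
does not show: anything about real speech — the generator has no
grammar, no semantics, no register differences beyond length and
vocabulary, and filler transitions are independent draws rather than
syntactically constrained sequences. Results on real corpora depend on
properties the simulation does not model.

## Numerical and degenerate-input conventions

Threshold ties close units (strict `>`); tau on constant rankings and
partial tau with a ±1 control raise rather than return NaN; empty
corpora read without error but refuse summarisation; blank corpus lines
are skipped and counted; RT tables reject duplicates, non-positive and
non-numeric values with line numbers. All randomness flows from named
seeds — the pipeline's master seed fans out to (baseline chunker, MLU
bootstrap, correlation bootstrap) sub-seeds via a seed sequence, so any
component can be rerun in isolation and whole runs are bit-reproducible.

## Known limitations

* The tokeniser is whitespace-only and optionally case-folding; inputs
  are assumed pre-cleaned transcripts (no punctuation handling, and
  never any stemming, lemmatisation or tagging).
* The per-word-mean threshold variant scans the word's left-neighbour
  set per decision; it is intended for analysis at corpus scales where
  neighbour sets stay small, not for very large vocabularies.
* Percentile bootstrap slightly undercovers for τ (see above); BCa or
  studentised intervals would narrow the gap at added cost.
* AoFP is only as fine-grained as the transcript MLU axis: words first
  attested in the same transcript share an AoFP value, producing heavy
  ties that τ-b (but not Pearson/Spearman machinery) is designed for.
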