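# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `spokenword`, and what the synthetic test
worlds do and do not establish.

## Signal front end

Waveforms are mono PCM; 16 kHz is canonical and other rates are resampled
on read. Features are 13 mel-frequency cepstral coefficients per 25 ms
Hamming window, updated every 10 ms (100 frames/s), with pre-emphasis
0.97, a 26-filter triangular mel bank from 0 Hz to Nyquist, and cepstra
taken as the first 13 DCT-II (orthonormal) coefficients of the log
mel-band energies — so coefficient 0 carries overall energy. First and
second time derivatives are least-squares regression slopes over ±2
frames with replicated edges, giving 39 components per frame. All of
these are conventional speech-analysis settings and are overridable via
`FrontendConfig`.

Framing convention: frames start at the signal onset, the last partial
frame is zero-padded, so a signal of N samples yields
`1 + ceil((N − window)/step)` frames (99 for 1 s at 16 kHz). Frame *t*
(1-based) is reported at its centre, `12.5 + 10·(t−1)` ms.

Segment noise is white Gaussian added over `[start_ms, end_ms)` only,
scaled so the RMS power ratio of the original segment to the noise equals
the requested SNR over that interval exactly; samples outside are
untouched. Note that the 25 ms analysis window and the ±4-frame
derivative context smear a noise onset roughly 52 ms backwards in feature
space — activation traces of clean/noised twins are bit-identical only up
to that margin.

## Phone models and training

Each (left-context, phone, right-context) triple has its own three-state
strictly left-to-right Markov model: no skips, no backward transitions,
every state emits at least one frame, so the head–body–tail structure is
always traversed. State emissions are diagonal-covariance Gaussian
mixtures over the 39-dimensional feature space (1 component by default);
these densities are the model's spectro-temporal receptive fields, and
each state carries a global integer STRF index. Self-loop probabilities
absorb duration variation.

Training is hard-alignment (Viterbi) expectation–maximisation within
labelled phone segments: each iteration realigns every token through its
model, re-estimates state moments from the hard assignments (one EM step
for multi-component mixtures), and re-estimates self-loop/advance
probabilities from alignment counts (segment exit counts as an advance).
The per-iteration total alignment log-likelihood is non-decreasing; the
suite asserts this on every seeded run. Hard alignment was chosen over
forward–backward weighting because it is exactly checkable against an
exhaustive-enumeration oracle; the difference is negligible for the
well-separated synthetic worlds used here. Variances are floored at 1e-3
(normalized feature units) with a logged warning; flooring fires routinely
for derivative components on small training sets, where a short segment's
deltas are nearly constant.

Sharing keys never attested in training material can be backfilled from
context-independent pooled models (`ModelSet.with_backfilled_keys`),
pooling by unweighted parameter averaging across the phone's trained
context variants.

## Lexicon, cohorts, pseudo-words, priors

The cohort tree keys children by the full sharing-key triple, so two
entries share a node path exactly as far as their per-position
(left, phone, right) keys agree. Word stress is not represented.
Homophones share a path but remain distinct entries.

Phonotactic licensing is attested-bigram licensing including word-boundary
bigrams: a string is a possible pseudo-word iff every adjacent pair
(with boundaries) occurs in some lexical entry, and the string itself is
not an entry. This is the minimal corpus-derivable reading of
"phonotactically licensed".

Top-down support: a word's prior is its unigram relative frequency (or
N-gram probability given context, with back-off to unigram and a logged
warning for unknown contexts); a cohort's prior is the summed probability
of its completions, i.e. the total probability of becoming any of them; a
pseudo-word's prior is a stimulus-independent constant (`pseudo_prior`,
default 0.01). Class masses (default 0.5 word / 0.5 pseudo-word,
matching a fifty-fifty lexical-decision design) multiply the within-class
probabilities.

## Activation decoding

Activation is best-path (maximum) scoring, not forward summation: for
hypothesis *h* at frame *t*,
`activation = (bestpath(1..t) + λ·log prior(h)) / t`, the best path
ending in any state of *h*'s final phone, with λ (`lm_weight`, default
1.0) scaling top-down against bottom-up evidence and duration
normalisation by frames decoded. Best-path decomposes over the prefix
tree, which makes node scores computable by one dynamic program down the
tree and exactly checkable by alignment enumeration on tiny instances
(the suite verifies agreement to 1e-9).

A full word's trace at frame *t* is the running best over the nodes on
its own path, so the full form adopts its activation from its shorter
cohorts while they are still the best explanation of the input. A
consequence worth knowing: two words sharing a k-phone prefix have
bitwise-identical traces while every divergent (depth > k) node is either
infeasible (a depth-d node needs at least 3(d−1)+1 frames) or dominated,
but the best alignment may push into a divergent phone before the audio
gets there, so divergence can begin slightly earlier than the nominal
segment boundary.

Pseudo-word hypotheses are decoded by token passing over the phonotactic
network using context-independent pooled phone models (the right context
of a phone is undetermined while a pseudo-word is being hypothesised on
the fly). Tokens merge per (phone, state), keeping the best path, so the
per-frame best pseudo-word activation is exact; the trace exposes one
running best-pseudo hypothesis plus, at offset, the distinct end-licensed
complete pseudo-words. A pseudo path may traverse a lexical string — by
design, a real word also receives activation "as a pseudo-word", and only
the top-down term separates the classes — but complete paths equal to an
entry are never offered as pseudo-word candidates at offset.

Beam pruning keeps, at each frame, hypotheses within `beam` activation
units of the frame best; pruned hypotheses are never revived. A
hypothesis becomes prunable only once it is feasible (finite activation).
The default beam is infinite: the synthetic lexicons used here are small
enough that pruning is an efficiency device, not a necessity.

Nested-candidate removal drops a candidate iff its phone string is a
proper contiguous substring of another candidate's with activation at
least as high (ties keep the longer candidate).

## Decisions and reaction times

Identification: at each frame, word candidates are filtered by nested
removal and ranked; the best word wins at the earliest frame where it
leads the second-best by θ *and* is the unique maximum (so θ = 0 decides
at the first unique maximum, not at a tie). Ties at a crossing are broken
lexicographically by phone string, deterministically. Lexical decision
compares the best word-class activation against the best pseudo-class
activation; the absolute gap must reach θ_ld and the label follows the
sign of the gap. A `postpone_to_offset` flag forces lexical decisions to
stimulus offset, the strategy listeners adopt when many stimuli turn
non-word only at their final segments; with the flag set the offset
comparison decides and the choice component is always charged.

If no threshold is crossed by offset, the highest-activation candidate is
selected and the choice reaction time is
`hick_a + hick_b · H`, where H is the entropy in bits of the
softmax(activation/τ) distribution over the offset candidate set (words,
word parts and complete pseudo-words, after nested removal). The
softmax-with-temperature transform is this package's documented choice of
activation-to-probability map. Early decisions charge no choice
component: `rt_ms = decision_ms + choice_ms + exec_ms` always, with
`choice_ms = 0` iff the decision preceded offset.

Parameter defaults and rationale:

| parameter | default | units | rationale |
|---|---|---|---|
| θ, θ_ld | 8.0 | activation (nats/frame) | operating point on the per-frame log-likelihood scale: large enough that one frame of context-model mismatch rarely decides, small enough that clean well-separated stimuli are decided well before offset. Free, task-fit parameters in principle. |
| τ | 1.0 | activation | neutral temperature; H is invariant to adding constants to activations |
| hick_a, hick_b | 0 ms, 100 ms/bit | ms | placeholder choice-RT line; these are fit-to-data constants in any serious comparison with human RTs |
| exec_ms | 200 | ms | constant motor execution latency |
| word_class_prior | 0.5 | – | fifty-fifty word/pseudo-word design |
| pseudo_prior | 0.01 | – | flat, stimulus-independent pseudo support |
| lm_weight λ | 1.0 | – | equal balance of bottom-up and top-down; task-dependent in principle |

A consequence of the θ-gap rule worth knowing when interpreting
accuracies: words sharing their first phone are scored by *different*
context-dependent models from the first frame (their sharing keys
differ), so sampling noise in small training sets can produce a
spuriously large gap at frames 1–2 and a fast wrong commitment. This is
the speed side of the speed–accuracy trade-off, not a defect; the
offset-decision ceiling (θ → ∞) on the same worlds is measured by the
acceptance script. The model also shows a lexical bias in early lexical
decisions: word-frequency priors dominate the flat pseudo prior until the
acoustics diverge, producing fast "word" responses and slower, sometimes
postponed, "pseudo-word" responses.

## Synthetic worlds

The generator defines each phone by a smooth random log-energy profile
over the 26 mel bands, scaled by a `separation` parameter (0 = all phones
statistically identical; 4.0 is the default "well-separated" condition),
with per-state perturbations at a quarter of that scale giving
head–body–tail structure. Ground-truth emission means are the DCT of the
state profiles (derivatives zero); variances are 1.0 (statics) and 0.25
(derivatives); the true self-loop probability is 0.8 (mean dwell 5
frames). Waveforms are white noise filtered through an FIR approximation
of each state profile's spectral envelope, one third of the phone
duration per state, RMS-normalised, concatenated; per-phone durations are
uniform on [60, 160] ms. Lexicons are unique random phone strings with
Zipf-distributed frequencies (top count 1000, exponent `zipf_s`,
default 1). Trials draw words uniformly from the lexicon and pseudo-words
by random walk through the licensing network, with per-trial waveform
seeds.

What this emulates: stationary spectral targets per phone, duration
variation, frequency-skewed lexicons, phonotactically legal pseudo-words,
segment-localised noise at controlled SNR. What it does not: pitch and
voicing (the model is pitch-insensitive by design), coarticulation beyond
the context-dependent model inventory itself, speaker variation, prosody,
amplitude envelopes. Passing tests therefore show that the machinery is
correct and behaves qualitatively like the intended listener model on
controlled worlds; they do not show that accuracy or RT levels transfer
to natural speech.

## Problem sizes

The test suite and the acceptance script use deliberately small worlds:
6–10 phones, 2–20 words, 40–100 trials per experiment, 3–8 training
tokens per word, 800 tokens at the largest parameter-recovery point, and
exhaustive-oracle instances of at most 8 frames and 2 phones. These sizes
keep every brute-force oracle exact and the full pipeline fast while
exercising all code paths.

## Known limitations

- Best-path scoring and hard-EM are approximations to forward-probability
  scoring and full Baum–Welch; chosen for oracle-testability.
- The pseudo-word channel uses context-independent pooled models, so its
  bottom-up scores are slightly mismatched against context-dependent word
  models trained on the same material; the lexical-decision gap therefore
  carries a small systematic word-side component beyond the prior.
- Isolated stimuli only: no across-word continuous-speech decoding, no
  lexical feedback to the feature level.
- No fitting of θ, hick constants or λ to human datasets; defaults are
  operating points, and any quantitative RT comparison requires fitting
  them.
- Confidence bands around winning-hypothesis traces are not computed.
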