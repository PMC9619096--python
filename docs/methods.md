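# Methods

## Problem

Mandarin lexical tone is cued primarily by the F0 (pitch) contour of the
syllable, but amplitude contour and duration covary with F0 in natural
speech and can carry the tone on their own.  For cochlear-implant users,
whose devices transmit temporal envelopes well but pitch poorly, a score
on natural recordings conflates pitch ability with secondary-cue use.  The
package implements the cue-dissociation approach: resynthesize disyllables
so that the pitch contour and the loudness contour of the tone-bearing
syllable vary independently, score responses by the pitch-implied tone
only, and read secondary-cue reliance off the covarying-vs-conflicting
(Cov/Conf) score gap.

## Vocoder

`dsp.analyze` decomposes a waveform into (i) an F0 track, (ii) a binary
voicing segmentation, and (iii) a per-frame spectral envelope on a fixed
frequency grid; `dsp.resynthesize` renders audio from (ii)+(iii) under an
arbitrary target F0.  It is a sinusoidal+noise scheme, not a clone of any
specific vocoder: the contract is that duration round-trips exactly, that
voiced-frame F0 round-trips within 3%, and that an imposed linear contour
is realized within 5% at its endpoints.

- **F0 tracking**: normalized autocorrelation per 40 ms Hann frame, 5 ms
  step, search band 60–400 Hz (covers both speaker registers, 80–300 Hz),
  voicing threshold 0.45 on the autocorrelation peak.  Period ambiguity is
  resolved with a small octave cost (0.02 per octave of lag), frames whose
  local peak is under 3% of the global peak are gated as silence, and a
  continuity filter drops voiced frames that are isolated or jump more
  than 0.3 octave from the local voiced median (0.1 octave for the
  edge frames of a run).  Real intonation moves well under 0.05 octave per
  5 ms step, so the filter cannot clip genuine contours; what it removes
  is formant ringing in onset bursts and fade tails.
- **Envelope**: for voiced frames, harmonic amplitudes are measured at
  multiples of the frame F0 through the analysis window and interpolated
  across frequency, giving an envelope that can be resampled at the
  harmonics of any *new* F0; for unvoiced frames the windowed magnitude
  spectrum is stored directly.
- **Resynthesis**: voiced spans are rendered as a harmonic cosine bank
  with per-sample phase integration of the target F0 and amplitudes
  sampled from the envelope (harmonics above 95% of Nyquist dropped);
  unvoiced regions are white noise shaped by the frame envelope with
  power-calibrated overlap-add, seeded for reproducibility.  5 ms raised-
  cosine edges avoid clicks at voicing boundaries.
- **F0 target interpolation** is linear in Hz over time, anchored at the
  first and last voiced sample of the manipulated syllable; a log-Hz
  option is not needed for the shipped linear grids.
- **Gain contours** (`apply_gain_contour`) scale voiced samples by
  10^(g/20) with g linear in time from the first to the last voiced
  sample; unvoiced samples are untouched.  Gains in dB are additive, which
  the tests exploit as an exact closed-form check.

## Contour grids

Nine pitch contours per speaker (flat 3, rising 3, falling 3) and three
gain contours — (0, 0), (−10, +10), (+10, −10) dB — live in
`data/contours.json`.  Female: flats 300/250/200 Hz, rises 150→300/250/200,
falls 300→220/170/120.  Male: flats 200/170/130, rises 100→220/180/150,
falls 180→140/110/80.  The rise/fall triplets are read as a shared start
with three endpoints, matching the published register examples.  Contour
category maps to tone by flat→1, rising→2, falling→4 (the dipping Tone 3 is
excluded from the design because its contour cannot be realized as a
monotone linear ramp).

## Synthetic recordings

`fixtures.make_word_set` emulates the studio recordings the corpus builder
expects: each word is two syllables — a Rosenberg glottal pulse train with
a linear F0 glide through three formant resonators, an optional high-passed
(>2.5 kHz) noise-burst onset, an 80 ms silent gap.  The second syllable is
always Tone 1, flat at ≈250 Hz (female) or ≈170 Hz (male); the first
carries a rising or falling glide within the speaker's register (female
190–300 Hz, male 110–210 Hz).  Durations, vowels, and exact F0s are drawn
reproducibly from the seed.  The fixtures are speech-*like*, not Mandarin:
they have no phonetic identity, no coarticulation, no jitter/shimmer, and
only binary voicing.  Passing tests therefore demonstrate that the
manipulation and analysis machinery meets its contracts on controlled
input — not that resynthesized natural recordings would sound natural.

## Corpus construction

Every Tone-1 syllable of a word receives the same pitch spec per token
(both Tone-1 syllables of a double-Tone-1 word move together), then the
gain contour over its voiced span.  Non-Tone-1 syllables pass through
identity resynthesis so all syllables share processing artifacts; this
avoids a processed-vs-natural confound.  All tokens are RMS-normalized
(default target 0.05 full scale) so overall level carries no cue; duration
is untouched by construction.  The manifest records specs, congruence
labels (Cov iff pitch and loudness categories agree — exactly 1/3 of any
full grid), RMS, and the manipulated voiced spans used by the verification
helper `verify_token_f0`, which re-estimates F0, fits a line over the
voiced frames (trimming 25 ms at the edges, where estimates are biased),
and classifies the slope with a ±10 Hz/s dead zone.

## Experiment engine

270 Di tokens are shuffled into 6 blocks of 45 (3AFC over tones {1, 2, 4});
a 100-trial 4AFC block of abstract natural monosyllables (25 words × 4
tones) sits between blocks 3 and 4.  A response is correct iff it names
the pitch-implied tone; feedback follows that rule, which is what trains
listeners toward the pitch cue.  Session groupings: pairs {1,2}/{3,4}/{5,6}
for the training-effect contrast, sessions 3–6 pooled for headline scores,
and the Mono block split 34/33/33 (earlier parts take the remainder; the
split rule is our choice, the source design does not state one).

## Listener model

Response probabilities are a lapse-mixed softmax over the allowed tones
with evidence e_t = w_pitch·1[t = pitch tone] + w_loud·1[t = loudness tone];
for monosyllables both indicators point at the true tone (cues covary in
natural speech).  This is the simplest parametrization with the degrees of
freedom the Cov/Conf logic needs — pitch reliance, loudness reliance,
inattention — and is an explicit modeling extension: nothing here claims
humans combine conflicting cues additively.

Fitting maximizes the likelihood under a weak half-normal (σ = 3)
shrinkage prior on the weights, with the lapse bounded to [0, 0.5] and a
flat prior.  The prior is an identifiability device: at a few hundred
trials the raw likelihood has a ridge (very large, nearly equal weights
with lapse at its bound mimic moderate weights) that occasionally pulls
the MLE to the bounds; σ = 3 costs ~0.5 nats at w = 3 but ~22 nats at
w = 20, removing the ridge while leaving interior estimates essentially
unchanged.  With it, rank correlation between true and recovered pitch
weights across simulated listeners is ≈0.9 at 270 trials.

Cohort generators encode the two qualitative listener types: CI-like
listeners draw w_pitch ~ lognormal(median 1.3), w_loud ~ lognormal(median
1.0), lapse ≈ 0.05 — cue mixers whose Cov scores beat their Conf scores;
NH-like listeners draw w_pitch ~ lognormal(median 6), w_loud = 0, lapse
≈ 0.01 — near-ceiling pitch-only observers with no Cov/Conf gap.

## Statistics

Scores convert to d′ via the unbiased m-AFC observer,
P(c) = E_{y~N(0,1)}[Φ(y + d′)^{m−1}], computed with a 128-node
Gauss–Hermite rule (agrees with adaptive quadrature to ~1e−15) and
inverted by Brent root finding on d′ ∈ [−2, 8] to |ΔP| < 1e−7.  Observed
proportions at 1 or at/below chance are clamped by half a trial
(1 − 1/(2n), chance + 1/(2n)) and flagged; the source analyses do not
state their edge handling, so the flag keeps the correction visible.
Within-subject contrasts use Wilcoxon signed-rank, between-subject
rank-sum, families are Holm–Bonferroni corrected, and experience
correlations are Spearman with average-rank ties (all via scipy/
statsmodels behind the `analysis` interface).

## Problem sizes

The shipped defaults reproduce the published design exactly: 10 base
disyllables (5 per speaker), 270 tokens, 45-trial blocks, 17-listener
CI-like and 8-listener NH-like cohorts, 100 replicate cohorts for the
congruence contrast, 50 listeners for parameter recovery.  The full corpus
builds in a few seconds; the entire test suite runs in well under a
minute.

## Known limitations

- Binary voicing: no aperiodicity mixing within voiced frames, so breathy
  or creaky phonation is out of scope.
- The harmonic envelope is measured per frame from a 40 ms window; very
  fast formant transitions are smoothed.
- `verify_token_f0` assumes the manipulated span is voiced throughout; a
  recording whose Tone-1 syllable has an internal voicing break would need
  per-span verification.
- The listener model treats trials as independent (no learning within a
  session); training effects must be injected by varying parameters across
  session groups if needed.
- The Mono comparison set is abstract (id + tone); no natural monosyllable
  audio is modeled.
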