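# Methods

This note records the modelling choices behind `caseseq`: what each
component assumes, which parameters matter and why their defaults are what
they are, what the synthetic generator does and does not emulate, and the
numerical conventions.

## Problem setting and assumptions

A *case* is the sequence of reports d_0..d_n sharing one tumor ID, ordered
by report date. The package assumes (a) every report of a case carries the
case's aggregate labels — the registry convention — and (b) a case has at
least two reports, because single-report cases have no context to exploit
and are filtered out during case assembly. The concatenation mechanism
additionally *requires* shared labels and raises otherwise; the GRU,
attention, and CRF mechanisms would also work with per-report labels but are
only exercised here under the shared-label condition.

Two scenarios are modelled. Offline (bidirectional): all reports of a case
exist when any one is classified. Online (unidirectional): report i must be
classified using only reports 0..i. The online variants are *exactly*
causal — masked attention scores are set to −inf so excluded positions get
a softmax weight of exactly zero, the GRU runs forward only, and
previous-mode concatenation includes documents 0..i — and the test suite
asserts bitwise invariance of outputs under randomisation of future
reports. Previous-mode concatenation includes the target report itself;
excluding it would leave the first report of every case with no input.

## Components

**Encoders.** The word-level CNN embeds tokens (dimension d_w), convolves
with windows of 3, 4, and 5 consecutive words, applies ReLU, max-pools each
feature map over time, and concatenates the pooled maps into the document
embedding. The requested output dimension is distributed as evenly as
possible across the three windows, so any dimension is representable.
Documents shorter than the largest window are zero-padded to it. The
hierarchical self-attention encoder (HiSAN-lite) runs unmasked multihead
self-attention over the tokens of each line, pools each line with a learned
attention query, then repeats both steps over the line embeddings; it is a
compact member of the hierarchical-attention family, not a port of any
published configuration, and line structure comes from the 50-token
segmentation below. Both encoders are strictly per-document.

**Context mechanisms.** The GRU uses the standard two-gate recurrence with
h_{−1} = 0; bidirectional mode concatenates an independently parameterised
reversed pass (output dimension doubles, and the head's input dimension
follows). Self-attention computes Q, K, V as ELU-activated per-position
affine maps (window-1 1D convolutions) of X + P, where P is a learned
absolute positional table, randomly initialised. Scores are scaled by
√(d/h) per head by default; a config switch (`attn_scale="d"`) divides by
the full model dimension instead, for comparison with formulations that
print that scaling. There is a single context layer with no residual
connections or layer normalisation — the mechanism is deliberately the
minimal printed form. Head outputs are concatenated without an output
projection.

**Heads.** The softmax head is an affine map with log-space softmax. The
linear-chain CRF scores a label sequence as the sum of per-position
emissions (affine in o_i) and a learned K×K transition matrix over adjacent
labels; the partition function comes from the forward algorithm in
log-space, training maximises per-case log-likelihood (averaged per
report), and decoding is Viterbi with ties broken toward the lowest class
index. There are no start/stop transition scores: the first label is scored
by emission alone. Per-case normalisation is used (each case is one CRF
sequence). On shared-label data the learned transition matrix becomes
diagonally dominant — staying beats switching — which the acceptance suite
verifies with the mean-diagonal-minus-mean-off-diagonal statistic.

**Training regimes.** Modular: train encoder + temporary softmax head on
individual reports, freeze it, extract one embedding per report, train
context + head on the embedding sequences. The encoder's parameters are
bit-identical before and after step 2 (asserted in tests). End-to-end:
start from the pretrained encoder and fine-tune everything jointly, one
case per sequence, all of a batch's documents encoded in one flattened
pass. Case batches are padded to the longest case; padded positions are
excluded from the loss and unreachable as attention keys (the diagonal
stays open so no softmax row is ever empty). Early stopping monitors
validation accuracy per epoch, saves the best epoch's parameters, and stops
after `patience` consecutive epochs without improvement (improvement means
strictly greater). Cross-validation is not used; each run has one fixed
train/val/test split.

## Parameters and defaults

| parameter | default | rationale |
| --- | --- | --- |
| model dimension d | 300 | reference configuration for registry-scale corpora (GRU hidden 300, attention 300/6 heads) |
| attention heads h | 6 | d must be divisible by h |
| batch size | 64 | reference configuration |
| optimizer | Adam, lr 1e-4 | reference configuration; β and ε at common defaults |
| patience | 5 epochs | reference early-stopping rule |
| max epochs | 100 | a bound the reference setup leaves open; needed for bounded runs |
| vocabulary min_count | 5 | tokens seen fewer than 5 times corpus-wide collapse to `unknowntoken` |
| max case length | 64 reports | positional-table size; longer cases are truncated oldest-first with a warning |
| concat length cap | 20,000 tokens | concatenation with the hierarchical encoder is rejected above this estimate (its memory grows too fast with document length) |

The scaled-down experiments in `caseseq.experiments` (2,000 cases, 4
classes, d = 32, h = 4) use learning rate 1e-3 and an epoch cap of 40: the
corpus is two orders of magnitude smaller than a registry corpus, so an
epoch is ~80 optimizer steps rather than thousands, and the smaller rate
would spend the entire epoch budget barely moving. These are the package's
chosen study conditions for the synthetic experiments; `TrainConfig`
defaults are unchanged.

## Preprocessing

Cleaning is applied in a fixed order: strip XML tags; lowercase; tabs to
spaces keeping line breaks; drop the periods of "dr.", "am.", "pm."; replace
floats (digits.digits) with `floattoken`; replace standalone integers above
100 with `largeinttoken`; transliterate unicode to ASCII (unmappable
characters dropped); collapse consecutive repeats of the same
non-alphanumeric character; pad every non-whitespace non-alphanumeric
character with spaces; whitespace-tokenize. Integers embedded in
alphanumerics ("t2n0") are left alone. Identifier removal is schema-driven
(identifiers live in record fields, not text). Cleaning is idempotent on
ASCII text; unicode characters that transliterate into digits (superscripts,
vulgar fractions) can change token class on a second pass because integer
replacement precedes transliteration in the fixed order.

For the hierarchical encoder, documents split at natural line breaks; lines
longer than 50 tokens re-split after any of `. : ; / ? ~ * < #`; still-long
segments re-split after any standalone single letter except "a", comma,
hyphen, underscore, or equals; a segment with no break character is kept
whole. Vocabulary ids are assigned specials-first, then by descending count
with lexicographic tie-break, making construction deterministic.

## The synthetic generator

`generate_token_corpus` emulates the *statistics* that make case-level
context necessary, not clinical language. Case length is 2 + (Geometric − 1)
with mean 3.2 (matching the registry mean after singleton filtering);
report dates ascend within a case and span 2004–2016+, so the date-based
split (cases touching 2016 go to test, the rest 80:20 train/val at case
level) operates exactly as on real data. Each case draws one label per
task; each class owns two unique cue tokens. With probability
`addendum_rate` (default 0.3) a report is an addendum containing only
background text; every case keeps at least one evidence-bearing report.
With probability `cue_split_rate` (default 0.5) the class's two cue tokens
land in different reports of the case, distributing the evidence across the
sequence. Background text is Zipf-distributed over a 2,000-token vocabulary
so rare-token collapsing is exercised; cue tokens are frequent enough to
survive the vocabulary threshold.

Because either cue token alone identifies the class, the best possible
per-report accuracy is the *signal ceiling*
(1 − addendum_rate) + addendum_rate/K — addenda are pure noise to a
per-report classifier. (An earlier design where split cues were shared
between classes made split reports ambiguous; it was dropped because it
moves the per-report ceiling to a different quantity than the one the
experiments are designed around, and the addendum mechanism already
provides the context-dependence being studied.) Context models close the
gap by reading neighbours: bidirectional context can label every addendum,
while unidirectional context fails exactly on addenda with no preceding
evidence-bearing report — hence the strict ordering bidirectional >
unidirectional > baseline that the acceptance suite checks on three seeds.

What passing these tests does *not* show: robustness to real clinical
language (section structure, negation, abbreviation noise), to label noise
in registries, to the extreme class skew of 500+-class tasks, or to cases
whose reports genuinely disagree. `generate_embedding_sequences` skips
encoders entirely (Gaussian class centroids at fixed pairwise distance,
addenda at the origin) and is used to test context mechanisms in isolation.

## Numerical conventions

All tensor math is float64 on a reverse-mode autodiff engine written for
this package; gradients are verified against central finite differences.
Masking uses −inf (not a large negative number), so masked softmax weights
are exactly zero and causal invariance is bitwise. All CRF path
computations are in log-space. Max-pooling routes gradient to the first
argmax on ties. Evaluation: accuracy equals micro-F in this single-label
setting; macro-F averages per-class F1 over the classes present in the
evaluated split's ground truth, with zero-division components set to 0 (a
convention that keeps the average meaningful when a task's schema has
hundreds of classes absent from a split). Bootstrap intervals are
percentile (2.5/97.5 of 1000 resamples of report-level prediction-truth
pairs) — F-score is not normally distributed, so no normal approximation —
and a percentile interval may exclude the point estimate; the report flags
when it does. McNemar's test uses the exact two-sided binomial below 25
discordant pairs and the continuity-corrected chi-square above.

## Known limitations

- One context layer only; no stacked blocks, dropout, residuals, or layer
  normalisation in the context stage.
- The CRF has no start/stop potentials and first-order transitions only.
- The hierarchical encoder is a simplification; its standalone accuracy is
  not expected to match purpose-built published configurations.
- Word embeddings are learned from scratch during encoder pretraining; no
  pretrained vectors are downloaded or shipped.
- The engine is CPU-bound numpy: fine for the scaled study conditions used
  here, not intended for registry-scale corpora.
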