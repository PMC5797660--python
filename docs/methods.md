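# Methods

## The learning problem

An infant-like agent experiences a sequence of *situations*. In situation
*i* it hears an utterance U^i of d word tokens, sees a set o^i of up to
seven visible objects, and shares joint attention with the caregiver on one
of them, o_k^i. Choosing a word from the utterance as the hypothesized name
of the attended object is an *internal* action: it does not change the
environment, and the following utterance is whatever the caregiver says
next. The agent must aggregate evidence across many individually ambiguous
situations (cross-situational learning), helped by two social cues: joint
attention (which object the reward is about) and, optionally, pitch
prominence on the referent word.

## Reward

The reward follows the novel-name–nameless-category constraint: word
choices should track attended-object transitions. For consecutive
situations with attended objects (o, o′) and chosen words (a, a′),

    r = r_match     if (o = o′ and a = a′) or (o ≠ o′ and a ≠ a′)
    r = r_mismatch  otherwise.

Word equality is word-*type* equality in the shared vocabulary, not
utterance-position equality. Two magnitude conventions are supported:
`RewardConfig()` gives (100, −1), the scale used by the tabular training
loops, and `RewardConfig.unit()` gives (+1, −1), the scale of the
single-transition analysis. Only the ordering matters for greedy behaviour;
the magnitude matters a great deal for the neural learners (see
*Calibration* below). The first situation of an episode has no predecessor
and yields no reward, so an episode over P situations produces P−1
transitions.

## State encodings

Both encodings are length-N vectors over the vocabulary (N grows with first
occurrence across the corpus):

* **binary** — 1 at each word occurring in the utterance;
* **prosodic** — at each occurring word, the difference between the 75th
  percentile of the word's pitch and of the whole utterance (Hz), zero
  elsewhere. Percentiles use linear interpolation between order statistics.
  A word occurring twice with different values keeps the maximum, since
  prominence is the signal of interest.

## Learners

**Tabular (Q-learning, SARSA, SARSA-λ).** The value table is P×N
(situations × words). Actions are restricted to the current utterance's
word types; bootstrap maxima and next-action choices are restricted to the
*next* utterance's word types. ε is held fixed (default 0.99). SARSA-λ uses
replacing traces: the TD error is computed once, the current pair's trace
is set to 1, all traced entries move by αδe, and traces decay by γλ. Only
nonzero traces are touched, which makes λ=0 reproduce plain SARSA bit for
bit on the same seeded trajectory. Greedy ties break toward the lowest word
index, for determinism.

**Neural (Q-NN, NFQ, DQN).** A four-layer perceptron N→H→H→N with sigmoid
hidden activations and a softmax output head maps the utterance vector to
one value per vocabulary word; the softmax concentrates value on one word
per utterance. Only the chosen action's output enters the squared-error
loss; the other outputs receive gradient through the softmax coupling.
Q-NN takes one gradient step per situation on the newest transition. NFQ
stores the most recent J transitions and regresses once per situation on
the whole store. DQN samples a minibatch from the replay memory, bootstraps
on a target copy of the network synced every C gradient steps (by default
the target-network maximum over the next utterance's candidates; a strict
double-estimation variant — online argmax, target evaluation — sits behind
`double_dqn`). ε anneals linearly from 0.99 to 0.0001 across the configured
episodes and is clamped thereafter. Exploration (both arms of ε-greedy) is
masked to the current utterance's words.

## The word–object matrix and lexicon readout

During training, every visit to a situation folds the current value row —
masked to the utterance's word types, zero elsewhere — into the attended
object's row of the M×N matrix QW as a running mean. Masking keeps each
word's QW column supported on the situations where the word was actually
heard; without it, softmax-suppressed words would contribute only noise and
the readout degrades badly (referent recovery dropped from 1.00 to ~0.30 in
our ablation at the default synthetic scale).

Readout: each object row is divided by its own maximum (all-zero rows stay
zero); a word's referent is the argmax of its normalized column over
objects (lowest object index on ties); a lexicon at threshold t is every
pair with normalized value ≥ t; precision/recall/F are computed over
*pairs* against the gold lexicon, and a sweep over a 0:0.01:1 grid reports
the best-F point (lowest threshold on ties). The co-occurrence baseline
(COOC) counts situations where the word was heard while the object was
attended (optionally: visible) and feeds the same readout.

## Calibration of reward scale and step size

The softmax head bounds every output to (0, 1). Against that range, a +100
regression target produces a match-side gradient about 100× the mismatch
side, so the −1 penalty never bites: every chosen word is pushed up and
token frequency dominates the learned mass. With unit rewards the two sides
are comparable and the penalty shapes the policy. Since the gradient of the
squared error scales with the target, the paper-scale step α=0.001 paired
with ±100 rewards and the step α=0.1 paired with ±1 rewards apply the same
effective update magnitude; the package therefore uses the unit calibration
for experiments that depend on value *contrast* (threshold-based lexicon
extraction), while referent selection — which rests on the masked
co-occurrence structure of QW — is robust under either convention.

## Key parameters

| parameter | default | role |
|---|---|---|
| α | 0.001 (tabular/neural) | TD / gradient step size |
| γ | 0.99 | discount |
| ε | 0.99 fixed (tabular); 0.99→0.0001 linear (neural) | exploration |
| λ | 0.9 | SARSA-λ trace decay |
| H | 200 | hidden units per layer |
| J | 50 | replay / store capacity |
| minibatch | 10 | DQN batch size |
| C | 4 | target-sync period (gradient steps) |
| init_scale | 0.01 | half-range of uniform weight init |
| r_match, r_mismatch | 100, −1 | reward magnitudes |

At init_scale 0.01 the two sigmoid layers squash the input's influence to
~1e−7 at the output, so early training moves mainly through output biases;
larger scales (±0.5) give input-sensitive networks from the start and are
used where policy learning itself is under test.

## Synthetic corpora

The generator emulates the structure of transcribed caregiver–infant play:
M objects, a planted lexicon assigning each of the referent words to
exactly one object (round-robin, so objects may have several names), 1 to
max_visible visible objects per situation with one attended uniformly, and
utterances of 2–6 tokens. With probability p_referent_word (default 0.7)
one of the attended object's names is inserted at a random position;
remaining tokens are Zipf-skewed fillers (exponent 1.0, mimicking frequent
function words) or, with probability 0.1 each, a name of some *other*
object. `GeneratorConfig.hard_mode()` lowers the naming rate to the 23%
observed in real interaction data. With prosody on, referent positions draw
pitch-prominence values from Normal(30, 5) Hz and all others from
Normal(0, 10) Hz.

What the generator does **not** emulate: utterance syntax and word order
statistics, multi-word names, verbs and function-word semantics beyond
frequency, attention annotation noise (available as an option, off by
default), and the long-tailed utterance-length distribution of real
speech. Tests passing on these corpora show that the learning machinery
extracts planted cross-situational structure; they do not certify
performance on transcribed recordings.

## Problem sizes used by the test suite

Chosen so the full suite runs on a single CPU at desk scale:

* referent recovery: 17 objects, 37 names, 380 fillers, 600 situations,
  ≤4 distractors, naming rate 0.7; DQN H=200, J=50, minibatch 10, C=4,
  300 episodes (paper-scale rewards, α=0.001, init ±0.01) — recovery 1.00,
  threshold 0.90 in the test;
* prosodic vs binary: 8 objects, 16 names, 120 fillers, 250 situations;
  DQN H=64, 60 episodes, unit calibration, 5 seeds — median best-F
  prosodic 0.167 vs binary 0.083;
* micro-MDP: 2 objects/2 names/40 situations, 500 episodes, all three
  tabular learners, default α.

## Numerical choices

* Sigmoid computed in the numerically stable split form; softmax shifted by
  the row max.
* Gradients are exact (verified against central finite differences at
  1e−5 relative on H=5/N=8 networks, every parameter tensor).
* Q-tables initialize uniform [0, 1) under the run seed; network weights
  uniform ±init_scale.
* All randomness flows through one `numpy` Generator per run, so every
  trainer is bit-reproducible given (corpus, config, seed).
* Degenerate inputs: empty utterances are rejected at construction; empty
  candidate sets raise; an underfull DQN replay buffer skips the update;
  an all-zero QW row normalizes to zeros; an empty lexicon scores 0/0/0.

## Known limitations

* Pair-level best-F on synthetic corpora at desk scale is modest: running
  means accumulate from episode 1, so early high-entropy mass dilutes late
  structure, and very frequent fillers compete with names inside each
  object row. Referent selection (per-word argmax) is the robust readout.
* The value function saturates near the softmax bound, so learned values
  separate matched from mismatched choices but carry little resolution
  beyond that.
* One attended object per situation, assumed correct; attention noise is
  modelled only as an optional mis-attention probability.
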