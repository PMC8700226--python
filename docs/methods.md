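# Methods

## Problem and pipeline

Neighbourhood food-environment research needs takeaway ("fast-") food
outlets disaggregated by cuisine type, but outlet registers only carry a
business name. This package implements an automatic cuisine classifier
that works from the business name alone, together with the data
preparation, evaluation and aggregation stages that surround it:

1. **Cleaning** — names are transliterated to lower-case ASCII (NFKD
   decomposition maps accented latin characters to their base letter;
   symbols with no equivalent are dropped), whitespace is collapsed.
2. **Deduplication** — chain branches are listed as the chain name plus a
   location ("roosters piri piri - stockwell", "tops pizza
   (trumpington)"); a single trailing hyphen- or bracket-delimited suffix
   is stripped, records are grouped by base name (a configurable known-
   chain list groups chains regardless of suffix), and one record per
   group is kept. Without this step the same name could sit in both
   training and validation. Owner labels can differ across branches: the
   two most frequent labels across the group are retained, ties broken
   alphabetically. A singleton group keeps its own label order, since
   every count is 1 and the tie rule would arbitrarily scramble the
   owner's ranking.
3. **Rule labelling** — one cuisine class per outlet from a 10-point
   scheme (chicken, kebab, pizza, burger, multi fast food, desserts,
   sandwich/café/bakery, fish and chips, South Asian, Southeast & East
   Asian), assigned by a priority cascade: known chain base name → its
   class; two or more of the name keywords chicken/kebab/pizza/burger →
   multi fast food; exactly one keyword → that class; otherwise the first
   owner label that maps to a class. "Halal" is ignored (it is a
   descriptor, not a cuisine); labels of cuisines too rare to train on
   are excluded. Keyword matching is whole-word by default ("kebabish"
   does not match "kebab"); a scheme switch enables substring matching.
   A six-point variant collapses the four fast-food classes and multi
   fast food into a single class.
4. **Split and balance** — a fixed validation sample per class is drawn
   without replacement; the remaining training names are resampled with
   replacement until every class holds exactly the balance target
   (classes above the target are resampled down to it, so all classes
   end exactly equal).
5. **Character LM classifier** — see below.
6. **Evaluation** — confusion matrix (rows = actual, columns =
   predicted), per-class and macro recall/precision, qualitative
   sensitivity bands.
7. **Aggregation** — per-area counts by cuisine, rates per 100,000
   residents, rate quintiles, and across-area descriptive statistics.

## The character-level model

Business names are short (one to a few words) and their word vocabulary
is sparse, so the classifier operates on characters. Training follows
the universal language-model fine-tuning pattern:

* **Language model.** A stacked LSTM over character embeddings is
  trained with a next-character cross-entropy objective on the entire
  name corpus (labelled or not). Sequences are `<bos> c1 … cn <eos>`;
  spaces and punctuation are ordinary tokens because word boundaries and
  marks like apostrophes carry signal.
* **Classifier.** The trained encoder receives a concat-pooled softmax
  head (last hidden state, max-pool and mean-pool over valid timesteps)
  and is fine-tuned on the balanced training set. Early stopping
  monitors validation accuracy with a configurable patience (default 3
  epochs); the returned model is the checkpoint of the best epoch.
  Optional slanted-triangular learning rates and gradual unfreezing
  (head only → head + top LSTM layer → everything) are available but off
  by default, favouring simple, reproducible runs.
* **Prediction.** Softmax over classes; the reported confidence is the
  maximum class probability.

General-corpus pretraining is intentionally not performed: the corpus
language model is the load-bearing stage for a character-level task, and
the encoder can be warm-started from any previously saved state where
transfer is wanted.

The network is implemented directly in NumPy (embedding, stacked LSTM
with full backpropagation through time, Adam, global-norm gradient
clipping at 5, inverted dropout between layers). Names are tens of
characters long, so sequences are processed without truncation and
training runs comfortably on one CPU core. All randomness flows from a
single integer seed through `numpy.random.Generator`, making runs
bit-reproducible.

### Default hyperparameters

| parameter | default | rationale |
| --- | --- | --- |
| embedding dim | 32 | character inventory is tiny (~30–40 symbols) |
| hidden dim | 128 | enough capacity for affix/word cues at CPU cost |
| layers | 2 | matches the small-corpus regime; 1 is fine for toy data |
| dropout | 0.2 | light regularisation on small corpora |
| batch size | 64 | CPU-friendly BLAS shapes |
| learning rate | 3e-3 (Adam) | stable across the test corpora |
| LM epochs | 2–4 | the corpus LM converges quickly on short names |
| fine-tune epochs | ≤ 8–15, patience 3 | early stopping does the real work |

## The naive baseline

The comparison model scores each word by its relative frequency within
each class's names (so class size does not dominate); a name's class
score is the sum of its words' scores and the argmax wins. Words
occurring in at least `stopword_fraction` of classes (default: all of
them) are stopwords, seeded with "and" and "takeaway". Ties — including
names made only of unseen words — go to the alphabetically first tied
class, a documented, auditable policy.

## The synthetic corpus generator

The real training data (owner-labelled listings from an online ordering
platform) cannot be redistributed, so the generator emulates its
structure with known ground truth. Word pools are pronounceable
syllable-built words generated under a fixed internal seed: 8 signal
words per class, 120 generic shared words (240 in subword mode), 24
place names, and one 3-letter class affix built from letters absent from
the syllable alphabet. Each base record draws 1–5 words; each word comes
from its class pool with probability `signal_strength`, otherwise from
the shared pool. Owner label 1 equals the true class except with
probability `label_noise`; a second random label appears on 40% of
records and a third "halal" label on 20% of those, mirroring the
platform's labelling habits. A base record becomes a chain (2–5 replicas
named " - place" or "(place)", replacing the base) with probability
`chain_rate`; emitted records are exactly duplicated with probability
`duplicate_rate`; accented variants of letters are injected at
`nonascii_rate` (from an RNG stream independent of corpus structure, so
the accent rate never changes which names are generated).

Three named conditions pin down the corpora used by the tests and the
acceptance script:

* **separable** — `signal_strength=1`, `label_noise=0`, disjoint class
  vocabularies: every name identifies its class, so a working classifier
  must score highly (the tests require macro recall ≥ 0.90).
* **zero-signal** — `signal_strength=0`: names carry no class
  information, so validation accuracy must stay inside the 99% binomial
  band around 1/K. Together with the separable condition this brackets
  the classifier from both sides.
* **subword** — the class signal is the 3-letter affix implanted at a
  random position inside one otherwise generic word per name
  (probability 0.9). With 240 shared words and ~7 insertion points per
  word, most affixed word *forms* in validation were never seen in
  training, so whole-word scoring degrades towards chance while a
  character model reads the affix directly — reproducing the qualitative
  ordering in which the learned classifier beats the word-score
  baseline. The affix is implanted in at most one word per name
  precisely to keep the form inventory large relative to the training
  set; implanting into every word would let the baseline memorise forms.

What the generator does **not** emulate: real-world class imbalance
beyond what `n_per_class` is set to, genuine brand names or place names,
semantic overlap between cuisines (e.g. shared "grill"/"peri peri"
vocabulary with class-dependent frequencies), or mislabelled chains.
Passing tests therefore demonstrate that the machinery is correct and
that the model can exploit whole-word and subword signal when present —
not that any particular accuracy will be reached on real listings.

## Evaluation conventions

* Confusion-matrix rows index the actual class and columns the
  predicted class, so each validation row sums to the per-class
  validation count. (Descriptions of this orientation vary; the
  row-totals-equal-class-size reading is adopted and used consistently.)
* "Overall" recall and precision are macro averages — unweighted means
  across classes. A class with no actual records (or never predicted)
  has undefined recall (precision), reported as NaN, excluded from the
  macro with a warning.
* Sensitivity bands follow published cut-offs (<20% very poor, 21–30%
  poor, 31–50% fair, 51–70% moderate, 71–90% good, >90% excellent).
  The printed ranges leave the integer boundaries ambiguous, so values
  are banded on half-open intervals at the midpoints (0.205, 0.305,
  0.505, 0.705, 0.905), which reproduces the printed label for every
  whole-percent value.

## Aggregation conventions

Rates are `count / population × 100,000`. Quintiles rank areas by rate
ascending with stable tie-breaking on area code, then cut the ranking
into five contiguous groups whose sizes differ by at most one (Q5 =
highest rates). Median and IQR use linear interpolation between order
statistics. Outlets are assumed pre-filtered to takeaways; identifying
takeaways among all food businesses is upstream of this package.

## Numerical and degenerate-input choices

* Ties in the naive baseline and in quintile ranking are broken
  alphabetically / by area code — deterministic and logged.
* A name that normalises to the empty string is flagged and excluded
  downstream with a warning rather than propagated.
* Unknown characters at prediction time map to an `<unk>` token; unknown
  owner labels are excluded with a logged warning.
* Probability distributions are validated to sum to 1 within 1e-6.
* Exact duplicates whose two labels tie 2–2 can have their label order
  swapped by the alphabetical rule; on the separable corpus this
  introduces ≲0.5% label noise, which the classifier thresholds absorb.

## Problem sizes

The canonical corpora use 10 classes × 500 base records, 100 validation
names per class and a balance target of 400 — large enough for the
classifier to separate the separable condition cleanly (macro recall
≥ 0.99 in practice) while keeping a full pipeline run to a few minutes
on one CPU core. The published study the pipeline mirrors used 400
validation names per class and a 4,000-name balance target; the split
module reproduces that arithmetic exactly in its tests.

## Known limitations

* The shipped owner-label map covers only commonly seen labels; real
  deployments should extend it via the scheme YAML (the full label
  inventory of any given platform is site-specific).
* No fuzzy duplicate detection: "burger king" and "burger king ltd" are
  different base names unless listed as a known chain.
* Single-label prediction only; outlets genuinely spanning cuisines are
  forced into one class.
* The NumPy LSTM is sized for corpora of tens of thousands of short
  names on CPU; it is not a general-purpose deep-learning stack.
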