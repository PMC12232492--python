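# Methods

## Task and representations

The package extracts mentions of 15 patient-derived cancer model (PDCM)
entity types (diagnosis, age_category, genetic_effect, model_type,
molecular_char, biomarker, treatment, response_to_treatment, sample_type,
tumor_type, cancer_grade, cancer_stage, clinical_trial, host_strain,
model_id) from abstract text. A mention is a half-open character interval
[start, end) with a type and its surface string; the surface string is
stored redundantly and validated against the text, which catches offset
drift at I/O boundaries. Same-type mentions may not overlap; cross-type
overlaps (biomarker "MEK" inside treatment "MEK inhibitor") are legal in
the standoff representation.

Abstracts are segmented into sentences by a rule-based splitter (terminal
`.!?` followed by whitespace and an uppercase letter or digit, with an
abbreviation list), and all downstream processing is per sentence.
Mentions that cross a sentence boundary are dropped with a warning; the
synthetic generator never produces them.

## Direct prompting

Extraction is cast as constrained generation: the prompt is an
instruction, the 15 type definitions, k few-shot examples (default 5) of
sentence → inline-tagged sentence, and the query sentence. The model is
expected to echo the sentence with `<type>…</type>` tags. Character
offsets are *never* requested from the model — word-piece tokenization
makes models unreliable at character counting — but recovered by
post-processing: the completion is de-tagged and aligned to the source
sentence by a character-level longest-common-subsequence alignment
(quadratic dynamic programming, vectorized along the source axis). Each
tagged region is mapped through the alignment; regions whose characters
align with identity below a threshold (default 0.8, configurable) are
treated as hallucinations and discarded with a diagnostic, as are
unknown tag names (reported, never guessed). Parsing never raises on
malformed output. This design makes the parser exactly as strong as the
alignment: a tagged region survives word substitutions and insertions
anywhere else in the sentence, and survives edits inside the region up to
the identity threshold.

Providers are a one-method text-in/text-out contract. The bundled
providers are mocks (gold oracle, noise-corrupted oracle, silent); real
API clients can implement the same contract but are out of scope.

## Soft prompting (prompt tuning)

Token classification over the BIO scheme: 15 types × {B, I} + O = 31
labels. Encoding places B on a mention's first token and I on the rest;
decoding is lenient (an orphan I opens a mention; malformed sequences
never fail), so any label sequence maps to a valid mention set. Mention
boundaries falling inside a token are expanded outward (recall
preserving). A single BIO sequence cannot carry cross-type overlapping
mentions; the longer mention is kept for encoding and the inner one
dropped (standoff gold keeps both).

The trainable state is a soft prompt P ∈ R^{L×d} (default L = 30)
prepended to the embedded input, plus a linear head W ∈ R^{h×31}, b ∈
R^{31} over the backbone's final hidden states — exactly L·d + (h+1)·31
parameters (1,983 with the bundled backbone). The backbone is frozen: its
parameter fingerprint is asserted unchanged every epoch, and the backward
pass computes gradients with respect to the *inputs* only. Prompt rows
are initialized from the backbone embeddings of the 15 type names (first
word piece); remaining rows are copies of random embedding-table rows;
the head is small-Gaussian initialized. Training minimizes token-level
cross-entropy with Adam at learning rate 0.001 for 50 epochs (defaults),
one sentence per update step; the checkpoint with the best dev micro-F1
in overlapping-match mode is returned. Per-sentence updates are
deliberate: at a fixed 50-epoch budget on corpora of a few hundred
sentences, batched updates leave too few optimizer steps to converge.
Where the protocol is silent (optimizer family, batch size, checkpoint
selection, word-piece pooling) these are package decisions; prediction is
a deterministic argmax with ties broken to the lowest label id, i.e. O.

## The backbone fixture

No deep-learning framework is assumed: the bundled backbone is a small
causal transformer (2 pre-norm blocks, width 32, 4·width MLP, sinusoidal
positions, ~156k parameters) written in numpy with an explicit backward
pass, gradient-checked against finite differences in the test suite.
Tokenization is word-level (words and punctuation with exact offsets) and
vocabulary ids are stable content hashes of the lowercased token (default
vocabulary 4,096, verified collision-free over the generator vocabulary),
so the fixture needs no vocabulary file and is bit-reproducible from its
seed across processes. Real LLM backbones attach through the same
contract (embed, encode, input-gradient, tokenize-with-offsets,
fingerprint); with them, words split into multiple pieces and the
first-piece convention represents the word.

## Evaluation

Matching is per type and one-to-one. Exact mode requires identical
boundaries; overlapping mode requires ≥1 shared character on half-open
intervals (touching spans do not match). The matcher is greedy:
predictions in (end, start) order each take the unmatched compatible gold
with the smallest end, which attains the maximum matching for interval
compatibility; the test suite verifies equality with an exhaustive
maximum-matching oracle on thousands of random instances. P, R and F1
are on the 0–100 scale with the 0/0 → 0 convention (relevant for types
with no test instances), rounded to 2 decimals only for display.
Overlapping-mode F1 always dominates exact-mode F1.

Inter-annotator agreement is the unweighted mean over annotator pairs of
exact-match F1 (symmetric under role swap), micro-averaged per pair
across the corpus. Cross-validation aggregation reports mean and sample
SD (n−1) per cell.

## Synthetic data

The generator emits templated sentences — an opener, 1–3 lexicon
surfaces joined by connectors, an optional tail — with exact planted
offsets and a ledger of per-type counts that equals the corpus statistics
by construction. Type frequencies default to the released gold corpus'
skewed profile (biomarker 784 … cancer_grade 8 of 3,313), so rare-type
behavior is exercised. The default lexicon is curated so that every word
carries exactly one BIO label across lexicon and carrier text: a
majority-vote lexicon solves the task perfectly, which is what makes the
soft-prompt learning criterion meaningful (a trained classifier must
solve a task that is solvable). `overlap_rate` plants nested
biomarker-in-treatment pairs; it defaults to 0 because nested pairs are
deliberately unrepresentable in single-sequence encodings and would break
the oracle round-trip closures.

Annotator noise drops, adds, type-confuses and boundary-jitters
mentions. Jittered spans are clamped to keep ≥1 character of the source
span and to stay inside the host sentence, so jitter-only noise degrades
exact-match scores while leaving overlapping-match agreement at 100 —
the property that separates the two evaluation settings in testing.

What the generator does **not** emulate: real scientific discourse,
contextually ambiguous mentions (the same word as biomarker in one
sentence and treatment in another), enumeration-style biomarker lists,
or annotator biases correlated across documents. Passing tests
demonstrate the pipeline's mechanics (offset bookkeeping, round trips,
optimization, protocol orchestration), not expected accuracy on real
abstracts.

## Problem sizes and numerics

Default study sizes: 50-document corpora (6 sentences each, 300
sentences) for end-to-end runs; 10 documents held out as dev; learning
curves over fractions {5%, 25%, 50%, 100%} of the 40 training abstracts
with 2 subsampling seeds, training with full defaults at every point;
property suites use 1,000 random instances. All randomness flows from
explicit integer seeds; training and generation are bit-reproducible on
CPU. Degenerate inputs have fixed conventions: empty mention sets are
valid everywhere, 0/0 scores are 0, empty model output flags the
sentence and contributes no mentions, sequences beyond the backbone
context are truncated with a warning.

## Known limitations

- The LCS alignment is quadratic in sentence length; fine for abstracts,
  not for full-text sections.
- Lenient BIO decoding and outward boundary expansion favor recall;
  precision-oriented applications may want strict decoding.
- The bundled backbone is a fixture for correctness and protocol work,
  not a language model; absolute scores on real text are meaningless
  until a real backbone implements the contract.
- Discontinuous and cross-sentence mentions are rejected by design.
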