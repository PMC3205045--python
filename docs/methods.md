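# Methods

This note documents the models implemented in `chemtagger`, the defaults and
why they were chosen, the numerical details, and what the synthetic fixtures
do and do not demonstrate.

## Document model and offsets

All annotations are standoff. Offsets are 0-based, half-open *code point*
offsets into the NFC-normalised source text, chosen over byte or UTF-16
offsets because Python string slicing makes the invariant
`text[start:end] == surface` directly testable. Paragraph-level token
sequences carry document-level offsets (paragraph offset + local offset);
source text is never mutated. Subscript digits (`C₂H₆O`) are mapped to ASCII
only in a parallel classifier surface, never in offsets.

## Tokeniser

Whitespace-delimited units are refined by three rules, applied recursively:

1. **Edge punctuation** (`. , ; : ! ? " ' ( ) [ ] { }`) is peeled into
   separate tokens. A trailing period survives when the remainder is a known
   abbreviation (packaged, editable list: `Fig.`, `calcd.`, `e.g.` …) or a
   single letter.
2. **Brackets** are peeled only when the remainder stays bracket-balanced;
   a matched enclosing pair is peeled together. Hence `(42)` → `( 42 )` but
   `(S)-ibuprofen` and `1-(chlorophenyl)` stay whole.
3. **Hyphens** are internal by default (`C-H`, `NSC-2648`,
   `2,5-dichlorobenzylamine` stay single tokens); a unit splits into
   head/`-`/suffix only when the text after the hyphen is one of the generic
   suffixes `based, containing, free, rich, dependent, induced, mediated,
   derived, treated` (configurable). The rationale is that downstream
   recognisers need formulae, serial numbers and locant-prefixed names as
   single tokens, while `water-based` is two lexical words.

Paragraphs are maximal runs separated by blank lines; no sentence splitting
is performed (no recogniser here needs it).

## N-gram naïve Bayes classifier

Training words are case-folded, subscript-normalised, and digits are
collapsed to `0` so the model responds to token shape. Each word is padded
with n−1 leading `^` and one `$`; every length-n window is counted per
class. Defaults: n = 4, additive smoothing α = 1 with a shared
unseen-bucket vocabulary (V = distinct n-grams in either class + 1), prior
π = 0.5. The score is the summed log-likelihood ratio of windows;
probability is the logistic transform offset by the prior log-odds. This is
the simplest scheme that satisfies two structural properties used as tests:
swapping the word lists negates every score, and scores match a direct-count
oracle exactly. The prior is exposed because corpus-frequency priors are a
legitimate alternative.

## Pattern recogniser

Tokens with chemical probability ≥ 0.5 (configurable) and at least one
letter are marked chemical; maximal runs of chemical tokens are scanned
left-to-right against glob patterns (`*` = any character run, case-folded,
whole-token anchored). The longest leftmost match becomes a multi-token CM
entity; leftover chemical tokens are emitted singly. Longest-leftmost
tie-breaking is the standard deterministic choice for lexical matchers.
Entity confidence is the geometric mean of member token probabilities —
a simple length-normalised aggregate that stays in [0, 1].

## MEMM recogniser

Labels: per-class B/I plus O for the four classes CM, RN, CJ, ASE
(9 labels), the minimal scheme that reconstructs typed multi-token spans.
A single conditional maximum-entropy model scores
P(label | previous label, features); the previous label enters as an
indicator feature, so learned weights form (previous label, label) pairs as
in a classic MEMM.

Feature templates (version-tagged `ct-memm-v1`): exact and case-folded
surface, compressed word shape (`C-H` → `A-A`), prefixes/suffixes of length
1–4, character trigrams of the padded surface, the n-gram chemical
probability quantised into deciles, a punctuation flag, and the same items
for the two neighbouring tokens under `prev:`/`next:` prefixes (BOS/EOS at
boundaries), plus a bias. Decoding refuses models whose template version
does not match the code.

Training minimises the L2-regularised negative conditional log-likelihood
(default λ = 1.0, max 200 L-BFGS iterations) with analytic gradients; the
objective is convex, and the recorded per-iterate objective is checked to be
non-increasing. Previous-label contexts during training are the gold labels.

Decoding is Viterbi under the hard constraint that I-t follows only B-t or
I-t (invalid transitions get zero weight; path weights are otherwise
products of the locally normalised conditionals). Entity confidence is the
probability that a valid label path realises *exactly* the emitted span:
labels clamped to B-t/I-t inside the span and the following position barred
from I-t, divided by the total weight of all valid paths, both computed by
forward passes in log space. This definition is checked against exhaustive
enumeration over all 9^L paths for short sequences. The label-bias property
of locally normalised models is inherited by design and not mitigated.

## Lexicon stages

- **Serial-number regex**: whole-token `fullmatch`, default
  `[A-Z]{2,4}-\d+`, configurable pattern and entity type, confidence 1.
- **Ontology lookup**: terms are normalised (case-fold, single-space);
  matching is token-aligned, longest-leftmost, and returns every identifier
  registered for the term. Token alignment avoids mid-token matches and
  keeps offsets sane. Term tables load from `term<TAB>id` TSV; a ~100-term
  synthetic fixture ships in-repo (real ontology term lists are a file
  format, not a bundled dataset).
- **Prefix automaton**: accepts one or more locant components — digit runs,
  Greek letter names and symbols, R/S/E/Z, cis/trans, o/m/p, N/O/S —
  separated by commas and terminated by a hyphen. The grammar ships as JSON
  so users can extend it (e.g. `tert`, primes). Matching walks a shared
  component trie with online determinisation, linear in token length;
  because the hyphen is the sole terminator, the first acceptance is the
  longest. Equivalence with a reference regex is asserted on random strings.

## Resolution

Lookup normalisation is case-fold plus whitespace collapse. Dictionaries
are consulted in registry order; structures are concatenated in that order
and deduplicated by (format, value) — so permuting the registry permutes
structure order but never changes the resolved/unresolved verdict. The
fallback hook runs only when every dictionary misses; it is the integration
point for an external systematic-nomenclature parser, kept as a hook rather
than a dependency. Unresolvable entities are represented by absence, never
by empty structure lists.

## Experimental-data checker

The grammars are a journal-style dialect (decimal shifts, en-dash ranges,
`J = x, y Hz`, `calcd for … found …`, `Anal. Calcd for …: E, x; … Found: …`)
expressed as regexes and kept as data. Kinds are located in the order HRMS,
elemental, ¹³C, ¹H; spans never overlap; a located span whose payload fails
to interpret (e.g. an unknown element symbol) is returned flagged
`parsed=False` rather than raising, and checks skip it rather than fail it.

Checks and default tolerances:

- ¹H integrals: sum of integrations must equal the formula's H count
  exactly.
- HRMS: printed calcd mass within 0.005 Da of the monoisotopic mass of the
  stated ion formula; found within 5 ppm of calcd. Monoisotopic only —
  average-mass HRMS checks are out of scope.
- Elemental analysis: printed percentages within 0.4 percentage points of
  computed mass percent, the common journal convention.

The packaged mass table carries both the principal-isotope exact mass (used
for HRMS) and the standard average atomic weight (used for elemental
percentages, as journals compute them).

## Entity merging

Candidates from the active recogniser, ontology lookup and prefix automaton
are merged deterministically: longer span wins, ties go to type priority
CM > ONT > CPR > RN > CJ > ASE, remaining ties to higher confidence; CPR
entities abutting or inside a CM span are dropped as redundant locants. The
cascade favours the most informative (CM) reading, is idempotent, and makes
output independent of candidate order. Whether ontology/prefix stages run
inside or beside the main recogniser was an open design point; they run as
parallel stages merged by this policy.

## Synthetic fixtures

`fixtures.generate_corpus` emulates annotated training text: sentences of
plain English words with inserted pseudo-chemical entity tokens, where a
class-specific suffix *is* the entity rule (CM: `-ol/-ane/-ate`, RN:
`-ation`, CJ: `-ic`, ASE: `-ase`). Defaults: 500 sentences of 6–12 slots,
entity probability 0.2 per eligible slot, two-token entities at rate 0.2,
class mix 70/10/10/10. Plain words ending in an entity suffix are excluded,
and a plain word always follows an entity, so every maximal run of
suffix-bearing tokens is exactly one gold span — the corpus is labelled
unambiguously by construction, which is what makes ≥0.95 held-out
precision/recall a meaningful recovery target rather than a ceiling effect.
Gold spans are recorded at insertion time, not by re-matching the rendered
text, so they are independent of the recognisers under test. Because
entities are never adjacent, the nominal entity rate applies to eligible
slots (positions not forced plain); measured rates are compared on that
basis.

These fixtures deliberately do not emulate journal prose, ambiguous or
nested mentions, or vocabulary shared between entity and non-entity tokens.
Passing tests on them demonstrates that the machinery (features, optimiser,
decoder, span reconstruction) is correct, not that any particular accuracy
will be reached on real literature.

## Numerical choices and degenerate inputs

- Forward/Viterbi passes run in log space; invalid transitions are −inf.
- Confidence ratios are clipped at 1 to absorb rounding.
- Empty documents, empty token sequences and empty entity lists all produce
  empty outputs rather than errors; empty tokens and empty formulae are
  contract violations.
- Ties in merging and pattern matching are broken by fixed deterministic
  orderings (document order, then type priority, then confidence).
- The suite's problem sizes (500-sentence training corpus, enumeration up
  to 9^6 paths, 1,000-string random batteries) keep a full run to seconds
  while exercising every stage at the sizes the properties call for.

## Known limitations

- The MEMM is locally normalised and exhibits label bias; a CRF would fix
  this but is deliberately out of scope.
- The pattern recogniser emits CM only; the four-class tagging lives in the
  MEMM.
- Data grammars cover the canonical dialect; journal variants (e.g. IR,
  melting points, `m/z` fragment lists) are not parsed.
- Dictionary resolution is exact-name lookup; no systematic-nomenclature
  parsing is attempted (hook provided).
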