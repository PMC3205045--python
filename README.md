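# chemtagger

Chemistry-aware text mining for synthetic-chemistry prose: chemical
named-entity recognition, name-to-structure resolution and automatic
checking of reported characterisation data.

Most of the chemical literature exists only as narrative text. Extracting
the chemistry from it requires components that general-purpose NLP tools get
wrong: a tokeniser that keeps `C-H`, `C2H6O`, `NSC-2648` and
`2,5-dichlorobenzylamine` intact; recognisers for chemical names, reactions,
chemical adjectives and enzymes; and parsers for the rigid strings in which
NMR, HRMS and elemental-analysis data are reported. `chemtagger` provides
these as a small, composable library plus a thin CLI, for anyone building
chemical information-extraction pipelines.

## What is inside

- **Document model** — `Token`, `TokenSequence`, `NamedEntity`,
  `ResolvedNamedEntity`: standoff annotations anchored by 0-based half-open
  character offsets, with the guarantee `text[start:end] == surface`.
  Entity classes: CM (chemical), ONT (ontology term), RN (reaction),
  CJ (chemical adjective), ASE (enzyme), CPR (locant prefix), plus DATA for
  experimental-data spans.
- **Tokeniser** — whitespace split, then iterative edge-punctuation peeling
  with bracket-balance and abbreviation guards, and hyphen splitting only
  before generic suffixes (`water-based` → `water - based`, but `C-H` stays
  whole).
- **N-gram classifier** — character 4-gram naïve Bayes over two word lists
  (chemical names vs. ordinary English with chemical words removed). A token
  with padded n-gram windows g₁…g_k scores
  `s = Σᵢ [log P̂(gᵢ|chem) − log P̂(gᵢ|non)]` with additive smoothing, and
  `P(chem|token) = σ(s + logit π)` for prior π.
- **Pattern recogniser** — marks tokens chemical at a probability threshold
  and assembles multi-token CM entities from glob patterns such as
  `*yl *ate` (e.g. "ethyl acetate").
- **MEMM recogniser** — a trainable maximum-entropy Markov model over the
  9-label per-class B/I/O alphabet, `P(yᵢ | yᵢ₋₁, xᵢ) ∝ exp(w·f(xᵢ, yᵢ₋₁, yᵢ))`,
  with L2-regularised convex training, constrained Viterbi decoding and
  entity confidences computed as constrained-forward probability ratios.
- **Lexicon stages** — whole-token regex matching for compound serial
  numbers (`NSC-2648`), longest-leftmost ontology-term lookup (term → id
  multimap), and a finite automaton for locant prefixes (`2,5-`, `N,N-`,
  `cis-`).
- **Resolution** — ordered registry of name → structure dictionaries
  (SMILES / InChI / CML) with an optional fallback hook where a systematic
  nomenclature parser can be plugged in.
- **Data checker** — regex grammars for ¹H/¹³C NMR peak lists, HRMS and
  elemental analysis, plus consistency checks: proton integrals vs. H count,
  printed HRMS calcd mass vs. monoisotopic mass of the stated ion formula,
  printed elemental percentages vs. computed mass percent.
- **Synthetic fixtures** — deterministic generators for word lists and
  annotated corpora so every stage is trainable and testable offline.

## Worked example

```python
from chemtagger import Pipeline
from chemtagger.dataparser import find_data, check_consistency, parse_formula

pipe = Pipeline()  # defaults: pattern recogniser + packaged fixture resources

text = "Stirred in ethyl acetate overnight, then washed with water."
for e in pipe.find_named_entities(text):
    print(f"{e.type.value:4s} [{e.start:2d},{e.end:2d}) {e.surface!r}  conf={e.confidence:.3f}")

for r in pipe.find_resolvable_entities("benzene and the methyl ester"):
    print(r.entity.surface, "->", [f"{s.format.value}:{s.value}" for s in r.structures][:2])

nmr = "1H NMR (400 MHz, CDCl3) δ 7.20 (m, 5H), 2.36 (s, 3H)."
(ann,) = find_data(nmr)
(rep,) = check_consistency(ann, parse_formula("C7H8"))
print(ann.kind, rep.check, rep.passed, rep.observed, rep.expected)
```

prints

```
CM   [11,24) 'ethyl acetate'  conf=1.000
ONT  [53,58) 'water'  conf=1.000
benzene -> ['SMILES:c1ccccc1', 'INCHI:InChI=1S/C6H6/c1-2-4-6-5-3-1/h1-6H']
HNMR hnmr_integration True 8.0 8.0
```

`ethyl acetate` is found by the `*yl *ate` pattern over two tokens the
n-gram model classifies as chemical (the confidence is the geometric mean of
their chemical probabilities); `water` comes from the ontology lookup; only
`benzene` resolves to structures, so `the methyl ester` is (correctly)
absent from the resolvable set; and the toluene peak list integrates to the
8 protons of C7H8.

The same functionality is available from the shell:

```
echo "Stirred in ethyl acetate overnight." | chemtagger run --input -
chemtagger check-data --input data.txt --formula C7H8
chemtagger gen-corpus --seed 1 --out corpus/
chemtagger train-ngram --chemical corpus/chemical_words.txt --english corpus/plain_words.txt --out ngram.json
chemtagger train-memm --corpus corpus/corpus.json --ngram ngram.json --out memm.json
```

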