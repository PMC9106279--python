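# notepol

Analysis pipeline for timestamped, group-labelled free-text clinical notes:
lexicon sentiment scoring, valence-shifter polarity scoring, temporal
comparison of group series with dynamic time warping, LDA topic modeling
with coherence/exclusivity model selection and post hoc covariate
prevalence analysis, and classifier-based group discrimination. A
synthetic-corpus generator with a full ground-truth ledger makes every
stage testable end to end without any real patient data.

## Modules

| module | what it does |
|---|---|
| `notepol.corpus_synth` | synthetic corpora (LDA text process + sentiment/shifter emissions + planted duplicates) with ground truth; independent polarity oracle and fixture grid |
| `notepol.ingest_preprocess` | CSV ingest, copy-paste deduplication, sentence split/tokenize, table lemmatization, stopword removal |
| `notepol.lexicons` | readers for emotion / integer-valence / binary / valence-shifter lexicon TSVs; bundled fixture lexicons |
| `notepol.sentiment` | per-note lexicon scoring, group contingency tables, chi-square + Bonferroni-corrected residual post hoc |
| `notepol.polarity` | sentence polarity with context clusters (4 before / 2 after, comma truncation), negators, amplifiers/deamplifiers (c=0.8, floor −1), √n normalization; Fourier trend; Lilliefors + Mann-Whitney group comparison |
| `notepol.temporal` | monthly group series; path-normalized DTW distance |
| `notepol.topics` | collapsed-Gibbs LDA (numba), semantic coherence, FREX exclusivity, K selection, permutation-based covariate prevalence effects, topic correlation network |
| `notepol.classify` | document-term matrices, stratified 75/25 split, native multinomial Naive-Bayes, pluggable SVM/RF/NN backends, AUC/sensitivity/specificity/κ/accuracy with no-information-rate test |
| `notepol.cli` | `notepol` command: full pipeline from one YAML config with a hashed run manifest |

## CLI

```bash
# full pipeline on the built-in synthetic config
notepol all --out runs/demo

# or stage by stage / with your own data and config
notepol synth --out runs/demo
notepol preprocess --notes notes.csv --out runs/demo
notepol all --config my_config.yaml --out runs/demo
```

Input corpora are UTF-8 CSV/TSV with header
`note_id,patient_id,group,shift,date,text` (`group` ∈ {covid, non_covid},
`shift` ∈ {morning, afternoon, night}, ISO dates). Lexicons are two-column
TSVs; small fixture lexicons ship with the package and real ones are
drop-in replacements by path. Each run writes per-stage CSV/JSON outputs
plus `manifest.json` with every seed and output hash; reruns with the same
config are bit-identical.

Exit codes: 0 success, 2 configuration error, 1 stage failure (partial
outputs kept with a `FAILED` marker).

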