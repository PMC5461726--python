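# Methods

## Model

`litassoc` treats an association between a target g (gene or its protein
product, identified by a SwissProt-style accession) and a disease z
(EFO-style identifier) as evidenced by sentence-level co-occurrence: one
co-occurrence event is a sentence containing at least one mention of g and
one of z. Events are aggregated per document and weighted by where they
occur, on the assumption that location encodes credibility — a title or
results-section pair usually reports the paper's own finding, while an
introduction pair usually restates prior knowledge. The confidence score of
a (document, g, z) triple is therefore a location-weighted event count, not
a probability; scores are comparable within a scoring batch and are used
only to rank documents per association.

## Pipeline stages and their assumptions

1. **Lexicon refinement.** Surfaces shorter than 3 Unicode characters are
   removed, as is any surface equal (case-insensitively) to a configured
   common-word stoplist entry. The stoplist ships empty by default and is an
   explicit input: which English words collide with gene names depends on
   the source vocabulary, so the intersection must be chosen at build time.
   Greek variants are generated for whole-word spelled names and symbols
   (alpha–omega, both directions, every combination of occurrences, capped
   at 8 replaceable tokens); variants inherit both filters. The length
   filter runs before variant generation so a surviving surface can still
   produce a too-short variant that is then dropped.
2. **Document model.** Two dialects (JSON-lines, minimal JATS-like XML)
   parse into title/abstract/body zones of offset-indexed sentences
   (0-based, half-open). Body headings are classified by a case-insensitive
   keyword table with fixed precedence (results > discussion > conclusion >
   methods > introduction > case study > appendix > references >
   acknowledgement/funding > competing interests > author contribution >
   supplementary), so "Results and Discussion" is results. Figure and table
   captions are their own zones because they carry their own section
   weight. Abstract sentences are classed first-or-second / last / other;
   "last" wins ties, so a one-sentence abstract is "last" — the last
   sentence carries the results-like signal, and ties resolve toward the
   more specific class.
3. **Annotation.** Longest-match, left-to-right, word-boundary-anchored
   dictionary lookup. Word characters are ASCII alphanumerics and Greek
   letters; internal hyphens join tokens. Surfaces of length ≤ 5 that are
   all-uppercase in the lexicon (gene-symbol style) match case-sensitively;
   all others case-insensitively. A surface mapped to several identifiers
   emits one mention per identifier — disambiguation is the abbreviation
   filter's job. A target and a disease match over the same span coexist.
   Note the longest-match rule means lexicon growth is not strictly
   monotone in mention count: a newly added longer surface can absorb a
   previously emitted nested match.
4. **Abbreviation filter.** Candidates are parenthesized all-uppercase
   tokens of length < 6 annotated as target or disease. The long form is
   taken from a window of the N+1 words before the parenthesis (N = short
   form length), trimmed by Schwartz–Hearst-style character alignment: the
   shortest window suffix whose words contain the short-form characters in
   order, with the first character at a word start; when no alignment
   exists the whole window is used. This keeps the window bounded while
   extracting "advanced life support" for (ALS) even when unrelated words
   precede it. Keep rules are a disjunction evaluated in a fixed order
   (D1–D2 for diseases, G1–G4 for genes) and the first firing rule is
   recorded; a dropped candidate suppresses all same-surface, same-kind
   mentions *in that document only* — ambiguity is document-local, an
   article about resuscitation does not make ALS ambiguous elsewhere. The
   keyword lists default to the printed exemplars (disease: disease,
   disorder, syndrome, defect, deficiency, cancer, carcinoma, tumor,
   tumour, infection; target: factor, receptor, gene, protein, enzyme,
   kinase, antigen, ligand; 20 context keywords for G4) and are
   configurable. G1's "body" includes figure/table captions; G4 needs the
   document's disease mentions, so it cannot fire when none are supplied.
5. **Association filters**, fixed order: article type (default research
   set {research-article, Research}, case-insensitive; documents without a
   type are dropped — conservative, matching the filter's intent), excluded
   sections (methods, references, acknowledgement/funding, competing
   interests, author contribution, supplementary), then minimum occurrence
   (drop iff body events = 1 and title = abstract = 0; body includes
   captions; abstract-only documents are unaffected). Within one sentence a
   pair counts once regardless of mention multiplicity; counting is per
   identifier pair, not per surface.
6. **Scoring.** Defaults are the published weights (sentence-location
   2/5/3; section 10/5/2/1; gene-in-abstract coefficient 0.2, counting
   mentions rather than a binary flag). S2 excludes the abstract — abstract
   events of a full-text article flow through S1 inside CS2 — and scores
   full-text titles at weight 10, the only reading under which the title
   weight and CS2's lack of a separate title term are both used. The
   boosting-up factor is the median of the batch's full-text body scores
   (even length: mean of the middle two; empty batch: 0) and is recorded in
   the run report; it is batch-relative by construction. Ranking is total:
   descending confidence, ties broken by ascending document id, chosen for
   reproducible regression output.
7. **Evaluation.** Average precision is normalized by the number of
   relevant documents *within* the cutoff (default 25), matching evaluation
   restricted to the top of the ranking; MAP is the arithmetic mean over
   associations. Pearson's r is used for score correlation between scoring
   variants.

## Synthetic corpus

The generator emulates the study conditions at desk scale: the default
corpus holds 109 documents — 40 abstract-only and 40 full-text background
research articles, 12 planted documents covering 4 associations across
every weighted zone and sentence location, 16 distractors cycling through
the three filter-defeat modes (review article; pair only in methods; single
body occurrence), and one ambiguous-abbreviation document. Sentences are
template-based ("GZA is associated with pathosis alpha in this cohort."),
so splitting and matching are exact and the generator can emit the precise
association record, score and rank each planted document must produce;
relevance judgments mark planted documents relevant. A fixed seed yields a
byte-identical corpus (the seed only varies filler wording).

What passing on this corpus shows: the pipeline's bookkeeping — parsing,
matching, filtering, weighting, ranking — is exact. What it does not show:
recall and precision on real text, where entity names nest, abbreviations
are introduced implicitly, sentence boundaries are messy, and section
headings are inventive. The published corpus-scale figures (MAP ≈ 0.9,
score correlations 0.82–0.94) depend on real dictionaries, a real corpus
and manual relevance judgments, and are out of scope here; on synthetic
corpora where planted documents are the only survivors, MAP is exactly 1.0
by construction.

## Numerical and degenerate-input choices

Scores are plain floats; all weights are positive, so every component is
non-negative and confidence is monotone in every count. Empty abstracts
yield zero-sentence zones; an empty document stream yields an empty, valid
run. Parse failures are per-record (logged and collected), not batch-fatal.
CS1 applied to a record with body counts, or CS2 to one flagged
abstract-only, raises rather than silently mis-scoring. Reference
quantities recomputed by `scripts/acceptance.py` use single-document
corpora (n = 1 or 2), since each is an exact worked example rather than a
statistical estimate.

## Known limitations

Dictionary matching has no contextual disambiguation beyond the
abbreviation filter; species are not resolved; relation polarity (negated
or speculative co-occurrence) is not modeled; cross-sentence anaphora is
invisible to sentence-level co-occurrence. The heading classifier is a
deterministic keyword table, not a trained section tagger, and multi-topic
headings resolve by precedence. The platform-level association score that
aggregates document scores across evidence sources is out of scope.
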