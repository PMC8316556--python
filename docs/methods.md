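# Methods

This note documents the model behind `genepheno`, the parameters that
matter, the numerical conventions, and what the synthetic-data tests do and
do not demonstrate about real corpora.

## Co-mention model

The package treats a sentence as the unit of evidence: a gene *G* and a
phenotype *P* are assumed to be associated in proportion to how much more
often they share a sentence than independence predicts. This is a purely
correlational model — no negation, causality or semantic-relation
extraction is attempted, so a sentence stating "G was *not* associated with
P" still counts as a co-mention. Association strength is normalized
pointwise mutual information over sentence counts:

    NPMI(G, P) = ln( n_GP · n_tot / (n_G · n_P) ) / ( −ln( n_GP / n_tot ) )

with natural logarithms throughout. `n_tot` counts **all** corpus sentences
(title, abstract and body paragraphs; reference lists, tables and captions
are excluded at parse time), not only target sentences. A sentence
contributes at most 1 to each count regardless of repeated mentions, and
`n_P` pools all synonyms of a standardized concept.

Boundary conventions are the analytic limits of the formula: `n_GP = 0`
returns −1 and `n_GP = n_tot` returns 1; the co-occurrence-complete case
`n_GP = n_G = n_P` returns exactly 1.0 (short-circuited, since the floating
ratio can land one ulp below 1). Results are clamped to [−1, 1]. A joint
count exceeding a marginal is treated as fatal count corruption rather than
being silently clamped.

## Text processing

Tokenization, sentence segmentation, stop-word removal and lemmatization
are implemented in-package as small deterministic rule systems rather than
as a statistical NLP stack. Dictionary matching only requires that a
sentence token and a vocabulary term normalize to the *same* string, so the
lemmatizer is a conservative table-plus-suffix-rules design (irregular
nouns, plural stripping including Latin/Greek medical plurals such as
*epilepsies* → *epilepsy*, and -ing/-ed verb forms). The stop-word list is
a packaged editable text file, not a hidden library default. Sentence
boundaries come from an abbreviation-aware rule splitter (`et al.`,
`Fig.`, initials, digit continuation). All of this is seed-free and
hash-stable: the same corpus and configuration always yield the same
sentence table.

Gene symbols are matched case-sensitively as whole raw tokens; phenotype
terms as lemma n-grams, longest match first, then leftmost, yielding a
non-overlapping mention set. Whole-token matching is the minimal guard
against substring artifacts (the gene `CAT` inside "scatter"); note that it
does **not** prevent phenotype hits inside larger noun phrases ("cancer"
inside "National Cancer Center") — that failure mode is reproduced on
purpose by the generator's noise mode and left unsolved, matching the
method's known false-positive profile.

## Lexicon and standardization

The phenotype lexicon is built from MRCONSO/MRSTY-style RRF files by
two-layer filtering: source vocabulary ∈ {HPO, OMIM, DDB, SNOMEDCT_US,
MSH}, then semantic types — non-HPO concepts must carry one of
{T047, T048, T184}; HPO concepts are excluded if they carry one of
{T045, T077, T079, T080, T082, T169}. The HPO exclusion list is open-ended
in real UMLS releases, so it is a configuration parameter defaulting to
those six codes. Only English rows (`LAT = ENG`) are retained, since
matching targets English prose. ASDPTO terms arrive from a flat TSV and
bypass the semantic-type layer. Column indices are configurable so that
compact hand-written fixtures remain format-valid.

Mentions resolve to concepts by source priority HPO(1) > ASDPTO(2) >
OMIM(3) > DDB(4) > SNOMEDCT_US(5) > MSH(6), ties by concept id — a total
order, so resolution is invariant under candidate permutation. Concepts
with an HPO id are assigned one of the 23 top-level phenotypic categories
(the children of *Phenotypic abnormality*) by breadth-first ancestor
traversal; when a term sits under several category roots the nearest root
wins, ties broken by table order. Category roots are configured by HPO id,
not by label, so ontology label edits cannot silently remap categories.
Anything without an HPO id, or unreachable from a category root, is "NA".
The hierarchy input is a minimal OBO-like dialect (`id:`/`name:`/`is_a:`
lines only) so fixtures are hand-writable; full OBO semantics are out of
scope.

## Filtering, profiles, network

Associations are filtered with strict thresholds `NPMI > 0` and
`n_GP > 5` (both configurable; the demo lowers the count threshold because
its corpus is three orders of magnitude smaller than a production corpus).
Per-gene rankings sort by NPMI descending, ties by `n_GP` descending, then
concept id — the same rule used when a gene is labeled by its top
phenotype's category, so the two views can never disagree on ties.

The gene–phenotype matrix is binary with entry 1 iff NPMI > 0 (strictly).
t-SNE (scikit-learn, PCA initialization, seed-deterministic) embeds gene
profiles in 2-D and k-means clusters the embedding; `k` has no default —
the choice is a user decision. The clustering routine accepts any numeric
gene table, so k-means can equally be run on the raw binary matrix by
passing it in place of the embedding. Concordance between clusters and
category labels is computed from the contingency table: adjusted Rand
index, Jaccard index, NMI with arithmetic-mean normalization, and purity.
Purity's second argument is the reference labeling. Degenerate single-class
partitions define NMI = 1 when both sides are trivial (identical) rather
than 0/0.

The interaction network links two genes when both have NPMI **≥** the
global average NPMI (mean over all retained records; a flag restricts the
mean to positive records) for a shared phenotype; the inclusive comparison
is a documented choice where strictness is unspecified. Parallel links
compress to an integer edge weight. Betweenness centrality is the raw
(unnormalized) Brandes sum over unordered pairs, via networkx; in weighted
mode the shared-phenotype count is an affinity, so edge length is
1/weight (flag-switchable to length = weight). The top fraction selects
`ceil(f · n)` genes, ties at the cut broken by symbol order.

## Synthetic data: what it shows and what it does not

The generator plants gene symbols and phenotype synonyms into template
sentences with per-sentence Bernoulli probabilities; configured pairs are
coupled through a single uniform draw so that the joint probability is
exact while marginals are preserved (feasibility `p_joint ≤ min(p_G, p_P)`
and `p_G + p_P − p_joint ≤ 1` is validated). Defaults are 50 articles × 100
sentences = 5,000 sentences, marginal probabilities of 2–6% and four
coupled pairs from strong (p_joint = 0.03 against marginals 0.06/0.05) to
weak (0.008) — the order of magnitude at which prominent genes recur in a
focused literature corpus. Articles carry empty titles so the sentence
count equals the planted slots exactly, which keeps the analytic NPMI of a
planted pair a closed form of the planting probabilities.

Because planting uses clean token boundaries and exact vocabulary
synonyms, the miner recovers planted counts *verbatim* and gold-standard
precision/recall are 100%. That validates the bookkeeping — counting
semantics, synonym pooling, standardization, NPMI arithmetic — not
real-world robustness: real corpora contain unseen phenotype paraphrases,
ambiguous gene symbols (`CARS` as a rating scale), and non-phenotype noun
phrases. Noise mode plants "National Cancer Center" distractors to keep
that false-positive mode under regression, but no synthetic corpus here
models paraphrase-driven false negatives; recall on manually curated
articles is the only guide there.

Estimator checks use 3σ binomial bands on counts, and an NPMI tolerance
obtained by propagating those 3σ corners through the formula — so the
tolerance derives from the planting parameters, not from observed output.

## Problem sizes

Test fixtures use a 300-sentence corpus for integration tests and the
5,000-sentence default corpus for the end-to-end recovery checks; oracle
comparisons run on partitions of up to 30 elements and graphs of up to 12
nodes, where exhaustive pair/path enumeration is exact and fast.

## Known limitations

- Correlational only: no assertion, negation or dosage semantics.
- Sub-sentence syntax is ignored; multi-clause sentences can yield pairs
  the prose does not assert.
- The rule lemmatizer under-normalizes rare inflections; a missed
  normalization costs recall, never precision.
- Non-HPO concepts cannot inherit top-level categories (no UMLS→HPO
  cross-walk), so category coverage depends on HPO's share of the lexicon.
- t-SNE geometry is seed- and implementation-dependent; only seeded runs
  are reproducible, and concordance values on small corpora are noisy.
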