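# Methods

This note documents the models, rules and numerical choices behind
`ghsieve`, and what the synthetic studies used in its tests do and do not
establish about real data.

## Problem setting

A de novo transcriptome assembled from a cultured protist host carries
transcripts from the host and from attached or symbiotic bacteria, fungi
and other eukaryotes. The pipeline screens candidate glycoside-hydrolase
(GH) transcripts and assigns each a five-way origin label — prokaryotic
contamination (PC), host genome-verified (G), host phylogenetically
verified (E), eukaryotic contamination (EC), or unique (U) — using only
offline inputs: similarity-hit tables that carry subject taxonomy as extra
columns, host-genome hit tables, a curated reference catalog, and gene
trees with bootstrap supports.

## Candidate extraction

The packaged enzyme catalog transcribes, for the seven targeted GH types,
their EC numbers (all of form EC3.2.1.x) and alternative enzyme names.
Matching is normalized substring search: keywords and annotation text are
lowercased, and hyphens, commas and whitespace runs collapse to single
separators, so `Endo-1,4-beta-Xylanase` equals `endo 1,4 beta xylanase`.
A word-boundary guard requires the keyword's first token to start, and its
last token to end, on a token boundary of the annotation: a suffixed form
like `laminarinase-like` still matches `laminarinase`, but a keyword can
never fire inside an unrelated longer token. A transcript may carry
several enzyme types and is kept in each. Redundancy removal collapses
exact peptide duplicates within each type (configurable to nucleotide
identity), keeping the lexicographically smallest transcript id —
"redundant" is not defined more precisely upstream, and exact identity is
the only definition that needs no alignment parameters.

Isoform grouping strips a Trinity-style `_i<digits>` suffix from the
transcript id; ids without the suffix are their own gene.

## Similarity-stage rules

* **Top hit**: minimal e-value; ties broken by maximal bitscore, then
  lexicographically smallest subject id (ties are otherwise undefined and
  must not depend on input order).
* **Prokaryotic filter**: a candidate is PC iff its top hit is Bacteria or
  Archaea. Candidates with no hits are retained: only positive prokaryotic
  evidence excludes, since dropping no-hit transcripts would silently lose
  the U category.
* **Genome verification**: label G iff ≥1 host-genome hit at e-value
  ≤ 1e-5 (inclusive).
* **Family assignment**: the GH family (GHF) of the top hit against the
  verified reference database at e-value ≤ 1e-5; candidates with no
  passing hit are U. Following the published category definitions, U takes
  precedence: a transcript with no family hit is reported U even when
  genome-verified.
* **Threshold extraction** (cellulosome-scaffolding variant): queries with
  any hit at e-value strictly below 1e-30. The genome stage is inclusive
  and this one strict, following the wording of each rule's source.

Default thresholds: 1e-5 (annotation and genome), 1e-10 (domain), 1e-30
(scaffolding), bootstrap 50 (collapse).

## Reference-database curation

An entry enters the verified eukaryotic GH database only if it has a
public reference and at least one evidence code of genomic origin
(assembled genome; cDNA aligned/hybridized to a genomic template; RNA from
a clean culture or tissue; close homology to a genome-verified relative).
Evidence codes are supplied as data pre-digested from the literature;
automating literature reading is out of scope. Retained entries group by
(enzyme type, GHF), and the summary reports total(retained) per type.

## Tree classification

Input trees are rooted as given (the procedure is rooting-dependent, and
the synthetic generator produces rooted trees). Internal-node labels are
read as bootstrap supports attached to the edge above the node, the common
IQ-TREE/consensus dialect. Collapsing contracts every internal edge with
support strictly below the threshold; edges with absent support are
retained (they are unsupported-but-present polytomies of the input), and
leaves are never removed.

On the collapsed tree, for query leaf q: C(q) is the maximal pure-query
clade containing q; M the smallest ancestor of C(q) containing a reference
leaf; S the superfamily set of M's references. Rules, in order:

(a) any leaf of C(q) genome-verified → every query leaf of C(q) is G
    (clade rescue; this deliberately precedes rule (b), resolving the
    otherwise-undefined case of a clade sister to both fungi and a
    genome-verified member);
(b) |S| = 1 and S prone → EC;
(c) |S| = 1 and S not prone → E with a review flag by default, EC in
    strict mode;
(d) |S| > 1 → E, flagged for review iff C(q)'s stem edge lacks retained
    support (a supported host clade on a chaotic backbone is a confident
    host call; an unsupported one merits review).

"Intermixed" is operationalized as |S| = 1: visually, a query clade
nesting among references of exactly one foreign superfamily. The prone set
defaults to {Fungi}: fungal neighbors are treated as contamination even at
high support, while a single non-fungal neighbor (e.g. a metazoan) is
retained as host-with-review, matching the conservative asymmetry of
manual practice; `strict_mode` removes the asymmetry. All leaves of one
C(q) receive identical labels, and a tree without reference leaves is
rejected as unclassifiable.

The classifier is verified exhaustively: over every annotated rooted
multifurcating topology with ≤6 leaves, two reference superfamilies (one
prone, one not), all genome-flag placements, both support settings and
both modes (122,792 cases), it agrees exactly with an independent
brute-force oracle that applies rules (a)–(d) by literal per-leaf ancestor
scans.

## Expression and signal-peptide models

Expression enters as TPM; the default predictor is log₂ TPM (the scale the
expression summaries use; raw TPM is available by flag). TPM = 0 has no
logarithm and is reported as not-detected; such transcripts are excluded
from regression and counted (a pseudocount is available but off by
default). The heatmap writer prints log₂ TPM to one decimal and leaves
cells in the open interval (−0.05, 0.05) blank — exactly the values that
would display as 0.0.

Signal-peptide presence y ∈ {0,1} given expression x is fit by maximum
likelihood under three curves:

* logistic: P(y=1|x) = 1/(1+e^−(β₀+β₁x)), 2 parameters;
* sigmoid: L/(1+e^−k(x−x₀)), 3 parameters, 0 < L ≤ 1 — distinguished
  from the logistic by its free maximum asymptote (a transcript class may
  never be fully secreted no matter how highly expressed);
* ReLU: clip(a(x−b), 0, 1), 2 parameters.

These parameterizations are this package's explicit choices; "sigmoid" and
"ReLU" admit several conventions. Probabilities are clipped to
[1e-9, 1−1e-9] inside the likelihood, so perfect separation yields a
finite, reported fit whose log-likelihood approaches 0 rather than an
error. Optimization is deterministic multi-start: BFGS for the logistic
(whose likelihood is concave; starts at the empirical-logit intercept with
slopes {0, ±1}); L-BFGS-B with box bounds for the sigmoid (L ∈ [1e-6, 1],
k ∈ [−60, 60], x₀ within the data range ±10 sd; 24 fixed starts over
quartiles); Nelder-Mead for the non-smooth ReLU (14 fixed starts including
near-constant curves a → 0 with a(x−b) ≈ ȳ), followed by one polishing
pass from the best start. Fits with a single-class response or n < 10 are
rejected ("degenerate response"), and the per-type association report
downgrades such groups to "not testable" rows instead of failing.

Model comparison is by AIC = 2k − 2 ln L̂ on identical data (mismatched n
is an error), reporting ΔAIC to the best model. The logistic slope's Wald
p-value comes from the observed information X'WX at the MLE; a singular
information matrix (complete separation) reports no p-value. Tests verify
the logistic fit against two independent oracles — statsmodels' IRLS and a
nested grid-search MLE — to better than 1e-4 in both parameters, and the
AIC identity is recomputed independently for every fit.

## Synthetic studies

The generator defines the study conditions under which the pipeline is
validated. Defaults: 100 GH candidates — 60 host, 20 prokaryotic, 10
fungal, 10 other-eukaryote — plus 20 annotation decoys, across 7 GH
families (labels echoing prominent families of the seven types: GHF5, 10,
28, 18, 2, 29, 16), family length 120 aa. Each family has a random
ancestral peptide; fungal and green-plant references diverge from it by
0.25 substitutions/site, bacterial references by 0.45, host transcripts by
0.10 and contaminants by 0.15 from their respective reference points.
These divergences put every true top hit ~15–20 identity points clear of
its nearest competitor at length 120, so the threshold stages are exercised
with realistic but unambiguous margins. Per-position identity of the
equal-length sequences (alignment is deliberately avoided) maps to a
surrogate e-value 10^(−identity%/2): real e-values depend on database
size, and only ordering and thresholds matter to the pipeline; pairs below
10% identity are omitted, mirroring a search threshold.

Half the families carry planted host-genome hits (every second host member
receives one strong hit), making their host clades G via the rescue rule;
hosts of the other families are expected E. Every fifth host transcript is
emitted as a second isoform of the preceding gene (differing by exactly
two substitutions so redundancy removal keeps it). Each family tree is
built in the true clade topology — host queries monophyletic, contaminants
nested inside their source superfamily's reference clade — with bootstrap
95 on true edges; the last half of families additionally wraps the host
clade and the fungal clade under a spurious edge with support 30, which
the 50% collapse must remove for correct classification (and whose
retention demonstrably misclassifies). A distance mode instead derives the
topology by neighbor joining (scikit-bio) from p-distances, for ≥4-leaf
trees. The raw reference catalog adds one curation-destined reject per
family (alternating missing-reference and missing-evidence), so 80% of
entries survive curation.

Expression: log₂ TPM ~ Normal(2, 3) — spanning roughly the ±15 range the
heatmap convention anticipates — with 5% of transcripts undetected;
signal peptides follow Bernoulli(logistic(β₀ + β₁·log₂TPM)) with β₀ = −1,
slope 1.2 for cellulase and chitinase and 0 elsewhere, echoing the
type-specific association the pipeline is meant to detect.

When the full synthetic study is pushed through the pipeline, the
contamination-prone taxa are set to the superfamilies the generator planted
its eukaryotic contaminants from ({Fungi, Viridiplantae}) — the synthetic
analog of treating the plausible contaminant sources conservatively.
Under these defaults the pipeline recovers the planted five-way labels at
100% on the tested seeds (the acceptance bar is ≥95%).

What passing does and does not show: the generator uses i.i.d.
substitution on equal-length peptides with clean clade structure and a
monotone surrogate e-value. It establishes that the decision logic is
correct and deterministic under controlled divergences, not that the
thresholds are optimal for real searches, nor that the classifier is
robust to alignment error, indels, rate heterogeneity, long-branch
attraction, or reference databases whose taxonomy labels are themselves
wrong. Problem sizes in the tests (100 candidates, ≤6-leaf exhaustive
enumeration, n ≤ 1000 regressions, 100 model-selection replicates) were
chosen as the smallest that exercise every rule with stable statistics.

## Known limitations

* Clade decisions depend on the input rooting; an outgroup-free tree
  rooted arbitrarily can change M and hence labels.
* The review flag in rule (d) keys on the stem edge's support only; branch
  lengths are never consulted, so a long-branch query inside a fungal
  clade is still called EC.
* Keyword extraction inherits the annotation text's vocabulary: an enzyme
  annotated only by an unlisted synonym is missed.
* The sigmoid/ReLU forms are fixed conventions; other parameterizations
  would give different AIC comparisons.
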