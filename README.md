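# ghsieve

Origin classification of glycoside-hydrolase (GH) transcripts in
contamination-prone de novo transcriptomes.

De novo transcriptomes of hard-to-culture protists (the motivating case is
a benthic foraminifer kept in culture with its attached bacteria and fungi)
inevitably mix host transcripts with transcripts from symbiotic or attached
organisms. When the genes of interest are GHs — enzymes that bacteria and
fungi also carry in abundance — deciding which candidate transcripts are
endogenous to the host is the whole analysis. `ghsieve` implements that
decision procedure as a tested, deterministic pipeline for researchers who
need to screen candidate enzyme repertoires without a reference genome.

## What it does

Candidates are first pulled from merged annotation text by keyword matching
against a packaged catalog of the seven targeted GH types (cellulase,
xylanase, pectinase, chitinase, mannanase, fucosidase, laminarinase), each
with its EC numbers and alternative enzyme names. Every candidate then ends
with exactly one five-way origin label:

* **PC** — prokaryotic contamination: the transcript's top similarity hit
  (smallest e-value, ties by bitscore) is bacterial or archaeal;
* **G** — host, genome-verified: at least one hit against host genomic
  fragments at e-value ≤ 1e-5;
* **E** — host, phylogenetically verified;
* **EC** — eukaryotic contamination;
* **U** — unique: no hit in any family of the verified eukaryotic GH
  reference database (itself curated by evidence-of-endogeneity criteria).

The E/EC decision is made on per-family gene trees. With bootstrap supports
below 50% collapsed into polytomies, each query leaf *q* defines
C(q), the maximal clade of query-only leaves containing *q*, and M, the
smallest ancestor of C(q) containing reference leaves with superfamily set
S. The clade is host if any member aligns to the host genome (the rescue
rule extends the label to the whole clade); contamination if S is a single
contamination-prone superfamily (Fungi by default); host-with-review if S
is a single non-prone superfamily (contamination in `strict` mode); and
host if the clade hangs on a backbone mixing superfamilies.

Downstream, expression (log₂ TPM) is summarized per enzyme type with the
published heatmap convention (one decimal; cells in (−0.05, 0.05) blank),
and signal-peptide presence is modeled against expression by maximum
likelihood under three Bernoulli response curves — logistic
1/(1+e^−(β₀+β₁x)), sigmoid L/(1+e^−k(x−x₀)) with free asymptote 0 < L ≤ 1,
and clipped-linear ("ReLU") clip(a(x−b), 0, 1) — compared by
AIC = 2k − 2 ln L̂, with Wald p-values for the logistic slope.

A first-class synthetic-data module generates every pipeline input with
planted ground truth (host gene families, prokaryotic/fungal/other-eukaryote
contaminants, hit tables, genome hits, support trees, expression tables with
a known logistic link), so the entire pipeline is verifiable end to end
without any external downloads.

## Worked example

```python
from ghsieve import SimulationConfig, run_synthetic_study

run = run_synthetic_study(SimulationConfig(seed=1))
print(f"planted-truth agreement: {run.truth_agreement():.2f}")
print(run.result.partition.to_string())
```

```
planted-truth agreement: 1.00
              PC   G  E  EC  U  total  eukaryotic  prokaryotic_side
enzyme_type
CELLULASE      3   8  0   4  0     15           8                 7
XYLANASE       3  10  0   4  0     17          10                 7
PECTINASE      3   9  0   4  0     16           9                 7
CHITINASE      3   0  9   2  0     14           9                 5
MANNANASE      3   0  8   2  0     13           8                 5
FUCOSIDASE     3   0  7   2  0     12           7                 5
LAMINARINASE   2   0  9   2  0     13           9                 4
```

The default study plants 100 candidates (60 host, 20 prokaryotic, 10
fungal, 10 other-eukaryote); all 100 final labels match the planted truth,
and each row sums across the five categories to its total. Host transcripts
appear as G in families with planted genome hits and as E elsewhere.

The association stage, run on a larger single-type expression table
(300 cellulase transcripts simulated with slope β₁ = 1.2):

```
enzyme_type origin_side   n  n_zero_tpm     beta0    beta1       wald_p status
  CELLULASE  eukaryotic 300           0 -1.187733 1.238947 5.848122e-16     ok
```

The fitted slope recovers the planted positive link between expression and
signal-peptide presence, with its Wald p-value far below 0.05.

The same pipeline is scriptable from the shell:

```bash
ghsieve run-all --seed 1 --outdir out/       # inputs + all reports
ghsieve classify --tree t.nwk --leaf-annotations leaves.tsv --support 50
```

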