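# Methods

## Scope and assumptions

`docsubre` classifies document-level chemical–disease (CID) relations in
annotated abstracts.  It assumes:

* entity recognition and normalization are already done (mentions arrive
  with character offsets, types and concept ids in PubTator format);
* per-sentence dependency parses arrive in CoNLL-U, one tree per sentence,
  title first; the package never runs a parser;
* coreference links and knowledge-base chemical–disease pairs, when used,
  are precomputed inputs (tab-separated tables), not computed here;
* two concepts participating in a relation are mentioned within at most 5
  consecutive sentences of each other, or in the title — pairs further
  apart are not candidates and count against recall ("uncovered");
* the title is a special sentence related to the whole abstract, so it is
  attached to every sliding window.

## Document subgraphs

A window of `w` consecutive abstract sentences plus the title forms one
subgraph: the union of the sentences' dependency trees (directed, labeled)
plus undirected labeled virtual edges.  Six families exist — `TITLE`,
`NEXT-SENT`, `COREF-sent`, `COREF-to-title`, `COREF-from-title`, `KB-CTD`
— each independently switchable, so ablation grids are runnable.  The
production default enables only `TITLE` and `NEXT-SENT`; the coreference
and knowledge-base families are implemented and tested but off by default,
since their value depends on the quality of the upstream link tables.
Implementation choices:

* documents shorter than `w` produce a single whole-document window
  rather than none, so short abstracts still yield candidates;
* `KB-CTD` edges are created per mention pair (between mention *head
  tokens*), not per concept pair;
* duplicate virtual edges (same endpoints and label) collapse — the graph
  is a set;
* coreference/KB edges with an endpoint outside the current window are
  skipped; endpoints outside the document are an error.

## Path mining

Breadth-first enumeration of simple paths between the two mention heads,
bounded by `md = 15` nodes per path and `kmax = 150` collected paths.
Virtual edges are traversed exactly like syntactic ones; each traversed
edge records its orientation (with/against the arc for syntactic edges,
traversal order for undirected virtual edges).  Collection order is fixed
— nondecreasing node count, ties broken lexicographically by node
coordinates — so runs are reproducible; neither the order nor the
tie-break affects correctness, only determinism.

Minimal-span filtering removes a mention-pair co-occurrence when another
co-occurrence of the same concept pair overlaps it with a strictly
contained sentence span: when a pair co-occurs both tightly and loosely,
the tight span is where the relation is most likely expressed, and the
loose span mostly contributes noise.

All surviving paths of one concept pair, across all windows and mention
pairs, merge into a single candidate instance.  Deduplication keys on the
lexical surface pattern — per-token (surface, POS) and per-edge (label,
direction) — rather than node identity, so the same pattern occurring at
different document positions also collapses; pre-deduplication
multiplicities are kept for the frequency-based selection strategy.
Finally the top `k = 3` paths are kept, by length (default) or by
multiplicity.  Pairs with zero paths are excluded from training and
predicted NONE.

## Path encoding

* Dependency unit: `d = tanh([type ++ direction] W_d + b_d)`.  The 72-row
  syntactic label table and the 6-row virtual label table are separate
  lookup tables sharing the transform; two direction rows cover both
  orientations, so a relation and its reverse share the type vector.
* Token: `t = tanh([word ++ POS ++ char-biLSTM ++ aux] W_t + b_t)` with
  pre-trained word vectors (fixed, lowercase lookup, zero OOV fallback), a
  learned POS table, a character biLSTM (85-char table, 50 units per
  direction) and a fixed 45-dim auxiliary lexical vector.  The auxiliary
  vectors here are synthetic per-word fingerprints (seeded from a CRC of
  the surface); a deployment can substitute any fixed lexical resource of
  the same shape.
* Child augmentation: for each child of the token on its **original**
  sentence tree (not the subgraph), the child context is
  `chi = [child word ++ child POS ++ incoming label] ++ t_parent ++ d * w_dist`
  with `d` the signed token offset child − parent.  Two gates apply:
  a learned self-attention weight `sigmoid(chi W_e + b_e)` and the
  distance heuristic `sigmoid(beta d^2)`, `beta = -0.03 < 0`, which damps
  far children smoothly (at `|d| = 5` the gate is ≈ 0.32).  The gated
  contexts pass through `K = 100` kernel filters with ReLU and a
  filter-wise max over children; tokens without children get a zero
  augmentation vector (the neutral ReLU output).  Both gates and the
  kernel filters operate on the full 832-dim concatenated context: that is
  the one reading under which the published component sizes — an
  832→scalar attention scorer (833 parameters) and 100 filters of size
  832×1 (83,300) — are both internally consistent, and those counts are
  what the accounting tests pin down.
* Final token vector: `x = tanh([t ++ a] W_x + b_x)`.

Default dimensions (the published-scale configuration): word 300, POS
57×50, dependency type 72×150, direction 2×150, characters 85×50 with
50-unit biLSTM per direction, auxiliary 45, token transform output 300,
dependency unit 150, distance base 32, kernel filters 100, final token 595.
The inventories fold their reserved unknown row *inside* the printed table
sizes (71 named dependency labels + unknown = 72 rows; 56 POS tags +
unknown = 57; 84 characters + unknown = 85), keeping the lookup-table
parameter counts exact.  A `small()` preset (word 24, token 16, 12 kernel
filters, character/auxiliary features off) is the default for experiments
in this repository; all synthetic results are produced at that scale.

## Shared-weight CNN

`N = 128` filters per region size `r ∈ {1,2,3}` (16 in the small preset)
slide over every path of an instance, advancing one dependency unit per
step; a window of size `r` concatenates `r` token vectors and the `r−1`
dependency vectors between them.  Filter-wise pooling takes each filter's
maximum over *all* paths and *all* positions jointly, per region size,
concatenated to the feature vector `f` — so `f` is invariant to path
order and to padding, and the same filters read every path (no per-path
parameters).  There is no ReLU between convolution and pooling; the
pooled maximum feeds softmax directly.  Paths shorter than `r` simply
contribute no window at that region size; if no path offers a window, the
block is zero.

Loss: per-example cross-entropy weighted 3:1 for CID:NONE (the subgraph
representation inflates negatives to roughly 3–4 per positive, and the
weight counteracts that imbalance), plus `lambda ||theta||^2`.  Training:
Adam (step 1e-3), Glorot uniform initialization, batch 128, dropout 0.5
after the embedding and CNN layers, zero-mean Gaussian noise with scale
0.001 added to the path embeddings, a max-norm cap of 3.0 per weight row,
early stopping on development F1 with patience 5, at most 50 epochs.
`lambda = 1e-4`.  The step size, cap, patience and `lambda` are exposed
configuration with conventional defaults.  The "noise 0.001" setting is
read as a zero-mean perturbation with scale 0.001; a constant +0.001
offset would merely shift biases.  Numeric floor `1e-12` inside the log.

The model is a plain parameter tuple on a small reverse-mode autodiff
engine written for this package (float64 numpy throughout); gradient
correctness is enforced by finite-difference checks at 1e-4.

## Evaluation protocol

Micro precision/recall/F1 over (document, chemical, disease) keys;
uncovered gold pairs are automatic false negatives.  The intra/inter
split classifies a *concept pair* as intra iff some single sentence
(title included) mentions both concepts, and scores each locus with the
other locus's relations excluded.  Percentages are printed with two
decimals, half-up.  Document-level aggregation is the identity because
instance merging already leaves exactly one instance per pair.  The
strict-majority ensemble predicts CID only when more than half of the
runs do; ties go to NONE.

## The synthetic-data generator

The generator emulates the *structure* of document-level CID annotation,
not biomedical language: titles always contain a chemical mention,
documents carry 8–10 abstract sentences built from fixed dependency-tree
templates, decoy chemical/disease mentions in the early sentences create
a surplus of negative pairs (about 3 negatives per positive at test
window sizes), and planted relations are split 70/30 intra/inter — the
reported share of relations only expressed across sentences.  A planted
relation always has a trigger verb ("induces"-class) on the dependency
route between the two mention heads; negatives co-occur only through
trigger-free routes built from the same verb/adjective pools, so lexical
statistics alone cannot separate the classes.

Inter positives come in two flavors, each exercising one virtual-edge
family: next-sentence positives (chemical under a trigger root, disease
in the following sentence) route through `NEXT-SENT`; title-routed
positives mention the chemical only in the title and make the trigger the
root of the penultimate sentence, so every path at `w >= 2` runs
title → `TITLE` edge → trigger root → `NEXT-SENT` → disease.  With
single-sentence windows the `TITLE` edge attaches directly to the disease
sentence and the only route bypasses the trigger — structurally identical
to the decoy patterns — so a `w = 1` model has nothing to find there, and
removing `TITLE` edges at test time severs title-routed pairs entirely.
This is what makes window-size and edge-ablation effects observable on
synthetic data.

What passing synthetic tests does **not** show: robustness to parser
errors, to lexical variety (the trigger lexicon has four verb pairs), to
discontinuous or nested mentions, to annotation noise, or to the weak and
indirect evidence patterns of real abstracts.  The synthetic scores are a
functional check of the pipeline, not a performance claim on any real
corpus.  One known small-sample artifact: because word vectors are random
and disease surfaces are sampled, a `w = 1` model can occasionally
memorize a disease surface that happened to appear mostly as a gold
partner, producing a stray inter-sentence positive on some corpus seeds;
at the 500-document default this effect is at most a few percent of inter
recall and is absent for most seeds.

Experiment defaults on synthetic data: 500 documents split 70/10/20
train/dev/test, `w_train = 5`, `w_test = 2`, top-3 shortest paths,
`TITLE` + `NEXT-SENT` edges, the small encoder preset, 50-epoch budget.
These sizes were chosen so the whole study (two trainings plus an
ablation) runs in about a minute on a single CPU.

## Degenerate inputs and numerical choices

* Mentions overlapping no token, or crossing sentence boundaries, are
  alignment errors; nested mentions resolve by token overlap.  The
  mention head is the token whose syntactic head lies outside the mention
  (ties or none: rightmost token).
* Unknown dependency labels and POS tags map to reserved unknown rows.
* Source = target head token (same-token pair) yields no paths.
* A fully masked pooling group (no valid window) contributes zeros and no
  gradient; gradient at tied maxima is split equally among ties.
* Empty training set and diverging (NaN) loss abort with diagnostics.

## Known limitations

* Window-local: no cross-window or whole-document graph, no cross-document
  evidence.
* Coreference and KB edges are consumed as given; their published benefit
  is sensitive to input quality, and no filtering of overly general
  concepts is applied to distant-supervision documents (they enter
  training unweighted through the same pipeline).
* The published headline scores on the real benchmark corpus are outside
  desk scale (external data plus multi-hour training runs); this package
  verifies the architecture by exact accounting and oracle equivalence,
  and the pipeline by synthetic recovery.
* Pure-numpy training is practical at the small preset but slow at the
  published scale.
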