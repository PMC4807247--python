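# Methods

This note records the models, conventions and design choices behind
`forumnet`, in the spirit of a model-documentation page: what is computed,
under which assumptions, and what the synthetic data can and cannot show.

## Reply-network construction

A threaded corpus maps to a directed multigraph with exactly one edge per
message (so edge count = message count, a conserved quantity asserted in
tests):

1. the thread-opening post is a self-loop at the initiator;
2. an untargeted message points to the thread initiator (a self-loop when
   the initiator posts it);
3. a targeted reply points to the replied message's author (a self-loop
   for self-replies).

Treating the opening post as a message with a self-loop is the only
reading under which "edges + self-loops = messages" balances in published
group-scale tallies; `self_loop_census` reports the three self-loop
provenances (opening / untargeted initiator follow-up / self-reply)
separately instead of folding them into one count, since published
tallies are ambiguous about that split. Self-loops are stripped before any
structural metric; the friend graph drops direction, multiplicity and
self-loops and is idempotent under re-projection.

## Metric conventions

Published cross-network tables mix conventions, so each choice here is
pinned and stamped into `network_summary(...).notes`:

- **Density** uses the multi-edge count, self-loops excluded:
  `m/(n(n-1))` directed, `2m/(n(n-1))` undirected. The multi-edge count
  is what makes the published directed-group density (143.8×10⁻⁵ at
  n = 5050, m = 36,657) arithmetically exact.
- **Reciprocity** is the fraction of simple-projection directed edges
  whose reverse exists (the "if A replied to B, the chance B also replied
  to A" reading). The Garlaschelli–Loffredo correlation-corrected value
  is emitted as a secondary note, not the headline.
- **Clustering** is node-averaged on the *undirected simple projection*,
  degree-<2 nodes contributing 0. This is the only convention consistent
  with the published Erdős–Rényi clustering value (≈2m/(n(n-1)) ≈
  0.29×10⁻² at the group scale).
- **Shortest paths** run on the directed simple projection; the average
  is over ordered *reachable* pairs only (unreachable pairs are never
  imputed), and the diameter is the largest finite pairwise distance.
  Per-node average distance (used in the member table) is the mean over
  that node's reachable set, `NaN` when the node reaches nothing.
- **Betweenness** is normalized directed shortest-path betweenness with
  endpoints excluded (verified against exhaustive path enumeration on
  small digraphs).
- Table scalings: density ×10⁻⁵, reciprocity and clustering ×10⁻².

## Bow-Tie decomposition

Broder-style reachability semantics around the *largest* strongly
connected component: IN reaches SCC, OUT is reached from it, TUBES lie on
IN→OUT paths avoiding SCC, TENDRILS hang off IN or into OUT (one side
only), everything else is DISC. Published reply-phrased definitions
("users who only replied to members of the core") are mapped to these
standard semantics, the only reading consistent with cross-study
comparisons; note one comparison source (a Java developer forum) defines
edge direction opposite to the replier→addressee convention used here, so
its IN/OUT columns read swapped. Two deliberate choices: smaller SCCs that
meet no other criterion fall into DISC, and ties for the largest SCC break
toward the component containing the lexicographically smallest node id
(determinism). Self-loops are ignored. The implementation is multi-source
BFS (O(V+E)); tests check exact agreement with a brute-force
reachability-matrix classifier over 1,000 random ≤10-node digraphs, the
partition property on every call, and the edge-reversal duality
(IN↔OUT swap).

## Null models

- **Erdős–Rényi G(n, m)**: exactly `m` distinct edges, uniform, via
  rejection sampling of linear pair indices (no self-loops).
- **Barabási–Albert variant**: complete directed 5-clique seed (20
  edges), then each arrival adds 7 edges to existing nodes drawn by
  linear preferential attachment on total degree, every edge pointing
  new → existing. With that orientation no cycle can leave the seed, so
  the largest SCC is exactly the 5 seed nodes at any size — at n = 5050 a
  0.10% SCC and a near-total IN component, matching the published profile
  of this construction and fixing the edge-direction choice. The first
  two arrivals face fewer than 7 existing targets; the default
  "exact-count" mode draws those targets with multiplicity so the total
  edge count is exactly `20 + 7(n-5)` (= 35,335 at n = 5050, density
  138.6×10⁻⁵). A published table lists the variant's edge count as equal
  to the observed network's 36,657 while printing the density implied by
  35,335; this package follows the density-consistent construction.
- **Watts–Strogatz**: ring lattice with `k` neighbors, independent
  rewiring probability `p` (networkx implementation). The published
  description says seven neighbors with p = 0.45, but seven is odd and
  inconsistent with the published undirected edge count (17,401 ≠
  5050·7/2); the default here is k = 6, with k exposed as a parameter,
  and the lattice clustering closed form 3(k−2)/(4(k−1)) tested at p = 0.

## Power-law fitting

Discrete maximum likelihood: for each candidate lower cutoff `x_min`
(unique degrees keeping ≥25 tail points, at most 200 candidates), the
exponent maximizes the Hurwitz-zeta likelihood
`-n ln ζ(α, x_min) - α Σ ln x`; the retained cutoff minimizes the KS
distance between empirical and fitted tail CCDFs. An exact inverse-CDF
sampler (`sample_discrete_power_law`) provides simulation truth: the
estimator recovers α = 2.5 within 0.05 at n = 10⁵, with bias shrinking in
n, and the closed-form continuous MLE serves as an independent
cross-check. Degenerate inputs (constant samples, <10 positive values)
are rejected rather than fitted.

## Dictionary counting

LIWC semantics: a word may carry several category labels; each label
increments its whole ancestor chain (a "sad" word counts toward sad,
negative and affective); a token counts once toward the tagged total no
matter how many categories it hits, so the tag rate stays a token
proportion while main-category rates may sum past 100%. All rates are
percentages of the unit's total token count (the standard LIWC
denominator — not dictionary-eligible tokens only), pooled over the
unit's messages before division, so rates are invariant to message order
and concatenation. Members whose text is entirely unavailable (deleted
accounts) keep their network edges but are excluded from every linguistic
denominator. The proprietary LIWC/SC-LIWC dictionaries cannot be shipped;
the package includes a ~100-word synthetic English toy lexicon covering
all 7 main categories, affect polarity with anxious/angry/sad, and the
pronoun persons, plus a validated loader for any dictionary in the same
tab-delimited format. Chinese segmentation is out of scope: the corpus
carries pre-tokenized text, with a tokenizer-callable hook at the reader
for raw-text records.

## Integration

The member feature table joins 6 topological properties (in-degree,
out-degree, threads created, per-node average shortest path, betweenness,
clustering) with 13 linguistic ones (word count, 7 main categories,
positive, negative, three pronoun persons), one row per member with
available text. Spearman correlations use average ranks on ties and
pairwise-complete observations (members with undefined per-node distance
are dropped per pair, not imputed; constant columns yield flagged `NaN`);
monotone-transform invariance is asserted, so log-scaling for display
never changes coefficients. The affect comparison is a two-sample
negative-vs-positive test among members using both polarities; published
degrees of freedom at group scale match neither the paired nor the pooled
layout exactly, so the unequal-variance (Welch) statistic is the headline
and the pooled-variance one is always reported alongside. Convergence
curves use equal-occupancy bins (20 by default — equal-width bins
degenerate under heavy-tailed topological columns), and the "two-phase"
shape is operationalized as the longest non-decreasing prefix / non-increasing
suffix of the bin means plus the argmax turning bin.

## Synthetic corpus generator

The generator emulates the structure of a large single-disease
depression-support group; its defaults are the study conditions, chosen
once:

- **Scale**: 5,050 members, 3,700 threads, deleted-account fraction
  37/5050 (structure kept, text dropped).
- **Thread participation**: mode forced to 2 (an initiator plus one
  replier) via `1 + Zipf(2.0)` truncated at 276 participants, with a 15%
  single-participant share. No published participant law exists; the
  shape targets the reported mode-at-2, heavy tail and cap.
- **Message volume**: each replier posts `1 + Poisson(2.2)` messages,
  initiators add Poisson(0.04) untargeted follow-ups; a reply targets a
  specific earlier message with probability 0.35, else the thread at
  large. The Poisson mean was calibrated once so that total messages
  center on the reported 40,357 (20 replicates: mean ≈ 40.9k, SD ≈ 2k)
  and then frozen; the scale test accepts ±6,000 messages (≈ mean ± 3 SD).
- **Activity**: member propensities `1 + Pareto(1.3)`; initiators and
  repliers are drawn proportionally, which induces the real-data coupling
  between posting volume, in-degree and text volume that the correlation
  tests recover.
- **Text**: per-member token-class mixtures drawn from a Dirichlet
  (concentration 48) around means with function words ≈ 48%, cognitive
  8%, relativity 6%, negative affect 4.5% > positive 4.0%, first-person
  pronouns 5.5% dominating second (1.2%) and third (1.8%), and an
  untagged filler share giving a corpus tag rate in the mid-70% range.
  Message lengths are lognormal (median 40 tokens). Short texts naturally
  produce members using only one or neither affect polarity.

What the generator does **not** emulate: calendar-time dynamics and
membership churn, topic structure and semantics (tokens are exchangeable
draws, so topic models or sequence effects cannot be studied), real
Chinese text (the toy lexicon is English), and the exact empirical
participant/degree laws of any particular platform. Tests passing on
generator output therefore validate the *pipeline's* correctness and the
qualitative couplings, not any platform-specific empirical value.

## Problem sizes and determinism

Every stochastic component takes an explicit seed; fixed seeds give
byte-identical outputs (asserted end-to-end). The reproduction script
uses the published network scale (n = 5050, m = 36,657) with 10
Erdős–Rényi replicates for SCC share and clustering and 5 for average
shortest path — at that scale the replicate SD is ~0.06 percentage points
for the SCC share, so 5–10 replicates pin the mean well below the
comparison slack. Unit tests run at a few-hundred-member scale, where the
full pipeline completes in seconds.

## Known limitations

- The observed group's empirical values (reciprocity 34×10⁻², SCC 54.53%,
  degree exponents 2.13/2.20, the member-level correlation matrix) depend
  on a non-deposited corpus; they live in `forumnet.reference` as
  documented constants and are not reproduction targets.
- `fit_power_law` assumes an i.i.d. tail sample; degree sequences of a
  single graph violate independence mildly, as in all standard practice.
- Betweenness is exact (Brandes via networkx) and O(nm): fine at
  5k nodes, slow beyond ~10⁵ edges.
- The Bow-Tie DISC class absorbs secondary SCCs by design; analyses that
  need those separately should consume the full per-node class map plus
  `networkx.strongly_connected_components`.
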