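# Methods

This note records the model, the numerical and design choices behind
`netloc`, and what the synthetic experiments do and do not establish.

## Model and procedure

The package treats a PPI network *G* = (*V*, *E*) as an undirected simple
graph over opaque string IDs (compared exactly, no case folding). Three
annotation sources assign each protein a subset of a fixed, ordered 11-term
compartment vocabulary (Cell membrane, Cytoplasm, ER, Extracell, Golgi,
Mitochondrion, Nucleus, Peroxisome, Lysosome, Endosome, Microsome):
experimental locations SCL and two sequence-predictor outputs MP and YC.
"Unknown" is the empty set everywhere — there is no sentinel term, and a
protein absent from a table behaves identically to one assigned ∅.

Prediction for a protein *p_u* with no experimental annotation proceeds in
four steps, per source *src* ∈ {SCL, MP, YC}:

1. **Neighbor location probability.** P_k = (number of src-annotated
   neighbors carrying l_k) / (number of src-annotated neighbors); 0 when no
   neighbor carries a src annotation.
2. **Membership degree.** m_src(p_u, l_k) = exp(P_k) · Σ ECC_N(p_u, p_v)
   over neighbors v carrying l_k. The exponential amplifies locations
   frequent among annotated neighbors; the ECC_N sum concentrates credit on
   densely embedded partners. m = 0 exactly when no neighbor carries the
   location, and adding a carrying neighbor with positive weight strictly
   increases it.
3. **Per-source thresholding.** NET_src = {l_k : m_src ≥ C · max_k m_src}
   (inclusive, so the argmax always survives), forced to ∅ when max = 0 or
   when fewer than θ_src neighbors carry a src annotation.
4. **Combination.** SEQ = MP(p_u) ∪ YC(p_u); NET = NET_SCL ∪ NET_MP ∪
   NET_YC; PRED = (NET ∩ SEQ) ∪ {l_k attaining the maximal membership in
   every source whose membership vector is not identically zero}; if PRED =
   ∅, the fallback source's direct prediction (MP by default) is used.

ECC(p_i, p_j) = z_ij / min(d_i − 1, d_j − 1), with the convention ECC = 0
when the denominator is 0: no triangle is possible, so the edge carries no
clustering evidence. ECC_N(p_u, p_v) divides ECC by the sum of ECC over
p_u's incident edges, so each neighborhood's weights sum to 1; when every
incident ECC is 0 the weights fall back to uniform 1/|NE(p_u)|, degrading
gracefully to unweighted neighbor voting. ECC_N is deliberately asymmetric:
the weight an endpoint assigns depends on its own neighborhood. Each of
these functional forms lives in a single function
(`PPINetwork.ecc_normalized`, `predictor._membership_form`, `combine`) so an
alternative can be swapped in without touching callers.

### Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| C | relative membership threshold, [0, 1] | 0.75 | higher C → smaller NET_src (monotone) |
| θ_SCL | min. experimentally annotated neighbors | 1 | gate for the SCL source |
| θ_MP, θ_YC | min. predictor-annotated neighbors | 60 | at realistic degrees this gates the sequence-source network paths off, leaving NET ≈ NET_SCL |
| fallback | source answering when PRED = ∅ | MP | the stronger base predictor |

The defaults are the grid-calibrated values for the human dataset (grid:
C 0.5–0.95 step 0.05, θ_SCL 1–20 step 1, tied θ_MP = θ_YC 10–100 step 10;
2000 trials). Raising C or any θ can only shrink or empty the per-source
sets, never grow them — a property the test suite asserts.

### Evaluation

Jackknife: every SCL-annotated protein in the network is re-predicted with
its own experimental labels hidden (the four steps never consult the target
protein's own SCL entry, so no table copy is needed); neighbors keep their
annotations. Metrics: AIM = mean |P∩T|/|P|, CVR = mean |P∩T|/|T|,
ACC = mean |P∩T|/|P∪T|, ATR = fraction with P = T, AFR = mean |PΔT|/m. A
protein with P = ∅ contributes 0 to AIM rather than being skipped, which
would inflate precision; the fallback rule makes empty predictions rare.
ACC ≤ min(AIM, CVR) and ATR ≤ ACC hold per protein and hence after
averaging; AFR = 0 iff ATR = 1. Metrics are reported to 3 decimals;
internal comparisons use the unrounded values. Grid search enumerates
C-outer / θ_SCL-middle / tied-θ-inner and keeps the first configuration
attaining the maximal objective (default ATR; AFR is minimized), making tie
resolution deterministic.

Per-location ("locative-protein") accuracies are deliberately not provided:
they are inconsistent with the exact-match rate that anchors the evaluation.

### Co-localization profile

Edges whose endpoints are both experimentally annotated get a Jaccard
co-localization score Q; Q is undefined (and the edge excluded) when either
endpoint is unannotated. Edges are binned by ECC into left-closed
right-open bins over [0, 1), with ECC = 1.0 folded into the last bin — it
occurs on cliques, and excluding it would silently drop data. The linear
fit and Pearson r are computed on the nonempty bins' (mean ECC, mean Q)
points; a raw per-edge fit is available behind a flag. With fewer than two
nonempty bins the fit is omitted; with zero variance in either coordinate
slope and r are set to 0 by convention.

## Synthetic data

`simulate` generates planted-partition graphs (networkx stochastic block
model; community sizes differ by at most one) in which every within-pair
connects with probability `p_within` and cross-pairs with `p_between`. Each
community draws a primary compartment (without replacement while terms
last), each protein's true set is its community primary plus uniform extras
with set size drawn from a multiplicity distribution defaulting to
{1: 0.70, 2: 0.25, 3: 0.04, 4: 0.01} — matching the observed shape of human
annotation multiplicity (~70% single-location, mean ≈ 1.4). Experimental
tables copy the truth on a random half of the proteins
(`annotation_coverage` = 0.5, the observed human coverage); simulated base
predictors flip each of the 11 labels independently with probability
`predictor_error` = 0.2 on a `predictor_coverage` = 0.9 fraction of
proteins. A covered prediction emptied by the flips is back-filled with one
uniformly drawn true term, mirroring base predictors that always emit at
least one location. All draws derive from a single integer seed.

The study conditions used by the acceptance checks are 1000 proteins, 10
communities, p_within 0.3, p_between 0.01, coverage 0.5, error 0.2, over 10
seeds; these sizes keep the full multi-arm benchmark under a minute while
giving ~500 jackknife targets per dataset. The negative control sets both
edge probabilities to the density-matched value p ≈ 0.039 (the positive
configuration's expected degree with the community contrast removed), so
community structure is the only manipulated variable. "No material gain" is
read as a mean exact-match advantage of at most 0.05 over the fallback
predictor.

What the generator does *not* emulate: the heavy-tailed degree distribution
of real interactomes, correlated (non-independent) predictor errors,
compartment co-occurrence structure beyond the planted primary, and
annotation bias toward well-studied proteins. Passing benchmarks therefore
demonstrate that the algorithm exploits community-correlated localization
when it exists — not that it attains any particular performance on a real
proteome.

Benchmark arms: each base predictor scored directly against the held-out
experimental truth, the meta-predictor with a single base predictor, and
with both. A single-predictor meta arm places the lone source in the MP
slot so it also serves as the fallback. Iterative prediction feeds each
round's full output (experimental pass-throughs included) back in as the
sole MP-slot source with the YC slot emptied; determinism makes any repeat
of a round a permanent fixed point, and on synthetic data the output
typically stabilizes at round 2.

## Known limitations and degenerate inputs

- With multi-location truths, the relative threshold C prunes rare
  secondary locations, bounding the exact-match rate near the
  single-location fraction; this is a property of the thresholding rule,
  not of the implementation.
- The set-intersection combination can produce small exact-match gains even
  on contrast-free networks (intersecting with an essentially random
  network set sparsifies noisy sequence predictions); the density-matched
  negative control bounds this effect.
- Empty networks, isolated proteins and fully unannotated sources are
  legal: probabilities and memberships are 0, per-source sets are ∅, and
  the fallback answers. Jackknife requires at least two annotated proteins.
- ECC caches per network instance assume the graph is not mutated after
  construction; all public constructors build immutable-by-convention
  networks.
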