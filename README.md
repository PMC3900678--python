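# netloc

Network-based meta-prediction of human protein subcellular localization.

Knowing which subcellular compartment a protein occupies — nucleus,
cytoplasm, ER, mitochondrion, … — is a key hint to its function, but
experimental annotation lags far behind sequencing. Sequence-based
predictors fill some of the gap; `netloc` goes one step further and uses the
protein–protein interaction (PPI) network as an *infrastructure for
combining predictors*: when calling a protein's locations it weighs the
experimental annotations and sequence-based predictions of all its
interaction partners, with each partner's vote weighted by how densely
embedded the connecting interaction is. The package is aimed at
computational biologists who have an interaction network plus per-protein
location tables (experimental and/or predicted) and want integrated
multi-label location calls, with the evaluation and calibration machinery to
go with them.

## The method

**Edge clustering coefficient.** For an interaction between proteins
*p<sub>i</sub>* and *p<sub>j</sub>* with degrees *d<sub>i</sub>*,
*d<sub>j</sub>* and *z<sub>ij</sub>* triangles through the edge,

```
ECC(p_i, p_j) = z_ij / min(d_i − 1, d_j − 1)
```

— the fraction of possible triangles the edge actually closes (defined as 0
when no triangle is possible). Interacting proteins connected by high-ECC
edges tend to share compartments, which `netloc` quantifies with the
co-localization score *Q<sub>ij</sub>* = |SCL(p<sub>i</sub>) ∩
SCL(p<sub>j</sub>)| / |SCL(p<sub>i</sub>) ∪ SCL(p<sub>j</sub>)| and its
ECC-binned profile. For weighting, ECC is renormalized over each protein's
incident edges (ECC_N, asymmetric, summing to 1 per neighborhood).

**Meta-prediction.** Three annotation sources share an 11-term vocabulary:
experimental locations (SCL) and two sequence predictors (MP, YC). For an
unannotated protein *p<sub>u</sub>* with neighborhood NE(*p<sub>u</sub>*),
each source contributes per location *l<sub>k</sub>* a membership degree

```
m_src(p_u, l_k) = exp(P_k) · Σ_{v ∈ NE(p_u), l_k ∈ src(v)} ECC_N(p_u, p_v)
```

where *P<sub>k</sub>* is the fraction of src-annotated neighbors carrying
*l<sub>k</sub>*. Locations with membership ≥ *C* · max<sub>k</sub>
m<sub>src</sub> form the per-source network prediction NET_src, gated to ∅
unless at least θ_src neighbors carry a src annotation. The final call is

```
PRED = (NET ∩ SEQ) ∪ {l_k attaining max membership in every source with evidence}
```

with NET = NET_SCL ∪ NET_MP ∪ NET_YC and SEQ = MP(p_u) ∪ YC(p_u), falling
back to the stronger sequence predictor (MP) when empty. Defaults are the
calibrated values *C* = 0.75, θ_SCL = 1, θ_MP = θ_YC = 60.

**Evaluation.** Multi-label measures over *n* proteins and *m* = 11 labels:
aiming (precision), coverage (recall), accuracy (Jaccard), absolute-true
rate (exact-match/subset accuracy) and absolute-false rate (Hamming loss),
computed under a jackknife protocol that hides each annotated protein's
experimental labels in turn; grid search calibrates (C, θ_SCL, tied
θ_MP=θ_YC) against any of these objectives.

A synthetic-data module generates planted-partition networks whose
communities share a primary compartment, with configurable experimental
coverage and per-label predictor noise, for end-to-end validation of the
whole pipeline.

## Worked example

```python
from netloc import PredictorConfig, predict_all
from netloc.simulate import SimulationConfig, simulate_dataset

config = SimulationConfig(n_proteins=300, n_communities=6, p_within=0.3,
                          p_between=0.02, seed=7)
sim_net, ann = simulate_dataset(config)
result = predict_all(sim_net.network, ann.scl, ann.mp, ann.yc,
                     PredictorConfig())
```

Running `python examples/predict_locations.py` (the same computation plus a
per-protein trace) prints:

```
155 of 300 proteins lack experimental annotations; predictions made for all of them
exact-match recovery on the unannotated proteins: 111/155 = 0.72
protein P002: NET_SCL=['Endosome'], SEQ=['Cytoplasm', 'Endosome', 'Extracell', 'Mitochondrion', 'Nucleus', 'Peroxisome']
  -> PRED=['Endosome'] via condition1 (truth: ['Endosome'])
```

72% of the held-out proteins are recovered *exactly* (every location right,
none extra) even though the simulated base predictors flip each label with
probability 0.2 — the trace shows why: the network narrows six noisy
sequence-predicted locations down to the one its annotated neighbors
support. The other scripts in `examples/` each demonstrate one capability
(interaction filtering and ECC, annotation cleaning and multiplicity
arithmetic, the Q–ECC profile, jackknife + grid search, and the multi-arm
benchmark); a `netloc` command-line interface exposes the same operations
for shell pipelines (`netloc --help`).

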