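# Methods

## Model

`snmtfvar` classifies missense variants as deleterious or neutral by
supervised non-negative matrix tri-factorization over fused data sources.
The two-source model factorizes the variant×score relation matrix R_VS
(m×n, entries in [0,1]) and the label vector Y (m×1, binary) in one shared
variant basis,

    J_tr = ‖R_VS − V U Sᵀ‖²_F + ‖Y − V U G_Yᵀ‖²_F
           + γ₁ tr(Vᵀ L_V V) + γ₂ tr(Sᵀ L_S S),

with V (m×k_V), U (k_V×k_S), S (n×k_S) and G_Y (1×k_S) all non-negative.
The three-source model adds ‖R_VD − V U₂ Dᵀ‖²_F and γ₃ tr(Dᵀ L_D D), where
R_VD (m×n_D) marks which diseases are associated with a variant's gene, U₂
is k_V×k_D and D is n_D×k_D. Sharing V across every reconstruction term is
what fuses the sources: variant clusters must simultaneously explain score
profiles, labels, and disease annotations, while the Laplacian penalties
pull network-linked variants (and similar scores, and co-occurring
diseases) toward nearby latent representations. The trace terms are
written in the canonical orientation tr(Xᵀ L X) — the factor's row
dimension must match the Laplacian — since any other pairing is
dimensionally inconsistent.

At test time S, G_Y (and D) are frozen. The test objective keeps only the
reconstruction of the test-side relation matrices and the test-side
variant-network penalty; minimizing it over V_ts embeds the unseen
variants into the learned cluster space, and the continuous
deleteriousness score is y = V_ts U G_Yᵀ (U₁ for the three-source model).

### Input normalization

Each constituent score is min–max rescaled to [0,1] (per column:
(A−A_min)/(A_max−A_min)). SIFT and LRT are flipped to 1−A first because
their minima mean most damaging. Bounds are fitted on training data only;
test values outside the training range are clipped into [0,1], keeping
R_VS non-negative. A constant training column maps to 0.5 everywhere — an
uninformative score should not push predictions either way. Rows with any
missing score are dropped before modeling.

### Networks

* **Variant–variant**: variants on one gene with n ≥ 2 variants form a
  clique with edge weight 1/(n−1), so each variant's same-gene weighted
  degree is exactly 1 regardless of annotation density; variants on
  different genes whose proteins interact inherit the PPI confidence as
  edge weight, without any 1/(n−1) division (that correction belongs to the
  weight-one same-gene edges only). STRING-style confidences on the 0–1000
  scale are rescaled to [0,1]; edges at or below confidence 0.15 are
  dropped. Genes sharing a protein are not auto-connected.
* **Score–score**: the Manhattan distance d(j,k) = Σᵢ|R_ij − R_ik| between
  score columns is converted to the similarity w = 1 − d/m, because a
  Laplacian penalty pulls *strongly connected* nodes together — using raw
  distance as an edge weight would smooth dissimilar scores toward each
  other. The raw distance matrix is kept as graph metadata and
  `ss_weight="distance"` restores it as the edge weight for comparison.
* **Disease–disease**: the Jaccard index of the two diseases' associated
  variant sets (variants inherit associations from their genes); pairs of
  empty sets get weight 0.
* All Laplacians are unnormalized, L = Deg − W. The unit-degree design of
  the variant network makes the unnormalized and random-walk forms nearly
  coincide there.

### Optimization

Factors are initialized by random Acol (each column of V₀ averages
`init_p` = 5 randomly chosen columns of R; S₀ and D₀ analogously from
rows; U factors uniform(0,1]; everything offset by eps = 1e−10 so
multiplicative updates can move any coordinate). Each factor X is then
updated multiplicatively, X ← X ⊙ numerator/(denominator + eps), where the
numerator collects the positive gradient parts (e.g. for V: R S Uᵀ +
Y G_Y Uᵀ + γ₁ W_V V) and the denominator the negative parts
(V U SᵀS Uᵀ + V U G_YᵀG_Y Uᵀ + γ₁ Deg_V V), with every Laplacian split as
L = Deg − W so both sides stay non-negative. This is the standard
graph-regularized tri-factorization scheme; its correctness is enforced in
the test suite by the monotonicity property (objectives never increase
beyond 1e−9 relative slack on random instances) rather than by matching
any particular printed algebra.

Iteration stops when |J_t − J_{t−1}|/max(J_{t−1}, eps) < tol (default
1e−5) or after `max_iter` = 200 iterations. Because the objective is
non-convex and multiplicative updates occasionally stall in poor local
optima (observed: isolated evaluation folds dropping from AUC 1.00 to
≈0.82 under one unlucky initialization), training runs `n_restarts` = 5
independent initializations and keeps the run with the lowest final
training objective. Restart selection never sees test data.

**Test-time factor handling.** V_ts is initialized by random Acol on the
test relation matrix. The interaction factors U/U₁/U₂ are by default
*reused* from training (`reuse_u=True`) rather than re-estimated: U₁
carries the mapping from variant clusters to labels learned jointly with
G_Y, and re-fitting it against the test reconstruction alone — an
objective with no label term — systematically discards that supervision
(measured as a drop in held-out AUC for the three-source model, 0.67 →
0.54 at score signal 0). Warm-started re-estimation remains available via
`reuse_u=False`. Prediction deliberately uses the same early-stopping
rule as training; running the test-phase optimization to much tighter
tolerances lets V_ts overfit the reconstruction and degrade ranking.

### Hyper-parameters

| name | default | meaning |
|---|---|---|
| k_V, k_S, k_D | 10, 3, 5 | variant / score / disease cluster counts |
| γ₁, γ₂, γ₃ | 1.0 | V–V, S–S, D–D Laplacian weights |
| max_iter, tol | 200, 1e−5 | stopping rule |
| n_restarts | 5 | random restarts, best training objective kept |
| init_p | 5 | Acol columns averaged per factor column |
| reuse_u | True | freeze trained U factors at test time |

γ = 1.0 puts the penalties on the same order as the reconstruction terms
(‖R_VS‖²_F ≈ 2m for m variants, while tr(Vᵀ L_V V) is O(m) under the
unit-degree variant network). `grid_search` implements the prescribed
selection procedure — maximizing mean gene-aware CV AUC over a grid
(default k_V ∈ {5,10,20,50}, k_S ∈ {2,3,5}, γ ∈ {0.01,0.1,1,10}) — for
users who want per-dataset tuning.

### Evaluation protocol

Folds are gene-partitioned: genes are shuffled under the run seed and
dealt into k near-equal groups, and variants inherit their gene's fold, so
no gene ever spans the train/test boundary. The default protocol is
10-fold CV; metrics are aggregated as mean and variance across fold×repeat
cells. The binary-call threshold maximizes Youden's J (sensitivity +
specificity − 1; an F1 criterion is available) over candidate cuts, always
on *training* variants — scored through the test-time inference path, so
the cut lives on the same scale as held-out scores (training-phase
reconstructions V U G_Yᵀ are systematically sharper than test-phase
scores and would mis-place the cut). AUC uses the midrank Mann–Whitney
convention (ties count ½); MCC reports 0 when a factor under its square
root vanishes; precision reports 0 with a warning when nothing is called
positive. The pure/mix gene partition (a gene is "mix" iff it carries both
label classes) and the pathogenic-gene mask (≥1 disease association)
support stratified reports for circularity diagnostics.

## Synthetic data generator

The generator emulates the five input tables with planted structure:

* **Scores**: R = V*U*S*ᵀ + truncated Gaussian noise (sd `noise_sd`,
  clipped to [0,1]). V* is a one-hot variant-cluster indicator; clusters
  are label-designated, and the planted core U* places deleterious
  clusters at (1+signal)/2 and neutral ones at (1−signal)/2, so the mean
  normalized score of deleterious minus neutral variants equals `signal`.
  A small per-cluster jitter of amplitude 0.05·signal·(1−signal)
  differentiates the planted score clusters without leaking label
  information at either signal extreme. Raw files are written on realistic
  per-predictor scales with SIFT and LRT damaging-descending, so ingestion
  must exercise the flip and normalization logic.
* **Labels**: genes are filled whole until the deleterious quota
  round(label_balance·m) is met; the boundary gene is split, producing
  exactly one natural "mix" gene per dataset and an exact balance.
* **PPI**: gene modules coincide with the planted variant clusters;
  within-module gene pairs receive edges with probability `ppi_density`
  and confidences uniform(0.15, 1].
* **Diseases**: each of a fraction `disease_informative_fraction` of
  deleterious genes associates with about half of its module's disease
  pool (at least one), so module diseases co-occur across genes and the
  disease–disease Jaccard network has planted block structure; noise pairs
  (10% of informative pairs) are drawn uniformly.
* An optional `missing_rate` plants one missing cell per affected row to
  exercise filtering.

Defaults: 40 genes × 5–15 variants (≈400 variants), 9 scores, 20 diseases,
4 variant clusters, signal 0.6, noise 0.1, ppi_density 0.3, label balance
0.4 (roughly the deleterious fraction of common benchmark compilations).

**What the generator does not emulate, and what passing tests therefore do
not show**: real constituent predictors are strongly correlated per
variant, while the generator's cell noise is independent, which makes a
nine-score panel more informative here than in real data; PPI modules are
perfectly aligned with label-pure variant clusters, making the variant
network a much cleaner gene-level signal than a real interactome; allele
frequencies, mutation spectra and per-gene annotation biases are absent.
Results on this benchmark demonstrate mechanism (the model recovers
planted structure through the intended channels), not clinical accuracy.

A consequence worth stating plainly: under these defaults the label-pure
PPI modules let the two-source model pool even a weak score signal across
whole modules, so its held-out AUC saturates near 1.0 once γ₁ is
well-chosen, and the disease source has no headroom to demonstrate an
advantage — the two- vs three-source comparison on this generator is a
near-tie, with the three-source model additionally paying a genuine
circularity cost on the mix gene (its neutral variants sit on a
disease-annotated, majority-deleterious gene). The disease channel itself
is demonstrably exploited: with the score signal removed entirely and
diseases fully informative, the three-source model reaches held-out AUC
≈0.67 against ≈0.48 for the two-source model.

## Numerical choices and degenerate inputs

* eps = 1e−10 guards every update denominator and the relative-change
  stopping rule.
* Non-finite objectives raise a numerical error advising smaller γ.
* Empty test sets return empty predictions; an all-zero test row with
  γ₁ = 0 admits the zero factor row as a fixed point and predicts 0.
* Jaccard weight for two diseases with empty variant sets is 0; constant
  score columns normalize to 0.5; variants on unmapped or association-free
  genes get zero network degree / zero R_VD rows and are handled as
  isolates.
* Threshold ties break toward the higher cut (the more conservative
  deleterious call).
* `max_iter=0` returns the initialization with a length-1 objective trace.

## Known limitations

* Multiplicative updates converge slowly near optima; restarts mitigate
  but do not eliminate local-optimum sensitivity.
* The mix-gene circularity cost of gene-level disease information is
  inherent to the model class, not a bug: neutral variants on pathogenic,
  disease-annotated genes are the hardest case.
* Scores for the two phases of the model (training reconstruction vs
  test-time embedding) live on different scales; all thresholds are
  therefore calibrated on the test-time path.
* The CLI assumes one gene per variant; multi-gene annotations must be
  resolved upstream. Overlap removal between user-supplied train/test sets
  is provided as an explicit utility (`snmtfvar.ingest.remove_overlap`),
  never applied implicitly.
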