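# Methods

## The model

`paqnn` predicts proton affinity (PA, kcal/mol) from a numeric
descriptor vector with a hybrid quantum-classical network:

1. **Feature scaling.** Each descriptor is min-max scaled on the
   training split to [0, π] so it can serve as a rotation angle
   (angle encoding). Out-of-range values at prediction time are clamped
   to the boundary.
2. **Patch encoding.** The scaled vector is split into S contiguous
   blocks of equal size. S structurally identical circuits on Q qubits
   — one per block, each with its own N_Params trainable rotation
   angles θ — embed their block and are measured qubit-wise in the
   Pauli-Z basis. The S·Q expectations are concatenated. Keeping each
   circuit small means few qubits and no long-range entanglement; the
   circuits can be evaluated sequentially or in parallel.
3. **Classical head.** Three fully connected layers with dimensions
   (n, n/2), (n/2, n/4), (n/4, 1) for n = S·Q (integer division, one
   bias per output unit), leaky-ReLU hidden activations and a sigmoid
   on the output. Targets are min-max scaled to [0, 1] on the training
   split, so the sigmoid output maps back into the fitted PA range
   through the inverse scaler — predictions cannot leave the training
   range by construction.

The trainable parameter count decomposes exactly as
`S·N_Params + Σ_layers (in·out + out)`; with integer-division layer
widths this reproduces e.g. 225 parameters for (S=4, Q=4, N_Params=12,
16 features) and 2625 for a classical head consuming 64 raw features.
One published configuration (4 qubits, 16 features, 2 subencoders, 20
params/circuit, printed total 153) is inconsistent with this
decomposition, which reproduces every other configuration exactly; it
is excluded from the accounting checks.

### Simulation and gradients

The simulator is an exact statevector implementation (complex128,
qubit 0 = most significant basis-index bit) over the gate set
{RX, RY, RZ, X, H, CNOT, CZ}, with rotations in the half-angle
convention. It is vectorized over batches of encoding angles, and the
parameter-shift rule — `(f(θ+π/2) − f(θ−π/2))/2` per rotation-gate
occurrence, occurrences of a shared slot summed — evaluates all shifted
circuits of a batch in a single pass. Correctness is pinned by two
independent oracles in the test suite: a dense Kronecker-product
unitary builder (agreement to 1e−10 on random circuits up to 4 qubits)
and central finite differences for gradients (1e−6).

### Default ansatz

When no explicit circuit is supplied, the encoder circuit is built as
re-uploading rounds: per round, a CZ entangling ring (omitted before
the first round), one RY encoding gate per wire for the next block of
feature slots, then a trainable-RY layer, repeated until exactly
N_Params trainable gates are placed. Two properties motivated placing
diagonal (CZ) entanglers *between* rotation layers rather than CNOT
rings *after* them:

* At all-zero trainable angles the circuit reduces exactly to the
  per-wire cosine map ⟨Z_q⟩ = cos(x_q) (paired CZ layers cancel), so
  training starts from an embedding that provably preserves the
  feature information — an identity-block initialization. Empirically,
  CNOT-ring circuits at random or zero angles collapse most of the
  recoverable signal in the Z-marginals (a gradient-boosting probe on
  the encoded features loses half the explainable variance), while the
  CZ layout keeps it intact and activates entanglement smoothly as the
  angles grow.
* The layout reproduces the depth/gate-count magnitudes of
  hardware-efficient encoders at every configuration used in the
  accounting checks.

### Training

Adam (β₁ = 0.9, β₂ = 0.999) minimizes mean-squared error on the scaled
targets; head gradients come from backpropagation and circuit-angle
gradients from the parameter-shift rule chained through the head's
input layer. Defaults, all exposed in `TrainConfig`:

| parameter | default | rationale |
|---|---|---|
| learning rate | 2e−2 | fastest stable convergence in pilot runs on the synthetic sets |
| epochs | 300 | training loss plateaus well before this on n ≈ 400 |
| batch size | 32 | standard; SGD noise helps leave saddle regions |
| θ init | uniform(−0.1, 0.1) | near the identity-transparent point of the ansatz |
| l1_penalty | 2e−3 (first head layer) | prunes uninformative subencoder outputs instead of letting the head memorize them |
| leaky slope | 0.4 | strong leak keeps gradients flowing through the very narrow head |
| n_restarts | 3 | the joint loss surface is multimodal (below) |
| split ratio | 8:2 | train/test convention used throughout |

Restarts are independently initialized (seeded as `[seed, restart]`)
and ranked by final training loss; `target_train_r2` optionally stops
restarting once the training fit explains the requested variance
fraction — a stopping rule that looks only at training data. A NaN/inf
loss aborts with diagnostics rather than continuing silently.

**Multimodality.** On the synthetic benchmark the joint optimization
has two basins: a "linear-only" plateau where the model captures the
planted linear terms but not the sine (training R² ≈ 0.72), and the
full solution (training R² ≥ 0.9, held-out R² ≈ 0.9–0.96). Which basin
a run reaches depends on the random stream; roughly a third of
initializations escape the plateau within 300 epochs. A head-only
control — the same three-layer head trained directly on the noiseless
cosine features for 2000 epochs — never escapes, which shows the escape
is driven by the trainable circuit reshaping the embedding, not by the
head alone. This is why restarts-with-selection is part of the
training protocol rather than an afterthought; with 8 restarts most
random streams reach the full solution, but some do not, and a run
that ends on the plateau is reported as-is (no hidden reruns).

## Synthetic data

Real PA compilations cannot be redistributed, so the package generates
its own study material:

* **Regression sets.** X ~ U(0,1)^{n×p}; the planted target is
  `f(x) = offset + scale·(3x₀ + 2x₁ − 1.5x₂ + x₃ + 1.2·sin(2πx₀))`
  affinely mapped onto [150, 260] kcal/mol, plus optional Gaussian
  noise. The form, coefficients and signal columns are recorded in
  `signal_spec` so tests recompute the ground truth independently. The
  sine makes the target deliberately non-monotone in the dominant
  feature — a single-frequency angle embedding cannot represent it
  linearly, so the benchmark genuinely exercises the trainable
  encoder. All columns beyond the first four are pure distractors.
* **Fingerprint sets.** k cluster prototypes (bit density 0.3) with
  i.i.d. bit flips per member; flip rates ≥ 0.5 are rejected because
  they erase the planted structure by construction.

What passing on this material does *not* show: real descriptor
distributions are heavy-tailed and strongly inter-correlated, real
structure–PA relationships are not four-term closed forms, and MACCS/
Morgan fingerprints of real molecules are far sparser than the
synthetic prototypes. Accuracy figures on the synthetic sets therefore
validate the machinery (gradients, protocol, leakage-freedom), not
chemical accuracy. Published cross-validation accuracies on the
curated experimental compound set are out of desk-reproduction scope —
they require the original compounds and DFT-level descriptor values —
and are replaced here by the property-based suite.

## Protocol details and numerical choices

* **Curation.** Elements outside {C, H, N, P, O, S}, unparsable
  SMILES, and radicals (any atom with unpaired electrons after valence
  perception) are removed; the rejection reason is logged, never
  raised. Stereoisomer groups — records sharing a canonical
  stereo-stripped structure — are merged to their mean PA when their
  spread is < 1 kcal/mol, else all members are kept. Survivors keep
  input order.
* **Descriptor filter.** Order: missing values → variance ≤ var_tol
  (default 1e−8) → pairwise |Pearson r| ≥ 0.9, walking pairs in fixed
  column order and dropping the later column (deterministic
  tie-break). The filter is idempotent.
* **Feature selection.** XGBoost gain importances rank the columns;
  top-k, or progressive removal of the least important until the
  evaluation MAE worsens by > 5% relative to the best seen (both
  thresholds exposed).
* **Scalers.** Fitted on training folds only and applied to held-out
  folds; the z-score, [0, π] and [0, 1] variants share one `ScalerSpec`
  with exact round-trip inversion on the fit range.
* **Cross-validation.** Per iteration i the data are reshuffled with
  seed `seed + i` and split into k folds; each sample is predicted
  exactly once per iteration and metrics are aggregated as
  mean ± std over iterations (population std). Baseline learners run
  inside pipelines so fold-local scaling can never leak.
* **Metrics.** R² = 1 − SS_res/SS_tot; for a constant target R² is
  reported as NaN (undefined marker) while MAE/RMSE are still
  computed. Correlation of encoded features with the target is Pearson
  by default (Spearman available); constant columns are NaN, never 0.
* **Butina.** Neighbor lists at similarity ≥ cutoff; the unassigned
  item with the most unassigned neighbors becomes the next centroid,
  ties resolved to the lowest input index for determinism. Verified
  against an independently written brute-force leader implementation
  on random instances up to n = 50.
* **Tanimoto.** `c/(a+b−c)` on set-bit counts; two empty fingerprints
  raise rather than silently returning 0.

## Known limitations

* The statevector simulator is exact but dense: memory and time scale
  as 2^Q, and the implementation caps Q at 14.
* No shot noise, device noise, transpilation or hardware execution is
  modeled; all results correspond to the noiseless-simulator setting.
* The restart protocol makes training cost stochastic (early stopping
  on the training fit shortens lucky runs); worst-case cost is
  n_restarts × epochs.
* `select_by_importance` inherits XGBoost's tree-construction
  determinism guarantees; it is deterministic for a fixed seed and
  version but rankings can change across xgboost releases.
* The quantum-chemical descriptor columns (ε_HOMO, ε_LUMO, chemical
  potential, hardness, dipole moment, MK/CM5 charge minima) are
  consumed as externally supplied numbers; computing them is outside
  the package's contract.
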