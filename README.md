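# dualbind

Sequence-based antibody–antigen binding-affinity prediction with a
dual-level protein representation: a **residue-to-residue interaction
module** that models local interface contacts, and a **global stochastic
projection embedding** that captures whole-chain composition, fused by a
feed-forward head that regresses pK_D.

The package is aimed at computational antibody engineers who need affinity
estimates when structures are unavailable — in particular for single-domain
antibodies (nanobodies), where sequence data vastly outpaces structural
data. Everything runs at desk scale on one CPU: a deterministic mock
embedding provider stands in for a protein language model behind a pluggable
provider contract, and a synthetic-data generator plants recoverable local
and global affinity signals so the whole pipeline is testable end to end
without downloads.

## Model

Given antibody and antigen sequences A = {a₁…a_m}, G = {g₁…g_n}, the target
is y = −log₁₀ K_D (pK_D, K_D in molar), related to binding free energy by
ΔG = −2.303·R·T·pK_D (pK_D 9 ≈ −12.3 kcal/mol at 298 K). Per-residue
embeddings X_ab ∈ R^{L_ab×D}, X_ag ∈ R^{L_ag×D} feed two branches:

* **Local:** Kolmogorov–Arnold network (KAN) stacks with sinusoidal
  learnable edge functions compress each chain position-wise to scalar
  potentials V_ab, V_ag; their outer product M = V_ab ⊗ V_agᵀ (rank ≤ 1,
  parameter-free) is a complete residue-pair contact grid, which a second
  KAN stack refines — concatenated with V_ab — into an interaction-aware
  antibody representation H_AA ∈ R^{L_ab}.
* **Global:** residue embeddings are projected on frozen random unit
  directions, sorted (exact permutation invariance), summarized by fixed
  quantiles, and antibody/antigen signatures are compared through trainable
  scaled squared distances d⁽ⁱ⁾ = Σ_j ((â_j−b̂_j)/σ_j)² mapped through
  softplus to the strictly positive pair feature h_pair.

Mean/max-pooled H_AA and h_pair are concatenated into a small feed-forward
head trained with MSE on pK_D (AdamW, early stopping, bit-reproducible per
seed). Ablation variants `no_r2r` and `no_gspe` drop one branch. MLM
data-preparation operators (15% masking with CDR-prioritized boosting,
length-stratified batching, masked cross-entropy) are included for the
language-model adaptation workflow. See `docs/methods.md` for the full
model description and design rationale.

## Worked example

Generate a synthetic dataset of 700 pairs, train the full model, and
evaluate:

```bash
dualbind generate --n-pairs 700 --seed 7 --out data
dualbind train --dataset data/pairs.csv --out run --seed 0
dualbind evaluate --checkpoint run/checkpoint.npz --data data/pairs.csv
```

The train command prints a machine-readable footer,

```json
{"best_epoch": 34, "checkpoint": "run/checkpoint.npz", "config_hash": "f1f2ac33f8cf", "val_mae": 0.3265557691295434, "variant": "full"}
```

meaning the best validation MAE was ≈ 0.33 pK_D units at epoch 34 — about a
factor 2 twofold error in K_D, against labels whose standard deviation is
≈ 1.2. Evaluating that checkpoint on the full dataset prints

```json
{"config_hash": "f1f2ac33f8cf", "mae": 0.23052467818618558, "n": 700, "pcc": 0.9711707814584071, "r2": 0.9402756547137934, "rmse": 0.29136625118633097}
```

i.e. the model recovers the planted affinity signal (R² ≈ 0.94, Pearson
r ≈ 0.97; this includes the 500 training pairs — held-out test MAE for this
configuration is ≈ 0.38–0.56 across seeds). Predictions for paired FASTA
files include the unit conversions:

```
   id_ab    id_ag  pkd_pred     kd_molar  dg_kcal_mol
ab_00000 ag_00000  7.697889 2.004982e-08   -10.497352
ab_00001 ag_00001  6.300930 5.001150e-07    -8.592365
```

so the first pair is predicted to bind at K_D ≈ 20 nM, ΔG ≈ −10.5 kcal/mol
at 298 K.

As a library:

```python
from dualbind import (SyntheticSpec, generate, ModelConfig, AffinityModel,
                      MockEmbeddingProvider)

records, truth = generate(SyntheticSpec(n_pairs=700, seed=7))
model = AffinityModel(ModelConfig(variant="full", seed=0),
                      MockEmbeddingProvider(dim=32))
result = model.train(records[:450], records[450:500])
report = model.evaluate_records(records[500:])
print(report.mae, report.pcc)
```

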