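# behavnet

Co-occurrence and clustering analysis of binary health-risk behaviors in
survey data: behavior dichotomization, observed/expected (O/E) ratio
clustering statistics, Ising-network estimation with bootstrap stability
assessment, and Louvain community detection. A bundled synthetic generator
samples exactly from a parameterized 7-node Ising model, so the entire
pipeline is testable without any external data download.

## The seven behaviors

All analyses use a fixed canonical column order:

| code | column                   | coded 1 when                         |
|------|--------------------------|--------------------------------------|
| B1   | `insufficient_fruit`     | fruit frequency response C or D      |
| B2   | `insufficient_vegetable` | vegetable frequency response C or D  |
| B3   | `salty_diet`             | flavor preference is `salty`         |
| B4   | `smoking`                | currently smokes (`yes`)             |
| B5   | `drinking`               | currently drinks (`yes`)             |
| B6   | `irregular_exercise`     | no regular exercise (`no`)           |
| B7   | `inadequate_sleep`       | usual sleep strictly under 6 hours   |

## Package layout

- `behavnet.synthetic` — exact 2^p enumeration of an Ising joint pmf, iid
  sampling, model-level O/E oracles, and a full survey-table generator with
  planted demographic odds ratios and ordinal outcomes.
- `behavnet.coding` — exclusion rules (age ≥ 65, complete demographics and
  behavior fields), dichotomization, behavior counts, outcome scoring (A–E
  to 5–1).
- `behavnet.stats` — prevalence with Wilson CIs, Spearman correlation with
  tie correction, and the co-occurrence logistic regression (odds ratios,
  Wald CIs, fixed reference levels).
- `behavnet.oe` — all-pairs O/E ratios, percentile-bootstrap (default) or
  log-delta confidence intervals, ranking with documented tie-breaks, and
  sex (or any) stratification.
- `behavnet.ising` — eLasso: nodewise L1-penalized logistic regression over
  a 100-point lambda path with EBIC selection (gamma = 0.25, AND rule), plus
  density, node strength, and clustering-coefficient metrics.
- `behavnet.stability` — nonparametric bootstrap edge-weight CIs and the
  case-dropping bootstrap with CS-coefficient.
- `behavnet.communities` — Louvain modularity maximization (seeded,
  deterministic) and partition comparison (ARI/NMI).
- `behavnet.pipeline` / `behavnet.cli` — end-to-end orchestration with a
  YAML config, deterministic per-stage seeds, and a byte-stable JSON report.

## CLI

```bash
behavnet simulate --n 5000 --seed 1 --out survey.csv   # synthetic data + JSON sidecar
behavnet validate survey.csv                           # header/vocabulary/range checks
behavnet code survey.csv --out matrix.csv              # binary behavior matrix
behavnet describe survey.csv                           # prevalence, counts, Spearman
behavnet oe survey.csv --stratify gender               # ranked O/E tables
behavnet network survey.csv                            # eLasso network + metrics
behavnet stability survey.csv --bootstrap-b 1000       # edge CIs + case-dropping
behavnet communities survey.csv                        # Louvain partition
behavnet run --config pipeline.yaml --out report.json  # everything, one report
behavnet report report.json                            # human-readable summary
```

Example `pipeline.yaml`:

```yaml
synthetic: {n_records: 5000}
seed: 42
oe_bootstrap_B: 1000
stability_B: 1000
gamma: 0.25
rule: AND
weight_transform: abs
```

Re-running with an identical config reproduces the report byte for byte:
every stochastic stage derives its seed from the master seed and the stage
name.

## Notes on methods

- O/E = P(A∩B) / (P(A)·P(B)); exactly 1 whenever `n_ij·N == n_i·n_j`.
- The default O/E interval is a percentile bootstrap of the 2×2 cell vector
  (B = 1000). The log-delta alternative uses
  Var[ln O/E] = 1/n_ij − 1/n_i − 1/n_j + 1/N, which is exact under
  independence but understates width for dependent pairs — prefer the
  bootstrap when pairs cluster.
- EBIC(λ) = −2·loglik + k·ln N + 2γ·k·ln(p−1), with k the number of nonzero
  predictors; per-node ties resolve toward the sparser model.
- Negative estimated edges are mapped by absolute value before community
  detection by default (`positive-only` available).
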