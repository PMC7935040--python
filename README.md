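# connctl

Network controllability of structural connectomes and its relation to
regional gray-matter volume.

`connctl` implements an end-to-end, fully testable analysis pipeline:

1. **connectome** — read/validate weighted region × region connectivity
   matrices (streamline counts), proportional thresholding (default: keep the
   10% strongest edges), node strength; bundled 120-region atlas.
2. **control metrics** — average controllability (trace of the infinite-horizon
   controllability Gramian, solved via the stationary discrete Lyapunov
   equation), modal controllability, and the Kalman rank test, on the
   stabilized adjacency (divided by 1 + largest singular value by default).
3. **study table** — join controllability, strength, regional gray-matter
   volume (rGM) and total intracranial volume (TIV) into a long-format table;
   within-subject centering plus z-scaling (pooled or within-subject SD).
4. **mixed models** — random-intercept linear mixed models
   (`ac ~ tiv + regions + degree × rgm + (1|participants)` and
   `ac ~ tiv + regions × degree + regions × rgm + (1|participants)`),
   ML likelihood-ratio stepwise selection, Wald CIs, Bonferroni-corrected
   per-region effects. The fitter profiles the single variance ratio
   directly, so it is robust when within-subject centering drives the
   random-intercept variance to zero (it is validated against statsmodels
   MixedLM in the test suite).
5. **null models** — weighted Maslov–Sneppen degree-preserving rewiring
   (binary degree sequence and edge-weight multiset conserved exactly; node
   strength intentionally not), and an empirical null test of the rGM
   coefficient across rewired cohorts.
6. **synthetic data** — seeded generators for heavy-tailed group-template
   connectomes, per-subject noise, rGM with an exactly-controlled correlation
   to template topology, TIV, and mixed-model fixtures with known true
   coefficients.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria; simulation-heavy
ones run at reduced replication counts there (thresholds adjusted via
binomial bounds), with the full-scale versions in `scripts/acceptance.py`.

## CLI

```sh
connctl run-all --config config.yaml --out results/      # full pipeline
connctl generate --config config.yaml --out data/        # synthetic cohort
connctl metrics  --data data/ --threshold 0.1 --out profiles.tsv
connctl analyze  --data data/ --out results/             # models + effects
connctl nulltest --data data/ -R 200 --seed 1 --out null/
```

Example `config.yaml`:

```yaml
seed: 1
threshold: 0.10          # proportion of strongest edges kept
scheme: singular_value   # adjacency normalization
sd_mode: pooled          # z-scaling denominator
response: ac
synthetic:
  n_subjects: 65
  n_regions: 120
  rgm_topology_coupling: 0.5
null_test:
  enabled: true
  n_replicates: 200
```

Every run writes `provenance.json` (config echo, seed, versions); result
JSONs are byte-identical across reruns with the same config and seed.

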