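# ceutil

Trial-based cost–utility analysis toolkit. Given two strategy arms summarized
by mean cost (USD) and mean effect (QALY), it computes:

- **Deterministic base case** — incremental cost/effect, ICER with dominance
  status (`dominant`, `dominated`, `trade-off-NE`, `trade-off-SW`,
  `indifferent`), and incremental net monetary benefit at a willingness-to-pay
  threshold (converted BRL→USD at a configurable rate).
- **One-way sensitivity analysis (OWSA)** — each scalar parameter varied
  between bounds (±15 % by default, or explicit CI/custom bounds) with
  tornado-ordered ranges; unstable ICER rows (sign change of ΔC or ΔE inside
  the interval) are flagged.
- **Probabilistic sensitivity analysis (PSA)** — method-of-moments beta fits
  for effects and gamma fits for costs, seeded Monte Carlo draws (fixed stream
  order `cost_int, cost_con, eff_int, eff_con` per draw, so exports are
  auditable), cost-effectiveness-plane classification, and the cost-effective
  proportion under the quadrant rule (dominant + north-east-below-threshold;
  cheaper-and-less-effective draws are excluded).
- **CEAC** — acceptability curves over a threshold grid, under either the
  net-benefit rule or the quadrant rule.
- **Synthetic trials** — patient-level two-arm data with gamma-distributed
  costs and beta-distributed utilities, plus arm-level estimation
  (means, standard errors) to feed the pipeline end to end.

Currency handling is limited to BRL/USD. Administrative procedure-table
prices (source `SIGTAP`) can be scaled by a correction factor (default 2.8)
exactly once — items carry a provenance flag making double application an
error. All values are full precision internally; two-decimal half-up rounding
is applied only at the reporting layer.

## CLI

Every subcommand takes `--config PATH`, `--seed INT`, `--out DIR`,
`--format {csv,json}` and `--quiet`, and writes a `manifest.json` recording
the timestamp, config digest, seed, package version and output file list.

```bash
CONFIG=$(python -c "import ceutil; print(ceutil.base_case_config_path())")

ceutil deterministic --config "$CONFIG" --out results   # base-case table
ceutil owsa          --config "$CONFIG" --out results   # tornado table
ceutil psa   --config "$CONFIG" --seed 1 --out results  # draw table, counts, CE-plane coords
ceutil ceac  --config "$CONFIG" --seed 1 --out results  # acceptability curve
ceutil simulate --config "$CONFIG" --seed 1 --out results  # synthetic patient CSV
```

The packaged fixture config (`src/ceutil/data/base_case.yaml`) encodes the
default two-arm comparison (INT 317.73 USD / 0.23 QALY vs CON 293.93 USD /
0.20 QALY, 12-week horizon, BRL 40 000/QALY threshold at 5.10 BRL/USD) and
references a six-line resource-cost CSV (`resource_costs.csv`).

### Config schema (YAML or JSON)

```yaml
strategies:        # exactly two; 'role' (intervention/comparator) orients them,
  - name: INT      # otherwise the first entry is the intervention
    mean_cost: 317.73      # USD
    mean_effect: 0.23      # QALY
    cost_se: 47.66         # optional; default se_rule * mean in the PSA
  - name: CON
    mean_cost: 293.93
    mean_effect: 0.20
cost_items: []             # inline items, and/or:
cost_items_csv: resource_costs.csv
utilities:
  - {label: ward, utility: 0.724, disutility: -0.061, setting: ward}
horizon: {weeks: 12, weeks_per_year: 52}
currency: {brl_per_usd: 5.10}
correction: {factor: 2.8, applies_to: [SIGTAP]}
threshold: {value: 40000, currency: BRL}
psa: {n_draws: 1000, seed: 1, se_rule: 0.15}
owsa: {variation: 0.15, bounds: {"int.mean_cost": [280, 350]}}
simulate: {n_int: 25, n_con: 27, utility_mean_int: 0.724, utility_mean_con: 0.693}
```

Validation reports **all** offending fields at once.

## Layout

```
src/ceutil/parameters.py     domain types, currency/correction arithmetic, config I/O
src/ceutil/deterministic.py  QALY accrual, ICER, dominance, net monetary benefit
src/ceutil/owsa.py           bounds, one-way re-evaluation, tornado ordering
src/ceutil/psa.py            moment fitting, Monte Carlo, CE-plane, CEAC
src/ceutil/synthetic.py      patient-level trial generator, arm estimation
src/ceutil/cli.py            click CLI, exports, run manifests
src/ceutil/data/             packaged base-case config + resource-cost CSV
```
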