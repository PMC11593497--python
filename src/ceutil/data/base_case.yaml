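# Base-case configuration: two-arm cost-utility comparison of an inspiratory
# muscle training add-on (INT) versus the rehabilitation program alone (CON).
# Arm-level means are direct inputs; monetary values in USD unless stated.

strategies:
  - name: INT
    role: intervention
    mean_cost: 317.73     # USD per patient over the horizon
    mean_effect: 0.23     # QALY
  - name: CON
    role: comparator
    mean_cost: 293.93
    mean_effect: 0.20

cost_items_csv: resource_costs.csv

utilities:
  - label: post-ward discharge
    utility: 0.724
    disutility: -0.061
    setting: ward
  - label: post-ICU discharge
    utility: 0.693
    disutility: -0.155
    setting: ICU

horizon:
  weeks: 12
  weeks_per_year: 52

currency:
  brl_per_usd: 5.10

correction:
  factor: 2.8
  applies_to: [SIGTAP]

threshold:
  value: 40000
  currency: BRL

psa:
  n_draws: 1000
  seed: 20240
  se_rule: 0.15          # se = 15% of each mean unless an arm se is given

owsa:
  variation: 0.15

simulate:
  n_int: 25
  n_con: 27
  utility_mean_int: 0.724
  utility_mean_con: 0.693
  se_fraction: 0.15
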