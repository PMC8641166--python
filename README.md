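# afcost

A patient-specific, real-world cost model comparing the two common
anticoagulation therapies for atrial fibrillation — warfarin and direct
oral anticoagulants (DOAC) — from both the patient's and the healthcare
service's perspective over a one-year window.

Because the original registry extracts (electronic health records and
travel-reimbursement data) are restricted, the pipeline is driven by a
fully seeded **synthetic registry generator** that reproduces the
published cohort structure: group sizes 3171/829, ages 76.0 ± 9.2 vs
72.7 ± 9.8, ≈17.5 INR monitorings per warfarin patient-year, ≈5.5 km road
distance to the nearest laboratory, ≈€12/h postal-area income, and
travel-reimbursement records covering ≈5% of contacts.

## What the pipeline does

1. **synthetic_data** — seeded generators for the road network +
   facilities (random geometric graph, connected by construction), the
   two-arm cohort, dated AF-related contact streams (negative-binomial
   counts; complication episodes always pair an urgent visit with ward
   days), and partial travel-reimbursement records.
2. **cohort** — inclusion/attrition rules (nursing home, prior AF
   diagnosis, residency, survival, continuous prescription covering the
   window plus 60 days, no therapy switch) with a per-rule exclusion log,
   the AF-contact filter (stroke/haemorrhage episodes kept only with an
   urgent visit *and* a ward day), and the wage coefficient
   (1.0 under 65 years, 0.35 otherwise).
3. **routing** — fastest routes on the network (speed = min(edge limit,
   mode cap); walking 4 km/h, bus 30 km/h), closest-laboratory
   assignment, bus-stop access distance. Verified against brute-force
   path enumeration.
4. **travel_model** — rule-based travel-mode assignment
   (reimbursement record > taxi 90+ > walking ≤1.25 km/<80 y or
   ≤0.25 km/80–89 y > bus > car) and the daily trip limiter
   (≤ 2 round trips per day; no trips mid-ward-stay; one-way legs on the
   first/last ward day; chained same-day contacts share one round trip).
5. **cost_engine** — travel costs per mode (car €0.43/km; taxi
   €5.90 + €1.59/km; bus banded fares €2.00/3.80/5.00; walking free;
   ambulance from reimbursement records only), time costs (€/h income ×
   wage coefficient, +5 min parking/service per car/taxi leg, 30 min per
   INR visit), drug payer splits (warfarin €0.08/€0.05 per day, DOAC
   €0.95/€1.76), the patient fee schedule with the €683 annual payment
   ceiling (excess reroutes to public expenditure), and exact per-day
   cost composition for both payers.
6. **reporting** — per-patient annual totals, group means ± SD with
   normal-theory 95% CIs, differences and Welch-style p-values, plus a
   utilisation/access summary.

## CLI

```bash
afcost simulate --config cohort.yaml --geo geo.yaml --seed 1 --out sim/
afcost route --geo-dir sim/ --from 0 --to 17 --mode car
afcost run --config cohort.yaml --geo geo.yaml --params params.yaml --seed 1 --out out/
afcost report --in out/ --out report/
```

All config files are optional YAML overrides of the calibrated defaults
(`afcost.config.CohortConfig`, `GeographyConfig`,
`afcost.cost_engine.CostParameters`). `afcost run` writes the synthetic
tables (`patients.csv`, `contacts.csv`, `reimbursements.csv`,
`facilities.csv`, `network_nodes.csv`, `network_edges.csv`), the cohort
and attrition log, `journeys.csv`, `daily_costs.csv`, and the
`cost_table.csv` / `utilisation_table.csv` / `report.md` summaries. The
full default run (4000 patients, 800-node network) takes a few seconds.

## Reproducibility

Every generator draws from named child streams of a single master seed:
identical configuration ⇒ bit-identical tables. Report regeneration from
a saved `daily_costs.csv` is byte-identical.
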