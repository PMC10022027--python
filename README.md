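# sitecap

Site capacity, utilization and productivity analytics for voluntary
medical male circumcision (VMMC) service-delivery programs.

VMMC is a surgical HIV-prevention service scaled up across Eastern and
Southern Africa, largely with PEPFAR support. Site and program managers
need to know, month by month, whether each site is performing as many
circumcisions as its staff and surgical beds allow. `sitecap` is a
desk-scale visual-management toolkit for exactly that question: it
ingests monthly per-site records (targets, personnel, beds, days of
operation, performance counts), computes capacity and productivity
indicators, rolls them up over the US fiscal calendar and geography, and
renders indicator tables, figures and a self-contained HTML dashboard.

## The model

The capacity model assumes each procedure occupies one station for 30
minutes within a 450-minute operating day, so a station handles 15
procedures per day. With `V` the VMMCs performed, `n` providers and `b`
surgical beds:

- **current daily capacity** `C_c = 15 n` — what the site can do with the
  staff it has (optionally scaled by task-shifting/task-sharing factors);
- **optimum daily capacity** `C_o = 15 b` — what it could do if staffing
  matched its beds;
- **utilization rate** `U = V / C_c` — `< 1` under-used, `> 1` over-used,
  `= 1` balanced (at two-decimal display precision);
- **productivity gain/loss** `P = V − C_o` — negative values are
  circumcisions the site's beds could have supported but its staffing
  did not deliver;
- **additional staff needed** — per-role shortfall against a normative
  template of one provider, trained assistant, nurse and counselor per
  bed;
- **VMMC cascade** — people reached by demand creation → people seeking
  services → VMMCs performed, with conversion ratios (which may exceed
  1: people seek services without having been reached).

Aggregates over a quarter, province or a fixed site plus its affiliated
outreach sites recompute every ratio from summed numerators and
denominators (`U = ΣV / ΣC_c`), never by averaging member ratios.
Fiscal years run 1 October – 30 September and are labelled by the ending
calendar year; Q1 is October–December.

## Worked example

```sh
sitecap synth --seed 42 --out data/          # synthetic 2-province program
sitecap indicators --in data/ --out out/ --level fixed_site_group --granularity quarter
sitecap report --in data/ --out report/ --level fixed_site_group --granularity quarter
```

Or in Python, reproducing the model's canonical site-days (each site has
one provider and one bed, so both capacities are 15/day):

```python
>>> from sitecap import worked_example_fixture, aggregate_indicators
>>> profiles, records = worked_example_fixture()
>>> ind = aggregate_indicators(profiles, records, "site", "month")
>>> print(ind[["group", "performed", "utilization_display",
...            "utilization_class", "productivity"]].to_string(index=False))
         group  performed  utilization_display utilization_class  productivity
Example Site A         15                 1.00          balanced             0
Example Site B         10                 0.67        under-used            -5
Example Site C         19                 1.27         over-used             4
Example Site D         18                 1.20         over-used             3
```

Site B performs 10 of a possible 15 — utilization 0.67, a productivity
loss of 5 circumcisions per day; site C is over-used at 1.27; site D's
gain of 3 means it outperformed what its single bed should support.

`sitecap report` writes, for each of nine figures (VMMCs over time,
site counts, targets vs performed, current vs optimum capacity, beds vs
providers, utilization, productivity, cascade, ...), a CSV/PNG pair plus
`dashboard.html`; utilization charts draw a reference line at 1 and
productivity charts at 0. Every number in a companion CSV equals the
indicator module's output — plots are views, never recomputations.

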