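# Methods

## The capacity and productivity model

`sitecap` implements a throughput model of VMMC service delivery. Its
single behavioural assumption is that one circumcision occupies one
station for a fixed `minutes_per_procedure` (default 30 min) within an
operating day of `operating_minutes_per_day` (default 450 min), giving
`slots_per_station_per_day = floor(450 / 30) = 15` procedures per
station per day. The three constants are kept mutually consistent:
assigning any one recomputes the dependent slot count (assigning the
slot count rescales the operating day). All defaults live in
`CapacityParams` and can be overridden in one YAML file via the CLI.

From there, for a site-month with `n` providers, `b` beds, `d` reported
days of operation and `V` circumcisions performed:

| indicator | formula | notes |
|---|---|---|
| current daily capacity | `floor(15 n × f)` | `f` = task factor(s), below |
| optimum daily capacity | `15 b` | beds are the binding capital input |
| period capacity | daily × `d` | reported days, not calendar days |
| utilization | `U = V / C_c` | classified at 2-dp display |
| productivity | `P = V − C_o` | exact integer arithmetic |
| average daily VMMCs | `V / d` | |
| target achievement | `V / target` | |
| staffing gap | `max(0, b·ratio − staff)` per role | normative template |

Current capacity deliberately depends only on providers and optimum
capacity only on beds: these are the spreadsheet formulas the model is
defined by. The broader staffing complement (assistants, nurses,
counselors) enters only through the normative staffing-gap template
(default one of each role per bed, configurable), because no published
formula ties those roles to throughput.

**Task shifting and task sharing.** Sites operating under task shifting
(whole procedure delegated to a nurse/clinical officer) or task sharing
(parts delegated) are flagged in the site profile, and
`current_capacity_daily` multiplies in `task_shifting_factor` /
`task_sharing_factor` for flagged sites. Both default to 1.0 — the
arrangements are distinguished but no quantified coefficient is
established, so the package refuses to invent one; programs that have
estimated their own adjustment set it in the params file. An optional
`cap_current_at_beds` switch caps current capacity at `15 b` for sites
with more providers than beds; it is off by default, keeping the plain
`providers × 15` formula.

**Undefined ratios.** A zero denominator (closed site, zero capacity,
no target) yields a flagged absent value (`None` /
`classification="undefined"`), never 0 or infinity: a closed site must
not appear perfectly efficient or infinitely over-used. Unreported
performance fields load as absent (distinct from zero) and propagate as
absent through every indicator, reflecting the variable completeness of
routine program data.

**Display rounding** is half-up at two decimals for ratios (so 10/15
prints 0.67 and 19/15 prints 1.27, with the under/over-used
classification judged at display precision so label and printed number
never disagree), one decimal for staffing stocks, counts unrounded.
Full precision is retained internally; rounding happens only in output
tables.

## Aggregation

Time buckets follow the US-government fiscal calendar: FY = 1 October –
30 September, labelled by the ending calendar year (2014-10 is FY15 Q1);
quarters Oct–Dec, Jan–Mar, Apr–Jun, Jul–Sep; half-years Oct–Mar and
Apr–Sep. Geographic levels are site, fixed-site group (a fixed site
plus its affiliated outreach sites, joined on `parent_fixed_site`),
health zone, province, region and all. `region` is an optional profile
column defaulting to the province.

Three rules keep rollups self-consistent:

1. additive fields (targets, performance counts, days) are summed;
2. staffing and beds are stocks, not flows — summed across sites within
   a month, then averaged across the months of a bucket (a `last`-month
   rule is available behind `staffing_rule`);
3. every ratio is recomputed from aggregated numerator and denominator
   (`U = ΣV / ΣC_c`), with capacities recomputed from the member
   site-months. Averaging member ratios would weight a 1-bed outreach
   site equally with a provincial hospital and is not offered; it is
   also the only rule under which a site→zone→province rollup equals
   the direct site→province rollup.

## Synthetic data

No real program dataset ships with the package, so the `synthetic`
module generates one with the structure of a two-province scale-up:
9 fixed sites (4 + 5) running 36 months from 2014-10; at the ramp month
(2016-10) each fixed site acquires 2–3 affiliated outreach sites (total
18–27) and staffing aligns with beds. Monthly output is drawn as
`round(capacity × u)` with `u ~ N(0.45, 0.30)` before the ramp (low,
volatile utilization) and `u ~ N(1.0, 0.05)` after it (the stabilized
regime), both clipped to [0, 2]. Demand counts are Poisson; seeking is
Poisson around reached × a multiplier ~ N(1.25, 0.20), exceeding 1 in
most months; follow-ups, adverse events, STI and HIV counts are binomial
thinnings of the counts that bound them, so every generated dataset
satisfies the record invariants by construction. Targets follow the
previous quarter's mean monthly output times a 1.1 growth factor,
emulating regular target revision. The generator is deterministic given
its seed.

What it does **not** emulate: seasonality, data-entry errors and
missingness, heterogeneous partner behaviour, site closures, or any
calibration to a real country's totals. Passing tests therefore
demonstrate arithmetic and structural correctness of the pipeline, not
predictive fidelity to any real program.

`worked_example_fixture()` is a separate, fully deterministic four-site
dataset in which every site has one provider, one bed and a single
operating day, so monthly indicators equal daily ones and the model's
canonical values (U ∈ {1, 0.67, 1.27}; P ∈ {0, −5, 3}) fall out of the
full pipeline.

## Numerical and design choices

- Integer arithmetic throughout capacities and productivity; the only
  floor is in current capacity after task-factor scaling.
- Rounding is decimal half-up (not banker's), matching how the printed
  indicator values are reported.
- CSV layout is two normalized files (`sites.csv`, `monthly.csv`) joined
  on `site_name`, so `(site, month)` uniqueness and referential
  integrity are checkable; months are ISO `YYYY-MM`; absent values are
  empty strings. Validation is total — every malformed row is reported
  with its row number, and no partially loaded dataset is returned.
- Age bands are configurable and inferred from the CSV headers; the
  default is the standard program-reporting set (10–14 … 35–49, 50+).
  No reconciliation is enforced between reached-by-age and
  reached-by-source totals, since none is defined for the inputs.
- Figures are static matplotlib files plus one self-contained HTML
  dashboard (base64-embedded images, no external references); content
  fidelity, not chart styling, is the contract, and every plotted number
  equals its companion CSV bit for bit.
- Problem sizes in the test suite (e.g. 6–12-month synthetic datasets
  for the aggregation property sweeps, 100 seeds for hierarchy checks,
  10 seeds for the stabilized-utilization check) were chosen as the
  smallest sizes that still exercise multi-quarter, multi-level rollups.

## Known limitations

- The per-role staffing template is a documented assumption, not an
  estimated model; sites with genuinely different skill mixes should
  override it.
- Cost and expenditure indicators are out of scope, as is cross-site
  benchmarking or ranking.
- Aggregated displays are a convenience; the indicators are designed for
  site-level decision making, not statutory regional/national reporting.
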