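"""Seeded synthetic service-delivery datasets.

The generator emulates the statistical shape of a two-province VMMC
scale-up: nine fixed sites run for 36 months from October 2014; midway
(October 2016) each fixed site acquires 2-3 affiliated outreach sites and
the program "stabilizes" — before the ramp, monthly utilization is low
and highly variable; after it, utilization concentrates tightly around 1
(performed is drawn as round(capacity x u) with u wide early and narrow
around 1 late).  Demand counts are Poisson; conversions, follow-ups and
adverse events are binomial thinnings of the counts they are bounded by,
so every generated dataset satisfies the record invariants by
construction.  Seeking is drawn around reached times a multiplier that
exceeds 1 in most months — people seek services without having been
reached by demand creation.

This is not a calibrated reconstruction of any real program's data;
headline totals from any particular country are not reproduction targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from sitecap.data_model import (
    AGE_BANDS,
    INFO_SOURCES,
    CapacityParams,
    MonthlyRecord,
    SiteProfile,
    days_in_month,
    validate_dataset,
)
from sitecap.indicators import current_capacity_daily

#: Age distribution of VMMC clients (younger-skewed program population).
_AGE_P = (0.24, 0.30, 0.20, 0.11, 0.08, 0.05, 0.02)
#: How demand-creation contacts split across information sources.
_SOURCE_P = (0.05, 0.12, 0.15, 0.12, 0.06, 0.28, 0.08, 0.04, 0.10)


def _month_range(start: str, n: int) -> List[str]:
    y, m = int(start[:4]), int(start[5:7])
    out = []
    for _ in range(n):
        out.append(f"{y:04d}-{m:02d}")
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return out


@dataclass
class SynthConfig:
    """Knobs of the synthetic program-data generator.

    Defaults encode the study conditions the generator emulates: 2
    provinces, 9 fixed sites, 36 months from 2014-10, outreach expansion
    from 2016-10 with 2-3 outreach sites per fixed site (so the quarterly
    outreach count lands in 18-27).
    """

    n_provinces: int = 2
    fixed_sites_per_province: Tuple[int, ...] = (4, 5)
    months: int = 36
    start_month: str = "2014-10"
    outreach_start_month: str = "2016-10"
    outreach_per_fixed: Tuple[int, int] = (2, 3)  # inclusive range
    # staffing ramp: beds grow from 1 toward this range by the ramp month,
    # providers lag beds before the ramp and match them after it
    max_beds_range: Tuple[int, int] = (2, 4)
    # utilization regimes: pre-ramp wide and low, post-ramp tight around 1
    pre_ramp_util_mean: float = 0.45
    pre_ramp_util_sd: float = 0.30
    post_ramp_util_mean: float = 1.0
    post_ramp_util_sd: float = 0.05
    # demand: reached ~ Poisson(performed-scale x reach_ratio);
    # seeking ~ Poisson(reached x multiplier), multiplier > 1 most months
    reach_ratio: float = 1.1
    seeking_multiplier_mean: float = 1.25
    seeking_multiplier_sd: float = 0.20
    # conversion/thinning rates
    followup_rates: Tuple[float, float, float] = (0.90, 0.75, 0.50)
    ae_rates: Tuple[float, float, float] = (0.010, 0.004, 0.001)
    sti_rate: float = 0.05
    hiv_test_rate: float = 0.95
    hiv_pos_rate: float = 0.03
    target_growth: float = 1.1
    age_bands: Tuple[str, ...] = AGE_BANDS
    seed: int = 42

    def __post_init__(self):
        if self.months < 1:
            raise ValueError("months must be >= 1")
        if len(self.fixed_sites_per_province) != self.n_provinces:
            raise ValueError("fixed_sites_per_province must list one count "
                             "per province")
        lo, hi = self.outreach_per_fixed
        if lo < 0 or hi < lo:
            raise ValueError("outreach_per_fixed must be a (lo, hi) range "
                             "with 0 <= lo <= hi")
        for name in ("followup_rates", "ae_rates"):
            for r in getattr(self, name):
                if not 0 <= r <= 1:
                    raise ValueError(f"{name} entries must be in [0, 1]")
        for name in ("sti_rate", "hiv_test_rate", "hiv_pos_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.seeking_multiplier_mean <= 0:
            raise ValueError("seeking_multiplier_mean must be > 0")


def _split(rng: np.random.Generator, total: int,
           p: Sequence[float], keys: Sequence[str]) -> Dict[str, int]:
    draw = rng.multinomial(total, np.asarray(p) / np.sum(p))
    return {k: int(v) for k, v in zip(keys, draw)}


def generate(config: Optional[SynthConfig] = None,
             params: Optional[CapacityParams] = None,
             ) -> Tuple[List[SiteProfile], List[MonthlyRecord]]:
    """Generate a validated synthetic dataset. Deterministic given the seed."""
    cfg = config or SynthConfig()
    params = params or CapacityParams()
    rng = np.random.default_rng(cfg.seed)
    months = _month_range(cfg.start_month, cfg.months)
    ramp_idx = next((i for i, m in enumerate(months)
                     if m >= cfg.outreach_start_month), len(months))

    profiles: List[SiteProfile] = []
    site_plan: List[Dict] = []
    for prov_i in range(cfg.n_provinces):
        province = f"Province {chr(ord('A') + prov_i)}"
        for s_i in range(cfg.fixed_sites_per_province[prov_i]):
            name = f"{province} Fixed Site {s_i + 1}"
            profiles.append(SiteProfile(
                site_name=name,
                health_zone=f"{province} Zone {s_i % 2 + 1}",
                province=province,
                urban_rural="urban" if s_i % 3 == 0 else "rural",
                ownership="public",
                dreams_status=bool(rng.random() < 0.3),
                agency="USG Agency",
                implementing_partner="Partner One",
                delivery_mode="fixed",
                pepfar_category="scale-up aggressive",
                vmmc_category="scale-up",
                task_sharing=bool(rng.random() < 0.5),
                task_shifting=bool(rng.random() < 0.5),
                opening_date=f"{cfg.start_month}-01",
                parent_fixed_site=None,
            ))
            fixed_zone = profiles[-1].health_zone
            max_beds = int(rng.integers(cfg.max_beds_range[0],
                                        cfg.max_beds_range[1] + 1))
            site_plan.append({"profile": profiles[-1], "max_beds": max_beds,
                              "start": 0, "outreach": False})
            lo, hi = cfg.outreach_per_fixed
            n_out = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
            for o_i in range(n_out):
                oname = f"{name} Outreach {o_i + 1}"
                profiles.append(SiteProfile(
                    site_name=oname,
                    health_zone=fixed_zone,
                    province=province,
                    urban_rural="rural",
                    ownership="public",
                    dreams_status=False,
                    agency="USG Agency",
                    implementing_partner="Partner One",
                    delivery_mode="outreach",
                    pepfar_category="scale-up aggressive",
                    vmmc_category="scale-up",
                    task_sharing=True,
                    task_shifting=True,
                    opening_date=f"{cfg.outreach_start_month}-01",
                    parent_fixed_site=name,
                ))
                site_plan.append({"profile": profiles[-1], "max_beds": 1,
                                  "start": ramp_idx, "outreach": True})

    records: List[MonthlyRecord] = []
    for plan in site_plan:
        p: SiteProfile = plan["profile"]
        history: List[int] = []  # monthly performed, for target setting
        for i, month in enumerate(months):
            if i < plan["start"]:
                continue
            post_ramp = i >= ramp_idx
            if plan["outreach"]:
                beds, providers = 1, 1
                days = int(rng.integers(6, 13))
            else:
                frac = min(1.0, i / max(1, ramp_idx))
                beds = max(1, round(1 + frac * (plan["max_beds"] - 1)))
                if post_ramp:
                    providers = beds  # ramp aligns staffing with beds
                else:
                    providers = max(1, beds - int(rng.integers(0, 2)))
                days = int(rng.integers(18, 25))
            days = min(days, days_in_month(month))
            cur_daily = current_capacity_daily(
                providers, params,
                task_shifting=p.task_shifting, task_sharing=p.task_sharing)
            cap_month = cur_daily * days
            if post_ramp:
                u = rng.normal(cfg.post_ramp_util_mean,
                               cfg.post_ramp_util_sd)
            else:
                u = rng.normal(cfg.pre_ramp_util_mean, cfg.pre_ramp_util_sd)
            u = float(np.clip(u, 0.0, 2.0))
            performed = int(round(cap_month * u))

            reached = int(rng.poisson(max(1.0, performed * cfg.reach_ratio)))
            mult = max(0.1, rng.normal(cfg.seeking_multiplier_mean,
                                       cfg.seeking_multiplier_sd))
            seeking = int(rng.poisson(reached * mult))

            if history:
                q = history[-3:]
                target = max(5, int(round(np.mean(q) * cfg.target_growth)))
            else:
                target = max(5, int(round(cap_month * 0.8)))
            history.append(performed)

            f48 = int(rng.binomial(performed, cfg.followup_rates[0]))
            f7d = int(rng.binomial(performed, cfg.followup_rates[1]))
            f6w = int(rng.binomial(performed, cfg.followup_rates[2]))
            ae = [int(rng.binomial(performed, r)) for r in cfg.ae_rates]
            sti = int(rng.binomial(performed, cfg.sti_rate))
            sti_tc = int(rng.binomial(sti, 0.8))
            hiv = int(rng.binomial(performed, cfg.hiv_test_rate))
            hiv_pos = int(rng.binomial(hiv, cfg.hiv_pos_rate))

            records.append(MonthlyRecord(
                site_name=p.site_name,
                month=month,
                target=target,
                providers=providers,
                trained_assistants=providers,
                other_nurses=max(1, providers - (0 if post_ramp else 1)),
                mobilizers=2,
                counselors=providers,
                beds=beds,
                days_of_operation=days,
                reached_by_age=_split(rng, reached, _AGE_P, cfg.age_bands),
                seeking_by_age=_split(rng, seeking, _AGE_P, cfg.age_bands),
                reached_by_source=_split(rng, reached, _SOURCE_P,
                                         INFO_SOURCES),
                vmmc_by_age=_split(rng, performed, _AGE_P, cfg.age_bands),
                followup_48h=f48,
                followup_7d=f7d,
                followup_6w=f6w,
                ae_mild=ae[0],
                ae_moderate=ae[1],
                ae_severe=ae[2],
                sti_diagnosed=sti,
                sti_treated_circumcised=sti_tc,
                hiv_tests=hiv,
                hiv_pos_referred=hiv_pos,
            ))

    validate_dataset(profiles, records)
    return profiles, records


def worked_example_fixture() -> Tuple[List[SiteProfile], List[MonthlyRecord]]:
    """A four-site, one-day dataset engineered around the model's worked
    examples.

    Each site has one provider and one surgical bed (daily current and
    optimum capacity both 15) and operates a single day, so monthly
    indicators equal daily ones:

    * Site A performs 15 -> utilization 15/15 = 1 (balanced),
      productivity 15 - 15 = 0;
    * Site B performs 10 -> utilization 10/15 = 0.67 (under-used),
      productivity 10 - 15 = -5;
    * Site C performs 19 -> utilization 19/15 = 1.27 (over-used);
    * Site D performs 18 -> productivity 18 - 15 = 3.
    """
    profiles: List[SiteProfile] = []
    records: List[MonthlyRecord] = []
    performed = {"A": 15, "B": 10, "C": 19, "D": 18}
    for label, v in performed.items():
        name = f"Example Site {label}"
        profiles.append(SiteProfile(
            site_name=name,
            health_zone="Example Zone",
            province="Example Province",
            urban_rural="urban",
            ownership="public",
            delivery_mode="fixed",
            pepfar_category="attained",
            vmmc_category="sustainability",
            opening_date="2017-01-01",
        ))
        vmmc = {b: 0 for b in AGE_BANDS}
        vmmc["15-19"] = v
        records.append(MonthlyRecord(
            site_name=name,
            month="2017-01",
            target=15,
            providers=1,
            trained_assistants=1,
            other_nurses=1,
            mobilizers=1,
            counselors=1,
            beds=1,
            days_of_operation=1,
            vmmc_by_age=vmmc,
        ))
    validate_dataset(profiles, records)
    return profiles, records
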