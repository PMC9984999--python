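# Pakistan routine EPI schedule, 2019.
# BCG + OPV-0 at birth; Penta/PCV/OPV and Rota at 6, 10(, 14) weeks;
# one IPV dose at 14 weeks (no prerequisite, no interval — eligibility is
# by age alone); measles at 9 and 15 months.
# Conventions: weeks as exact day counts (6w=42d); ">28 days after" as
# min_interval_days 29; "through 28 days of age" as max_age_days 28
# inclusive; BCG indicated through the first birthday inclusive.
country_id: pakistan_2019
series:
  - antigen: BCG
    doses:
      - {index: 1, label: BCG, min_age_days: 0, max_age_years: 1}
  - antigen: OPV
    doses:
      - {index: 1, label: OPV-0, min_age_days: 0, max_age_days: 28}
      - {index: 2, label: OPV-1, min_age_days: 42}
      - {index: 3, label: OPV-2, min_age_days: 70, min_interval_days: 29, requires_previous: true}
      - {index: 4, label: OPV-3, min_age_days: 98, min_interval_days: 29, requires_previous: true}
  - antigen: Penta
    doses:
      - {index: 1, label: Penta-1, min_age_days: 42}
      - {index: 2, label: Penta-2, min_age_days: 70, min_interval_days: 29, requires_previous: true}
      - {index: 3, label: Penta-3, min_age_days: 98, min_interval_days: 29, requires_previous: true}
  - antigen: PCV
    doses:
      - {index: 1, label: PCV-1, min_age_days: 42}
      - {index: 2, label: PCV-2, min_age_days: 70, min_interval_days: 29, requires_previous: true}
      - {index: 3, label: PCV-3, min_age_days: 98, min_interval_days: 29, requires_previous: true}
  - antigen: Rota
    doses:
      - {index: 1, label: Rota-1, min_age_days: 42}
      - {index: 2, label: Rota-2, min_age_days: 70, min_interval_days: 29, requires_previous: true}
  - antigen: IPV
    doses:
      - {index: 1, label: IPV, min_age_days: 98}
  - antigen: Measles
    doses:
      - {index: 1, label: Measles-1, min_age_months: 9}
      - {index: 2, label: Measles-2, min_age_months: 15, min_interval_days: 29, requires_previous: true}
coadmin_groups:
  - [[BCG, 1], [OPV, 1]]
  - [[Penta, 1], [OPV, 2], [PCV, 1], [Rota, 1]]
  - [[Penta, 2], [OPV, 3], [PCV, 2], [Rota, 2]]
  - [[Penta, 3], [OPV, 4], [PCV, 3], [IPV, 1]]
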