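# Bangladesh routine EPI schedule, 2019.
# BCG at birth; Penta/PCV/OPV at 6, 10, 14 weeks; two IPV doses at 6 and
# 14 weeks (IPV-2 additionally >28 days after IPV-1); measles-rubella at
# 9 and 15 months. No birth OPV dose and no rotavirus series.
# Same day/interval conventions as the Pakistan file.
country_id: bangladesh_2019
series:
  - antigen: BCG
    doses:
      - {index: 1, label: BCG, min_age_days: 0, max_age_years: 1}
  - antigen: OPV
    doses:
      - {index: 1, label: OPV-1, min_age_days: 42}
      - {index: 2, label: OPV-2, min_age_days: 70, min_interval_days: 29, requires_previous: true}
      - {index: 3, label: OPV-3, min_age_days: 98, min_interval_days: 29, requires_previous: true}
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
  - antigen: IPV
    doses:
      - {index: 1, label: IPV-1, min_age_days: 42}
      - {index: 2, label: IPV-2, min_age_days: 98, min_interval_days: 29, requires_previous: true}
  - antigen: MR
    doses:
      - {index: 1, label: MR-1, min_age_months: 9}
      - {index: 2, label: MR-2, min_age_months: 15, min_interval_days: 29, requires_previous: true}
coadmin_groups:
  - [[Penta, 1], [OPV, 1], [PCV, 1], [IPV, 1]]
  - [[Penta, 2], [OPV, 2], [PCV, 2]]
  - [[Penta, 3], [OPV, 3], [PCV, 3], [IPV, 2]]
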