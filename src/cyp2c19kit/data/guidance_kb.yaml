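# Curated CYP2C19 dosing/risk knowledge base for pediatric drugs cleared by
# CYP2C19.  One record per published recommendation; every number is
# traceable to its source study via the citation field.  This is a lookup
# table, not a pharmacokinetic model: percent adjustments are kept as
# intervals rather than collapsed to midpoints.

voriconazole:
  takahashi-2021:
    citation: "Takahashi et al. 2021, voriconazole PK model in pediatric hematopoietic cell transplantation"
    units: mg/kg
    normal_by_weight_band:          # half-open bands: <15, [15,30), >=30 kg
      - {max_weight_kg: 15, dose: 16}
      - {max_weight_kg: 30, dose: 12}
      - {max_weight_kg: null, dose: 10}
    multipliers:
      poor_intermediate: [0.50, 0.67]    # "33-50% lower"
      rapid_ultrarapid: [1.25, 1.50]     # "25-50% higher"
  tian-2021:
    citation: "Tian et al. 2021, voriconazole trough study in Chinese pediatric HSCT patients"
    units: mg/kg twice daily
    # doses labelled per phenotype group (UM-or-EM vs PM-or-IM); rapid
    # metabolizers are mapped to the UM/EM group (documented caveat)
    groups:
      um_em:
        under_12_years: 6.53
        over_12_years: 3.95
      pm_im:
        under_12_years: 5.75
        over_12_years: 4.23
  chen-2022:
    citation: "Chen et al. 2022, voriconazole exposure and dosing in immunocompromised children"
    units: mg/kg/day
    median_daily_dose:
      normal: {dose: 20.8, range: [16.2, 26.8]}
      intermediate: {dose: 18.2, range: [13.3, 21.8]}
      poor: {dose: 15.2, range: [10.7, 19.1]}
  package-insert:
    citation: "voriconazole drug package leaflet, pediatric weight-based dosing"
    units: mg/kg
    age_bands:
      - {max_age_years: 2, dose: [5, 7], note: "suggested for children under 2 years"}
      - {max_age_years: 12, dose: 9, note: "per 12 h IV or PO, ages 2-12"}
      - {max_age_years: null, dose: 6, note: "loading dose per 12 h IV, older than 12 years"}
  hicks-2020:
    citation: "Hicks et al. 2020, prospective CYP2C19-guided voriconazole prophylaxis in neutropenic AML"
    units: mg twice daily
    prophylaxis:
      rapid: 300
      ultra-rapid: avoid
      default: 200

trough_windows:
  standard:
    window: [1.5, 5.0]
    units: mg/L
    citation: "target trough window for voriconazole: >5 mg/L adverse effects, <1.5 mg/L treatment failure"
  garcia-garcia:
    window: [1.0, 5.5]
    units: mg/L
    citation: "Garcia-Garcia et al. 2021, immunoassay target window 1-5.5 ug/mL"

ssri:
  strawn-2019:
    citation: "Strawn et al. 2019, CYP2C19-guided escitalopram and sertraline PK modelling in pediatric patients"
    units: mg/day
    escitalopram:
      poor: 10
      normal: 20
      ultra-rapid: 30
      ultra-rapid_note: "twice-daily dosing split required to match normal-metabolizer exposure"
    sertraline:
      poor: 100
      normal: 150
      rapid: 200
      ultra-rapid: 200

risk_flags:
  - drug_class: PPI
    condition: star17_carrier
    flag: >-
      CYP2C19*17 carrier: faster PPI inactivation, reduced exposure; associated
      with PPI-refractory acid exposure and PPI-insensitive eosinophilic
      esophagitis
    citation: "Franciosi et al. 2018 (GERD pH-probe); Mougey et al. 2019 (eosinophilic esophagitis)"
  - drug_class: clopidogrel
    condition: poor_or_intermediate
    flag: >-
      reduced formation of the active clopidogrel metabolite in poor and
      intermediate metabolizers; recommendation extrapolated from adult data
      (no pediatric pharmacogenetic studies of clopidogrel yet)
    citation: "Lee et al. 2022 (CPIC clopidogrel guideline, adult evidence)"
  - drug_class: SSRI
    condition: poor
    flag: >-
      poor metabolizers on escitalopram/citalopram experience more adverse
      effects (including serotonin syndrome and faster weight gain) and more
      frequent treatment discontinuation
    citation: "Aldrich et al. 2019, escitalopram/citalopram tolerability in youth"

comedication_flags:
  - drug: omeprazole
    effect: raises voriconazole trough (competitive CYP2C19 inhibition)
    citation: "Tian et al. 2021, drug-drug interaction analysis"
  - drug: rifampicin
    effect: lowers voriconazole trough (enzyme induction)
    citation: "Tian et al. 2021, drug-drug interaction analysis"
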