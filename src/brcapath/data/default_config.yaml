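# Default (illustrative) parameter set for the brcapath model.
#
# SYNTHETIC / ILLUSTRATIVE: the curves below are smooth schedules chosen to
# match widely published magnitudes for female breast and ovarian cancer in
# BRCA1 carriers, BRCA2 carriers and the general population (BRCA1 breast
# incidence peaking near age 50 with cumulative risk ~60-65% by age 70; BRCA2
# incidence rising with age to ~50% by 70; ovarian risks ~30% / ~11%;
# population breast risk ~8% by 70 for recent cohorts).  They are NOT a
# transcription of any published penetrance table; for exact reproduction of
# published carrier probabilities, replace them with the fitted
# genotype-specific incidences of the model you wish to mirror.
#
# Rates are events per 100,000 person-years; each value applies from its age
# key (inclusive) up to the next key, on a yearly grid 0..79.

mutation_frequencies:        # population carrier probabilities
  brca1: 0.00128
  brca2: 0.00204

test_sensitivity:
  brca1: 0.70
  brca2: 0.80

polygene:
  n_loci: 3
  sd_schedule: {0: 1.65, 20: 1.40, 30: 1.28, 40: 1.15, 50: 1.03, 60: 0.90, 70: 0.78}

cohorts:
  - {label: "1900-1919", start: 1900, end: 1919}
  - {label: "1920-1929", start: 1920, end: 1929}
  - {label: "1930-1939", start: 1930, end: 1939}
  - {label: "1940-1949", start: 1940, end: 1949}
  - {label: "1950-1989", start: 1950, end: 1989}

population_incidence:
  breast:
    "1900-1919": {0: 0, 20: 0.8, 25: 6.0, 30: 18.8, 35: 45.0, 40: 90.0, 45: 135.0,
                  50: 165.0, 55: 180.0, 60: 202.5, 65: 225.0, 70: 240.0, 75: 251.2}
    "1920-1929": {0: 0, 20: 0.8, 25: 6.6, 30: 20.5, 35: 49.2, 40: 98.4, 45: 147.6,
                  50: 180.4, 55: 196.8, 60: 221.4, 65: 246.0, 70: 262.4, 75: 274.7}
    "1930-1939": {0: 0, 20: 0.9, 25: 7.0, 30: 22.0, 35: 52.8, 40: 105.6, 45: 158.4,
                  50: 193.6, 55: 211.2, 60: 237.6, 65: 264.0, 70: 281.6, 75: 294.8}
    "1940-1949": {0: 0, 20: 0.9, 25: 7.5, 30: 23.5, 35: 56.4, 40: 112.8, 45: 169.2,
                  50: 206.8, 55: 225.6, 60: 253.8, 65: 282.0, 70: 300.8, 75: 314.9}
    "1950-1989": {0: 0, 20: 1.0, 25: 8.0, 30: 25.0, 35: 60.0, 40: 120.0, 45: 180.0,
                  50: 220.0, 55: 240.0, 60: 270.0, 65: 300.0, 70: 320.0, 75: 335.0}
  ovarian:
    all: {0: 0, 30: 5, 40: 15, 50: 30, 60: 45, 70: 55}

carrier_incidence:
  breast:
    brca1: {0: 0, 20: 20, 25: 400, 30: 1200, 35: 2200, 40: 2900, 45: 3200,
            50: 2900, 55: 2600, 60: 2300, 65: 2100, 70: 1900}
    brca2: {0: 0, 20: 10, 25: 100, 30: 300, 35: 700, 40: 1200, 45: 1700,
            50: 2000, 55: 2200, 60: 2500, 65: 2700, 70: 3000}
  ovarian:
    brca1: {0: 0, 30: 30, 40: 800, 50: 1400, 60: 1500, 70: 1400}
    brca2: {0: 0, 40: 50, 50: 500, 60: 700, 70: 800}

# Proportion of incident breast cancers that are ER-negative in the general
# population, by age at diagnosis (10-year bands, decreasing with age; the
# incidence-weighted under-70 aggregate is ~0.36).
population_er_negative_proportion: {0: 0.55, 30: 0.48, 40: 0.42, 50: 0.36, 60: 0.30, 70: 0.25}

options:
  survivor_pool: breast_ovarian   # remove women from the unaffected pool on either cancer
  use_brca2_er_table: false       # default: population ER curve for BRCA2 tumours
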