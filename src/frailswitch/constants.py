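"""Literature-derived constants that define the study conditions.

These are the printed values the whole pipeline is built around: the
physiological ceilings used to pin production/degradation ratios, the
cohort baseline means and annual biomarker trends, the disabled-compartment
mortality amplifier, the population-extinction horizon, and the four-way
stratification of the reference cohort of 718 community-dwelling women.
"""

# Physiological maxima (uninhibited steady states of the toggle)
MAX_IGF1 = 400.0  # ng/ml
MAX_IL6 = 25.0    # pg/ml

# Cohort baseline means
MEAN_IGF1 = 107.8  # ng/ml (== mcg/L)
MEAN_IL6 = 3.14    # pg/ml

# Linear biomarker trends with age
IGF1_SLOPE_PER_YEAR = -1.95  # ng/ml per year
IL6_SLOPE_PER_YEAR = 0.05    # pg/ml per year

# Mortality structure
K_EXTRA = 2.5                     # hazard amplifier for the disabled state
MORTALITY_RATIO_5Y = 2.5          # 5-year mortality, worst vs best cohort
LONGEVITY_HORIZON_MONTHS = 240.0  # maximal survival after baseline
EXTINCTION_TOL = 1e-3             # operational definition of "maximal survival"

# Four-way stratification (high/low IGF-1 x high/low IL-6)
COHORT_COUNTS = {
    "highIGF_lowIL6": 398,
    "highIGF_highIL6": 128,
    "lowIGF_lowIL6": 142,
    "lowIGF_highIL6": 50,
}
TOTAL_N = 718

# Cohorts ordered from lowest to highest clinical risk
RISK_ORDER = (
    "highIGF_lowIL6",
    "lowIGF_lowIL6",
    "highIGF_highIL6",
    "lowIGF_highIL6",
)

# Initial-condition scan ranges (IL-6 range 0.001-0.01 mcg/L == 1-10 pg/ml)
SCAN_IGF1_RANGE = (40.0, 300.0)
SCAN_IL6_RANGE = (1.0, 10.0)

MONTHS_PER_YEAR = 12.0
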