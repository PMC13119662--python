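"""Single versioned block of exposure-assessment constants.

Every toxicological benchmark, consumer-group body weight, intake parameter
and advisory threshold used anywhere in the package lives here, so that a
change (e.g. a revised reference dose) propagates consistently.

Units are stated per constant; concentrations are mg THg per kg wet weight
throughout the package, intake rates in grams of fish per week unless a
name says otherwise.
"""

from __future__ import annotations

#: Oral reference dose for methylmercury, mg per kg body weight per day
#: (US EPA benchmark, 0.1 ug/kg/day).
RFD_MG_KG_DAY: float = 0.0001

#: Tolerable weekly intake for methylmercury, mg per kg body weight per week
#: (EFSA benchmark, 1.3 ug/kg/week).
TWI_MG_KG_WEEK: float = 0.0013

#: Fixed body weights by consumer group, kg.
BODY_WEIGHT_KG: dict[str, float] = {
    "adults": 70.0,
    "pregnant": 60.0,
    "children": 15.0,
}

#: National average fish consumption, g per week (7.3 kg/year; 7300 * 7 / 365).
BASELINE_IR_G_WEEK: float = 140.0

#: Annual consumption corresponding to the weekly baseline, g per year.
BASELINE_IR_G_YEAR: float = 7300.0

#: Triangular weekly-intake distribution (min, mode, max), g per week.
TRI_MIN_G_WEEK: float = 50.0
TRI_MODE_G_WEEK: float = 140.0
TRI_MAX_G_WEEK: float = 350.0

#: Monte Carlo iteration count.
MC_N_ITER: int = 30_000

#: Traffic-light advisory bounds on safe weekly intake, g per week:
#: red below RED_BELOW, yellow in [RED_BELOW, GREEN_FROM), green at/above.
RED_BELOW_G_WEEK: float = 140.0
GREEN_FROM_G_WEEK: float = 300.0

#: Analytical limit of detection for total mercury, mg per kg wet weight
#: (0.05 ug/kg).
LOD_MG_KG: float = 0.00005

#: Days per week, used for the exact weekly -> daily intake conversion
#: (140 g/week == 0.02 kg/day).
DAYS_PER_WEEK: float = 7.0

#: Default fraction of muscle THg treated as methylmercury. Muscle mercury is
#: predominantly methylated (commonly 80-95%), and total mercury is used as a
#: 1:1 proxy by default; set below 1 to explore the speciation caveat.
MEHG_FRACTION: float = 1.0
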