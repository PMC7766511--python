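"""Published reference summaries from a North American Angus evaluation.

Worked-example inputs: summary numbers printed in a published genetic
evaluation of longevity in ~600k North American Angus cows.  They are
used to exercise the aggregation arithmetic of this package (culling
group additivity, posterior model probabilities from printed DIC pairs,
grand means of printed correlation tables, commonly-selected averages)
without access to the underlying proprietary records.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CULLING_GROUP_COUNTS",
    "ALL_REASONS_TOTAL",
    "KNOWN_REASONS_TOTAL",
    "DIC_TABLE",
    "BETWEEN_REASON_CORR",
    "BETWEEN_DEFINITION_CORR",
    "COMMONLY_SELECTED_TOP1",
]

#: cows per culling-reason class, grouped (class name -> count)
CULLING_GROUP_COUNTS = {
    "natural_death": {
        "died_unknown": 55_232,
        "culled_due_to_age": 94_997,
    },
    "structural_problems": {
        "eye_problem": 499,
        "body_structure": 13_101,
        "teat_udder_conformation": 5_845,
        "rectal_prolapse": 73,
        "vaginal_prolapse": 103,
        "feet_conformation": 5_183,
    },
    "disease": {"illness_disease": 4_994},
    "fertility": {
        "fertility": 124_696,
        "missed_calving_opportunity": 29_723,
    },
    "performance": {
        "productivity_performance": 53_837,
        "temperament": 8_168,
    },
    "miscellaneous": {
        "culled_miscellaneous": 44_563,
        "sold_commercial": 163_529,
    },
}

#: printed total over all culling reasons
ALL_REASONS_TOTAL = 604_543
#: printed phenotyped total of the five known culling reasons
#: (natural death, structural problems, disease, fertility, performance)
KNOWN_REASONS_TOTAL = 396_451

#: DIC printed per culling group and longevity definition for the
#: order-4 model, (homogeneous, heterogeneous) residual variance
DIC_TABLE = {
    ("natural_death", "TL"): (-14_333_660, -97_527_370),
    ("natural_death", "FLa"): (-2_998_505, -7_435_206),
    ("natural_death", "FLb"): (-35_724_631_037, -162_024_103_613),
    ("structural_problems", "TL"): (-1_947_409, -275_489),
    ("structural_problems", "FLa"): (-937_946, -2_624_539),
    ("structural_problems", "FLb"): (-3_032_840_387, -11_343_283_933),
    ("disease", "TL"): (-432_592, -63_888),
    ("disease", "FLa"): (-219_798, -765_673),
    ("disease", "FLb"): (-1_728_658_673, -69_837_105_629),
    ("fertility", "TL"): (-15_460_202, -137_123_460),
    ("fertility", "FLa"): (-5_952_231, -13_167_214),
    ("fertility", "FLb"): (-15_053_722_233, -691_563_543_599),
    ("performance", "TL"): (-5_518_605, -52_327_651),
    ("performance", "FLa"): (-3_418_738, -7_036_948),
    ("performance", "FLb"): (-6_421_240_367, -28_107_833_193),
    ("miscellaneous", "TL"): (-19_534_605, -153_303_945),
    ("miscellaneous", "FLa"): (-7_195_212, -15_449_397),
    ("miscellaneous", "FLb"): (-26_940_276_644, -26_942_298_626),
    ("all_reasons", "TL"): (-32_816_459, -44_115_210),
    ("all_reasons", "FLa"): (-20_020_368, -20_113_943),
    ("all_reasons", "FLb"): (-85_088_486_564, -93_934_683_621),
}

#: per-pair average genetic correlations between culling reasons
#: (rows: the ten reason pairs; "Average" column of the printed table)
BETWEEN_REASON_CORR = {
    "all_ages": np.array(
        [0.13, 0.02, 0.14, 0.18, 0.12, 0.15, 0.16, 0.05, 0.00, 0.24]),
    "3_to_12": np.array(
        [0.22, 0.00, 0.20, 0.25, 0.25, 0.27, 0.26, 0.16, 0.01, 0.39]),
}

#: average genetic correlations between longevity definitions per known
#: culling reason (natural death, structural, disease, fertility,
#: performance), ages 3 to 12
BETWEEN_DEFINITION_CORR_3_12 = {
    ("TL", "FLa"): np.array([0.58, 0.72, 0.63, 0.52, 0.73]),
    ("TL", "FLb"): np.array([0.75, 0.76, 0.72, 0.67, 0.76]),
    ("FLa", "FLb"): np.array([0.60, 0.72, 0.63, 0.57, 0.74]),
}
BETWEEN_DEFINITION_CORR = BETWEEN_DEFINITION_CORR_3_12  # short alias

#: commonly-selected top-1% sire percentages per known culling reason,
#: ages 3 to 12
COMMONLY_SELECTED_TOP1 = {
    ("TL", "FLa"): np.array([45.32, 66.73, 63.56, 43.65, 79.12]),
    ("TL", "FLb"): np.array([91.49, 92.50, 93.51, 88.52, 92.67]),
    ("FLa", "FLb"): np.array([48.74, 67.31, 64.07, 44.62, 80.30]),
}
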