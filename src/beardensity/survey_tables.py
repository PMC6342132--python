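"""Published summary numbers from the 2013-2014 southwestern Alberta
black bear rub-object survey, used as worked-example inputs and as
checks on the information-criterion machinery.

These are survey-level summaries (detection tallies, model-selection
rows, abundance tables, study-area composition), not the individual
capture histories, which are not bundled here.
"""

#: Detections per occasion (occasions 1-7 systematic, 8 opportunistic).
DETECTIONS_BY_OCCASION = {
    (2013, "M"): [99, 78, 46, 16, 20, 23, 12, 12],
    (2013, "F"): [16, 26, 24, 41, 22, 29, 11, 8],
    (2014, "M"): [108, 77, 34, 19, 16, 18, 7, 15],
    (2014, "F"): [27, 27, 20, 23, 32, 16, 10, 13],
}

#: Individuals detected per year and sex.
INDIVIDUALS = {
    (2013, "M"): 126,
    (2013, "F"): 101,
    (2014, "M"): 122,
    (2014, "F"): 100,
}

#: Unique bears identified across both years.
UNIQUE_BEARS = {"M": 186, "F": 161}

#: Number of established rub objects.
N_RUB_OBJECTS = 873

#: Random:used ratio for the placement-bias RSF.
AVAILABLE_RATIO = 20

#: Study-area composition, km^2.
TENURE_AREA_KM2 = {"private": 1872.0, "crown": 1204.0, "protected": 511.0}
STUDY_AREA_KM2 = 3600.0

#: Selected model-selection rows (log-likelihood, parameter count) with
#: the matching sample size (detected individuals).
MODEL_ROWS = {
    "males_2013_step1_top": {"LL": -1750.67, "K": 8, "n": 126},
    "females_2013_step2_top": {"LL": -940.50, "K": 9, "n": 101},
}

#: Delta-AICc values of the eight reported 2013 male step-2 models.
MALE_2013_STEP2_DAICC = [0.0, 2.52, 2.87, 6.25, 6.82, 7.17, 7.42, 7.76]

#: Abundance point estimates by tenure (from the SECR density surfaces).
ABUNDANCE = {
    ("M", 2013): {"protected": 33.4, "private": 79.6, "crown": 31.8},
    ("F", 2013): {"protected": 49.8, "private": 183.0, "crown": 37.9},
    ("M", 2014): {"protected": 41.7, "private": 59.1, "crown": 28.5},
    ("F", 2014): {"protected": 44.4, "private": 133.6, "crown": 32.7},
}

#: Independent Glacier National Park reference densities per 1,000 km^2
#: (point, 95% lo, 95% hi) used to anchor the RSF extrapolation.
REFERENCE_DENSITY = {
    "M": (48.3, 40.2, 57.3),
    "F": (72.3, 60.3, 87.5),
}
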