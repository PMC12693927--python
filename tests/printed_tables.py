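"""Published summary-table values used as test inputs and expectations.

TABLE6 holds the per-stage time-in-category percentages per sensor and
period together with the printed per-period "Average" rows (unweighted
stage means).  Economics inputs live in
``microclim.summaries.DEFAULT_ECONOMIC_INPUTS``.
"""

STAGES = ("vegetative", "reproductive", "harvest")

# sensor -> period -> {"stages": {stage: (opt, sub, crit)},
#                      "average": (opt, sub, crit)}
TABLE6 = {
    "S1-EQ": {
        "day": {"stages": {"vegetative": (33.5, 22.8, 43.7),
                           "reproductive": (45.8, 29.2, 25.0),
                           "harvest": (28.8, 27.4, 43.8)},
                "average": (36.0, 26.5, 37.5)},
        "night": {"stages": {"vegetative": (11.6, 28.9, 59.5),
                             "reproductive": (1.2, 14.8, 84.0),
                             "harvest": (15.8, 27.2, 57.0)},
                  "average": (9.5, 23.6, 66.8)},
    },
    "S2-NQ": {
        "day": {"stages": {"vegetative": (30.4, 28.6, 41.0),
                           "reproductive": (40.1, 28.4, 31.5),
                           "harvest": (30.6, 25.1, 44.3)},
                "average": (33.7, 27.4, 38.9)},
        "night": {"stages": {"vegetative": (15.6, 33.5, 50.9),
                             "reproductive": (1.0, 18.9, 80.1),
                             "harvest": (18.8, 35.8, 45.4)},
                  "average": (11.8, 29.4, 58.8)},
    },
    "S3-SQ": {
        "day": {"stages": {"vegetative": (48.0, 21.4, 30.6),
                           "reproductive": (43.1, 35.6, 21.3),
                           "harvest": (28.0, 29.4, 42.6)},
                "average": (39.7, 28.8, 31.5)},
        "night": {"stages": {"vegetative": (1.7, 6.8, 91.5),
                             "reproductive": (0.6, 5.2, 94.2),
                             "harvest": (18.0, 25.4, 56.6)},
                  "average": (6.8, 12.5, 80.8)},
    },
    "S4-WQ": {
        "day": {"stages": {"vegetative": (44.4, 21.9, 33.7),
                           "reproductive": (34.7, 44.1, 21.2),
                           "harvest": (15.5, 26.5, 58.0)},
                "average": (31.5, 30.8, 37.6)},
        "night": {"stages": {"vegetative": (2.6, 13.4, 84.0),
                             "reproductive": (3.0, 11.9, 85.1),
                             "harvest": (26.4, 37.9, 35.7)},
                  "average": (10.7, 21.1, 68.3)},
    },
}
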