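"""Published model-choice summaries for the four dissemination hypotheses.

The grapevine east-to-west dissemination analysis reports, for each of its
four competing-hypothesis groups, the per-scenario logistic-regression
posterior probability (percent), its 95% confidence interval, and the
number of summary statistics (out of 9) deviating significantly from the
observed data at p < 0.05 and p < 0.01.  These printed values serve as the
worked example for the scenario-selection rule: feeding them to
:func:`~vineflow.inference.select_best_scenario` reproduces the published
winners (S1, S6, S7, S10).
"""

from __future__ import annotations

from .inference import SelectionResult, select_best_scenario

#: Reported per-scenario posterior probabilities (%), 95% CIs (%) and
#: outlying-statistic counts for each hypothesis group.
REPORTED_MODEL_CHOICE: dict[str, dict[str, dict]] = {
    "hypothesis_1": {
        "S1": {"pp": 74, "ci": (72, 79), "outliers_05": 1, "outliers_01": 2},
        "S2": {"pp": 51, "ci": (48, 54), "outliers_05": 6, "outliers_01": 0},
        "S3": {"pp": 43, "ci": (40, 45), "outliers_05": 2, "outliers_01": 3},
    },
    "hypothesis_2": {
        "S4": {"pp": 52, "ci": (46, 53), "outliers_05": 0, "outliers_01": 4},
        "S5": {"pp": 57, "ci": (55, 64), "outliers_05": 2, "outliers_01": 2},
        "S6": {"pp": 81, "ci": (75, 82), "outliers_05": 1, "outliers_01": 2},
    },
    "hypothesis_3": {
        "S7": {"pp": 88, "ci": (82, 91), "outliers_05": 1, "outliers_01": 2},
        "S8": {"pp": 57, "ci": (54, 64), "outliers_05": 2, "outliers_01": 2},
        "S9": {"pp": 38, "ci": (32, 40), "outliers_05": 2, "outliers_01": 2},
    },
    "hypothesis_4": {
        "S10": {"pp": 75, "ci": (71, 79), "outliers_05": 2, "outliers_01": 2},
        "S11": {"pp": 46, "ci": (42, 48), "outliers_05": 3, "outliers_01": 4},
        "S12": {"pp": 58, "ci": (57, 60), "outliers_05": 3, "outliers_01": 2},
    },
}

#: Reported overall classification performance (%) per hypothesis group.
REPORTED_PERFORMANCE = {
    "hypothesis_1": 77,
    "hypothesis_2": 87,
    "hypothesis_3": 92,
    "hypothesis_4": 88,
}


def reported_selection(hypothesis: str) -> SelectionResult:
    """Apply the selection rule to the reported values of one hypothesis.

    Outlying-statistic counts at the two significance thresholds are summed
    into the single count the rule consumes.
    """
    rows = REPORTED_MODEL_CHOICE[hypothesis]
    summaries = {
        sid: {
            "pp": float(v["pp"]),
            "ci": v["ci"],
            "n_outlying": v["outliers_05"] + v["outliers_01"],
        }
        for sid, v in rows.items()
    }
    return select_best_scenario(summaries)
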