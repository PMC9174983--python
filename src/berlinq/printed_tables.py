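"""Class-conditional response tables of the reference survey cohort.

These are the per-item answer counts of a cross-sectional survey of 387
Italian professional nurses (311 scored low-risk, 76 high-risk for
obstructive sleep apnea by the Berlin Questionnaire), broken down by risk
group.  They serve two purposes:

* calibration targets for the synthetic-cohort generator
  (:mod:`berlinq.simulate`), and
* grouped inputs for closed-form group statistics and discrimination
  scores, so those quantities can be reproduced without individual-level
  data.

Levels are stored in canonical questionnaire order (the order answer
options are presented to a respondent), which for yes/no items is
``No < Do not know < Yes``.  A few cells of the published summary are
internally inconsistent (counts not summing to the group size, or a count
recoverable only from its percentage); such tables are transcribed as-is
and flagged ``consistent=False`` rather than repaired.
"""

from __future__ import annotations

from dataclasses import dataclass

N_LOW = 311
N_HIGH = 76
N_TOTAL = N_LOW + N_HIGH

#: shared answer scales
NDY = ("No", "Do not know", "Yes")
FREQ5 = (
    "Never or almost never",
    "1–2 times a month",
    "1–2 times a week",
    "3–4 times a week",
    "Every day",
)
LOUDNESS = (
    "Slightly louder than breathing",
    "As loud as talking",
    "Louder than talking",
    "Very loud—it can be heard from adjacent rooms",
)
SYMPTOM5 = (
    "Never",
    "About once a week",
    "Two or three times a week",
    "Almost every day",
    "Several times a day",
)
SYMPTOM6 = ("I have not had these problems",) + SYMPTOM5
YN = ("Yes", "No")
NY = ("No", "Yes")
BMI_GROUPS = (
    "Underweight <18.5",
    "Normal weight 18.5–24.9",
    "Overweight 25–29.9",
    "Obese ≥30",
)
#: continuous BMI range backing each BMI group, kg/m^2 (survey range 18–46)
BMI_BIN_EDGES = ((18.0, 18.5), (18.5, 25.0), (25.0, 30.0), (30.0, 46.0))


@dataclass(frozen=True)
class ClassConditionalTable:
    """Level-by-risk-group counts for one questionnaire item.

    ``missing_low`` / ``missing_high`` hold structurally or otherwise
    unanswered respondents; level counts exclude them.  ``consistent`` is
    False where the published cell values do not add up to the group sizes.
    """

    item_id: str
    levels: tuple[str, ...]
    counts_low: tuple[int, ...]
    counts_high: tuple[int, ...]
    missing_low: int = 0
    missing_high: int = 0
    consistent: bool = True

    def __post_init__(self) -> None:
        if not (len(self.levels) == len(self.counts_low) == len(self.counts_high)):
            raise ValueError(f"{self.item_id}: level/count length mismatch")
        if any(c < 0 for c in self.counts_low + self.counts_high):
            raise ValueError(f"{self.item_id}: negative count")
        if (sum(self.counts_low) + self.missing_low == 0
                or sum(self.counts_high) + self.missing_high == 0):
            raise ValueError(f"{self.item_id}: a class has no mass at all")

    def totals(self) -> tuple[int, int]:
        return (sum(self.counts_low) + self.missing_low,
                sum(self.counts_high) + self.missing_high)


def _t(item_id, levels, low, high, missing_low=0, missing_high=0, consistent=True):
    return ClassConditionalTable(item_id, tuple(levels), tuple(low), tuple(high),
                                 missing_low, missing_high, consistent)


# --- Berlin Questionnaire items, by risk group -------------------------------

BQ_TABLES: tuple[ClassConditionalTable, ...] = (
    _t("B1", NDY, (164, 83, 64), (2, 2, 72)),
    _t("B2", LOUDNESS, (213, 5, 11, 8), (35, 8, 12, 21), 74, 0),
    _t("B3", FREQ5, (173, 46, 41, 20, 31), (1, 5, 9, 13, 48)),
    _t("B4", NDY, (172, 71, 68), (9, 6, 61)),
    _t("B5", FREQ5, (299, 3, 3, 3, 3), (41, 10, 11, 8, 6)),
    _t("B6", FREQ5, (117, 73, 68, 23, 30), (8, 9, 9, 16, 34)),
    _t("B7", FREQ5, (76, 82, 88, 33, 32), (8, 6, 11, 17, 34)),
    _t("B8", NDY, (284, 0, 27), (58, 0, 18)),
    _t("B9", FREQ5, (212, 15, 5, 1, 0), (37, 7, 5, 2, 3), 78, 22),
    _t("B10", NDY, (284, 11, 16), (33, 4, 39)),
)

BQ_TEXT: dict[str, str] = {
    "B1": "Do you snore?",
    "B2": "If you answered yes: how loud is your snoring?",
    "B3": "How often do you snore?",
    "B4": "Has your snoring ever bothered other people?",
    "B5": "Has anyone noticed that you stop breathing during your sleep?",
    "B6": "How often do you feel tired or fatigued after your sleep?",
    "B7": "During your waking time, do you feel tired, fatigued or not up to par?",
    "B8": "Have you ever nodded off or fallen asleep while driving a vehicle?",
    "B9": "How often does this occur?",
    "B10": "Do you have high blood pressure?",
}

# --- extended (proprietary) questionnaire items, by risk group ---------------

EXTENDED_TABLES: tuple[ClassConditionalTable, ...] = (
    _t("Q1", ("Female", "Male"), (247, 64), (46, 30)),
    _t("Q2", ("21–30", "31–40", "41–50", "51–60", ">61"),
       (103, 75, 68, 62, 3), (12, 13, 32, 16, 3)),
    _t("Q3", BMI_GROUPS, (6, 179, 73, 53), (2, 25, 27, 22)),
    _t("Q4", ("Yes", "No", "Ex-smoker"), (81, 190, 40), (23, 39, 14)),
    _t("Q5", ("<43 men/41 women", "≥43 men/41 women", "Unknown"),
       (135, 18, 158), (29, 11, 36)),
    _t("Q6", ("Nurse", "Coordinator", "Executive", "Other"),
       (282, 22, 1, 6), (63, 5, 6, 2)),
    _t("Q7", ("Regional Diploma", "University Diploma", "Bachelor's degree",
              "Master degree", "Post-graduate"),
       (61, 20, 167, 34, 29), (24, 7, 31, 8, 6)),
    _t("Q8", ("1–5", "6–10", "11–15", "16–20", "21–25", "26–30", ">31"),
       (118, 32, 29, 30, 27, 37, 38), (12, 15, 2, 13, 15, 8, 11)),
    _t("Q9", ("Full-time", "Part-time"), (284, 27), (72, 4)),
    _t("Q10", ("Daily shift only", "24 h shift"), (129, 182), (33, 43)),
    _t("Q11", YN, (193, 118), (42, 34)),
    _t("Q12", YN, (2, 309), (18, 58)),
    _t("Q13", NY, (265, 46), (60, 16)),
    _t("Q14", NY, (272, 39), (48, 28)),
    _t("Q15", NY, (310, 1), (71, 5)),
    _t("Q16", NY, (305, 6), (65, 11)),
    _t("Q17", NY, (309, 2), (73, 3)),
    _t("Q18", NY, (207, 104), (35, 41)),
    # high counts sum to 74 of 76; shortfall carried as missing
    _t("Q19", NY, (239, 72), (38, 36), 0, 2, consistent=False),
    _t("Q20", NY, (310, 1), (70, 6)),
    # low counts sum to 321 > 311 as published
    _t("Q21", NY, (291, 30), (58, 18), consistent=False),
    _t("Q22", NY, (303, 8), (68, 8)),
    _t("Q23", NY, (308, 3), (71, 5)),
    _t("Q24", NY, (307, 4), (71, 5)),
    _t("Q25", NY, (280, 31), (60, 16)),
    # low "Yes" percentage cell garbled in the published table
    _t("Q26", NY, (305, 6), (74, 2), consistent=False),
    _t("Q27", SYMPTOM5, (284, 20, 3, 3, 1), (58, 8, 5, 3, 2)),
    _t("Q28", SYMPTOM5, (152, 117, 33, 7, 2), (22, 22, 14, 11, 7)),
    _t("Q29", SYMPTOM5, (195, 89, 16, 8, 3), (36, 16, 15, 6, 3)),
    # high "Almost every day" count reconstructed from its printed percentage (28% of 76)
    _t("Q30", SYMPTOM5, (132, 62, 29, 69, 19), (21, 12, 13, 21, 9), consistent=False),
    _t("Q31", SYMPTOM6, (138, 112, 48, 8, 4, 1), (30, 15, 15, 12, 3, 1)),
    _t("Q32", SYMPTOM6, (133, 104, 58, 9, 6, 1), (15, 27, 17, 11, 5, 1)),
    _t("Q33", SYMPTOM5, (189, 92, 22, 4, 4), (34, 17, 15, 7, 3)),
    _t("Q34", SYMPTOM5, (169, 106, 19, 14, 3), (26, 23, 14, 7, 6)),
    # low counts sum to 325 > 311 as published
    _t("Q35", SYMPTOM5, (180, 105, 17, 6, 17), (26, 25, 13, 10, 2), consistent=False),
    _t("Q36", SYMPTOM5, (208, 82, 9, 12, 0), (41, 15, 10, 8, 2)),
    _t("Q37", SYMPTOM5, (165, 115, 16, 11, 4), (26, 25, 12, 11, 2)),
    _t("Q38", SYMPTOM5, (79, 99, 69, 61, 3), (5, 23, 18, 27, 3)),
)

EXTENDED_TEXT: dict[str, str] = {
    "Q1": "Gender",
    "Q2": "Age (Y)",
    "Q3": "BMI group (kg/m^2)",
    "Q4": "Smoking",
    "Q5": "Neck circumference (cm)",
    "Q6": "Profession",
    "Q7": "Instruction level",
    "Q8": "Work experience (Y)",
    "Q9": "Working hours",
    "Q10": "Work shift",
    "Q11": "Work shift regularity",
    "Q12": "Previous OSA diagnosis",
    "Q13": "Hypo/hyperthyroidism",
    "Q14": "Arrhythmias",
    "Q15": "Transient ischemic attack or stroke",
    "Q16": "Diabetes mellitus",
    "Q17": "Presence of cerebrovascular diseases",
    "Q18": "Anxiety",
    "Q19": "Sleep disorders",
    "Q20": "Chronic obstructive pulmonary disease (COPD)",
    "Q21": "Asthma",
    "Q22": "Frequent confusion or agitation",
    "Q23": "Alcohol abuse",
    "Q24": "Drug abuse",
    "Q25": "Depression",
    "Q26": "Craniofacial morphological alterations",
    "Q27": "Have you ever fallen asleep during an activity (e.g., during work)?",
    "Q28": "Did you have difficulty concentrating during an assignment?",
    "Q29": "Did you have to force yourself to express yourself clearly?",
    "Q30": "Have you had to use stimulants (coffee, tea, ginseng, etc.) to stay active?",
    "Q31": "Have the problems reported in the previous questions interfered with your ability to work?",
    "Q32": "Have the problems reported in the previous questions interfered with your social relationships?",
    "Q33": "Have your reactions in everyday situations been slow?",
    "Q34": "Did you have to try harder than usual to keep track of what you were doing?",
    "Q35": "Did you have difficulty paying attention for a long time on a task?",
    "Q36": "Have you had difficulty paying attention to multiple tasks at once?",
    "Q37": "Did you have to work hard to pay attention and not make mistakes?",
    "Q38": "Did you feel the need to doze off during the course of the day?",
}

ALL_TABLES: tuple[ClassConditionalTable, ...] = BQ_TABLES + EXTENDED_TABLES
TABLES_BY_ID: dict[str, ClassConditionalTable] = {t.item_id: t for t in ALL_TABLES}


def get_table(item_id: str) -> ClassConditionalTable:
    try:
        return TABLES_BY_ID[item_id]
    except KeyError:
        raise KeyError(f"no reference table for item {item_id!r}") from None
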