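"""Published cohort summary tables used as inputs to the baseline test
battery and to the generator defaults.

The study enrolled 13 full-term neonates with congenital heart disease
(CHD) and 30 healthy controls (HC).  Raw per-subject data are not part of
this package; what is recomputable at the desk are the between-group tests
on the printed counts and mean/SD/n summaries below, and those summaries
also anchor the synthetic cohort generator.
"""

from __future__ import annotations

import numpy as np

from .cohort_stats import ContingencyTable, SummaryStats

__all__ = ["N_CHD", "N_HC", "GENDER_TABLE", "DELIVERY_TABLE", "FEEDING_TABLE",
           "MATERNAL_NUTRITION_TABLE", "BIRTH_WEIGHT", "AGE_AT_SAMPLING",
           "GESTATIONAL_AGE", "ANTIBIOTICS", "GBS", "CORE_GENERA",
           "SPO2_MEAN", "SPO2_SD"]

N_CHD = 13
N_HC = 30

# columns are (CHD, HC) throughout
GENDER_TABLE = ContingencyTable(
    ["female", "male"], ["CHD", "HC"], np.array([[4, 11], [9, 19]]))

DELIVERY_TABLE = ContingencyTable(
    ["cesarean", "vaginal"], ["CHD", "HC"], np.array([[6, 17], [7, 13]]))

FEEDING_TABLE = ContingencyTable(
    ["breastfeeding", "formula", "mixed", "TPN"], ["CHD", "HC"],
    np.array([[8, 20], [3, 10], [2, 0], [0, 0]]))

MATERNAL_NUTRITION_TABLE = ContingencyTable(
    ["meat", "vegetarian", "vegan", "unknown"], ["CHD", "HC"],
    np.array([[13, 26], [0, 2], [0, 0], [0, 2]]))

BIRTH_WEIGHT = {"CHD": SummaryStats(3153, 539, 13), "HC": SummaryStats(3332, 519, 30)}
AGE_AT_SAMPLING = {"CHD": SummaryStats(7.8, 3.1, 13), "HC": SummaryStats(1.7, 1.5, 30)}
GESTATIONAL_AGE = {"CHD": SummaryStats(38.2, 2.7, 13), "HC": SummaryStats(39.0, 1.7, 30)}

# (affected, group size): maternal antibiotics during pregnancy, GBS colonization
ANTIBIOTICS = {"CHD": (4, 13), "HC": (21, 30)}
GBS = {"CHD": (1, 13), "HC": (3, 30)}

# the ten most frequent genera of the cohort, in descending overall abundance
CORE_GENERA = ["Enterococcus", "Staphylococcus", "Escherichia", "Bacteroides",
               "Bifidobacterium", "Parabacteroides", "Enterobacter",
               "Pseudomonas", "Klebsiella", "Streptococcus"]

# pulse-oximetry SpO2 of the CHD cohort (percent)
SPO2_MEAN = 90.9
SPO2_SD = 3.4
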