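"""Published summary tables from the Gayasan National Park survey.

A 2012 ethnomedicinal field survey of 208 informants living in and around
Gayasan National Park (Korea) recorded 200 medicinal vascular-plant species
across 16 Heinrich-style ailment categories. The raw use-report table was
never deposited, but the survey's printed summary tables — per-category
taxa/citation counts with their informant consensus factors, demographic
counts, and per-species fidelity rows — are transcribed here. They serve as
worked-example inputs and as reference behaviour for the index
implementations; full-pipeline behaviour is exercised on synthetic surveys
(:mod:`ethnokit.simulate`).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "GAYASAN_CATEGORY_COUNTS",
    "GAYASAN_DEMOGRAPHICS",
    "ACHYRANTHES_FIDELITY_ROWS",
    "SIX_ROW_BARLEY_AILMENTS",
    "category_counts_frame",
]

#: Per ailment category: (distinct taxa nt, use citations nur, printed ICF
#: at 2 dp). Sorted as printed: ICF descending.
GAYASAN_CATEGORY_COUNTS: tuple = (
    ("Muscular-skeletal disorders", 49, 2142, 0.98),
    ("Pains", 87, 2942, 0.97),
    ("Respiratory system disorders", 46, 1513, 0.97),
    ("Liver complaints", 15, 447, 0.97),
    ("Cuts and wounds", 20, 473, 0.96),
    ("Inflammation", 28, 587, 0.95),
    ("Genitourinary system disorders", 52, 1062, 0.95),
    ("Circulatory system disorders", 65, 1250, 0.95),
    ("Skin diseases and disorders", 25, 464, 0.95),
    ("Gastrointestinal disorders", 68, 1257, 0.95),
    ("Diabetes", 10, 165, 0.95),
    ("Nervous system disorders", 34, 545, 0.94),
    ("Veterinary ailments", 22, 300, 0.93),
    ("Poisonings", 26, 321, 0.92),
    ("Others", 36, 431, 0.92),
    ("Birth-related disorders", 14, 138, 0.91),
)

#: Headline survey counts used by the ratio computations.
GAYASAN_DEMOGRAPHICS = {
    "n_informants": 208,
    "n_male_informants": 28,
    "n_female_informants": 180,
    "n_medicinal_species": 200,
    "n_flora_species": 542,
    "n_rosaceae_species": 13,
    "n_families": 87,
    "n_genera": 168,
}

#: Fidelity-level rows printed for *Achyranthes japonica* (Miq.) Nakai:
#: nine ailments whose 2-dp FLs partition the species' citations to 100.00.
ACHYRANTHES_FIDELITY_ROWS: tuple = (
    ("Arm pain", 16.71),
    ("Arthritis", 1.62),
    ("Bone diseases", 32.61),
    ("Common cold", 2.43),
    ("Convulsion", 3.23),
    ("Knee pain", 2.16),
    ("Leg pain", 31.54),
    ("Lumbago", 9.16),
    ("Pollakiuria", 0.54),
)

#: The 36 distinct ailments recorded for six-row barley
#: (*Hordeum vulgare* var. *hexastichon*), the broadest pharmacopoeia entry
#: of the survey.
SIX_ROW_BARLEY_AILMENTS: tuple = (
    "Abdominal pain",
    "Arm pain",
    "Arthritis",
    "Bone diseases",
    "Cancer",
    "Carpal tunnel syndrome",
    "Chronic myofascial pain",
    "Common cold",
    "Cough",
    "Edema",
    "Eye disease",
    "Fatigue",
    "Finger pain",
    "Gastric ulcer",
    "Gastritis",
    "Gastroenteric disorder",
    "Hemorrhaging",
    "Hookworm",
    "Hyperthermia",
    "Hypofunction",
    "Indigestion",
    "Jaundice",
    "Leg pain",
    "Liver diseases",
    "Lumbago",
    "Paralysis",
    "Pollakiuria",
    "Pruritus",
    "Pus",
    "Raynaud's Phenomenon",
    "Sexual enhancement",
    "Shoulder pain",
    "Sinews and joint pain",
    "Skin diseases",
    "Tarsal tunnel syndrome",
    "Woman diseases",
)


def category_counts_frame() -> pd.DataFrame:
    """The published per-category (nt, nur, printed ICF) table as a frame."""
    return pd.DataFrame(
        GAYASAN_CATEGORY_COUNTS,
        columns=["category", "nt", "nur", "icf_printed"],
    )
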