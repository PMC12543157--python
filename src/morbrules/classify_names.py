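"""Display names for the morbidity groups and subgroups."""

#: Titles of the numbered groups.
GROUP_TITLES = {
    "1": "Abortion",
    "2": "Hypertensive disorders",
    "3": "Obstetric haemorrhages",
    "4": "Infections",
    "5": "Other obstetric complications",
    "7": "Diabetes",
    "8": "Non-obstetric complications",
    "9": "Unknown causes",
    "10": "Childbirth",
    "11": "Other obstetric conditions",
    "12": "External causes",
    "13": "Others",
}

#: Display names of the item labels (group/subgroup level).
ITEM_NAMES = {
    "1a": "Abortion without complications",
    "1b": "Abortion with complications",
    "2a": "Pregnancy-specific hypertension",
    "2b": "Chronic hypertension",
    "3": "Obstetric haemorrhages",
    "4a": "Pregnancy-related infections",
    "4b": "Infections not related to pregnancy",
    "5": "Other obstetric complications",
    "7a": "Gestational diabetes",
    "7b": "Non-gestational diabetes",
    "8a": (
        "Respiratory system diseases complicating pregnancy, childbirth "
        "and the postpartum period"
    ),
    "8b": (
        "Diseases of the digestive system complicating pregnancy, childbirth "
        "and the postpartum period"
    ),
    "8c": (
        "Diseases of the circulatory system complicating pregnancy, childbirth "
        "and the postpartum period"
    ),
    "8d": "Anemia complicating pregnancy, childbirth and the postpartum period",
    "8e": (
        "Other non-obstetric causes complicating pregnancy, childbirth "
        "and the postpartum period"
    ),
    "9": "Unknown causes",
    "10": "Childbirth",
    "11": "Other obstetric conditions",
    "12": "External causes",
    "13": "Others",
}
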