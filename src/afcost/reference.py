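"""Published reference values for the two-arm anticoagulation cost
comparison, used as a validation fixture for the reporting layer.

Means and standard deviations are annual euros per patient over a
12-month follow-up; group sizes are the published arm sizes.  The
component naming matches :data:`afcost.reporting.COST_COMPONENTS`.
"""

REFERENCE_GROUP_SIZES = {"warfarin": 3171, "doac": 829}

REFERENCE_MEANS = {
    "warfarin": {
        "total_healthcare": 805.2,
        "total_patient": 296.7,
        "total_combined": 1102.0,
        "time_travel": 195.6,
        "time_cost": 79.5,
        "travel_cost": 118.2,
        "fees": 74.0,
        "drug_patient": 27.0,
        "inr_monitoring": 519.2,
        "primary_visit": 12.7,
        "specialised_visit": 61.1,
        "primary_ward": 12.2,
        "specialised_ward": 78.6,
        "drug_society": 18.0,
        "society_travel": 99.3,
    },
    "doac": {
        "total_healthcare": 927.3,
        "total_patient": 406.5,
        "total_combined": 1333.8,
        "time_travel": 17.5,
        "time_cost": 3.3,
        "travel_cost": 14.3,
        "fees": 29.2,
        "drug_patient": 359.8,
        "inr_monitoring": 4.3,
        "primary_visit": 16.6,
        "specialised_visit": 100.3,
        "primary_ward": 13.9,
        "specialised_ward": 88.4,
        "drug_society": 668.2,
        "society_travel": 26.5,
    },
}

REFERENCE_SDS = {
    "warfarin": {
        "total_healthcare": 1118.7,
        "total_patient": 256.3,
        "total_combined": 1272.2,
        "time_travel": 221.8,
        "time_cost": 84.4,
        "travel_cost": 168.1,
        "fees": 155.0,
        "drug_patient": 0.0,
        "inr_monitoring": 296.2,
        "primary_visit": 51.7,
        "specialised_visit": 303.9,
        "primary_ward": 130.2,
        "specialised_ward": 706.7,
        "drug_society": 0.0,
        "society_travel": 305.4,
    },
    "doac": {
        "total_healthcare": 1150.9,
        "total_patient": 132.8,
        "total_combined": 1250.8,
        "time_travel": 61.5,
        "time_cost": 11.2,
        "travel_cost": 52.4,
        "fees": 88.0,
        "drug_patient": 10.4,
        "inr_monitoring": 14.1,
        "primary_visit": 47.5,
        "specialised_visit": 608.5,
        "primary_ward": 122.4,
        "specialised_ward": 781.0,
        "drug_society": 19.4,
        "society_travel": 110.8,
    },
}

#: published cost differences (warfarin − DOAC) per component
REFERENCE_DIFFERENCES = {
    "total_healthcare": -122.1,
    "total_patient": -109.8,
    "total_combined": -231.8,
    "time_travel": 178.1,
    "time_cost": 76.2,
    "travel_cost": 103.9,
    "fees": 44.8,
    "drug_patient": -332.8,
    "inr_monitoring": 514.9,
    "primary_visit": -3.9,
    "specialised_visit": -39.2,
    "primary_ward": -1.7,
    "specialised_ward": -9.8,
    "drug_society": -650.2,
    "society_travel": 72.8,
}

#: published percentage shares (component of the arm's relevant total)
REFERENCE_SHARES = {
    "warfarin_inr_of_healthcare": 64.5,
    "doac_drug_of_healthcare": 72.1,
    "doac_drug_of_patient": 88.5,
    "warfarin_time_travel_of_patient": 65.9,
    "doac_time_travel_of_patient": 4.3,
}
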