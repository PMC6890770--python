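"""Fixed categorical vocabularies shared across modules."""

#: Study data-type labels attached to published parameter estimates.
DATA_TYPES = (
    "twin study",
    "family study",
    "family study using EHRs",
    "SNP-based study",
    "PRS-based study",
)

#: Mathematical-model labels attached to published parameter estimates.
MODELS = ("AE", "ACE", "PRS", "SOLAR", "GREML", "LDSC")

#: Biological-system disease categories (20 systems plus "Other").
CATEGORIES = (
    "circulatory",
    "congenital",
    "dermatologic",
    "developmental",
    "endocrine",
    "gastrointestinal",
    "genitourinary",
    "hematologic",
    "hereditary",
    "immune",
    "infectious",
    "mental",
    "metabolic",
    "musculoskeletal",
    "neoplastic",
    "neurologic",
    "nutritional",
    "ophthalmological",
    "otic",
    "respiratory",
    "Other",
)

#: Estimate types supported in estimate tables.
ESTIMATE_TYPES = ("h2", "rg", "re", "rp")

SEXES = ("M", "F")
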