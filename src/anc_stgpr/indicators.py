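"""Registry of the nine antenatal-care indicators.

Five content items (iron supplementation, weight measured, blood pressure
measured, blood sample, urine sample), two composites built from them
(content proportion = all five received; content mean = mean number of the
five items received), and two timing indicators (early initiation = first
visit in the first trimester; mean number of visits).

Each indicator carries:

``kind``
    "proportion" or "mean" — selects the model transform (logit vs log).
``denominator``
    "anc_attendees" for quantities tabulated among women attending at least
    one antenatal-care visit, "all_livebirths" otherwise.  Iron
    supplementation is asked of every respondent with a livebirth, so it is
    tabulated among all of them; the clinic-conditional items and the
    composites are only asked of attendees.
``scale_by_anc1``
    whether the modelled (attendee-conditional) estimate is multiplied by
    ANC1 coverage to express it among all women with a livebirth.  Mean
    visits is tabulated over all women directly (non-attendees contribute
    zero visits), so it is never rescaled; iron is already on the all-women
    scale.
``upper``
    hard upper bound on the natural scale (5 for the content mean), or None.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class IndicatorDef:
    name: str
    kind: str                 # "proportion" | "mean"
    denominator: str          # "anc_attendees" | "all_livebirths"
    scale_by_anc1: bool
    upper: float | None = None

    @property
    def transform(self) -> str:
        return "logit" if self.kind == "proportion" else "log"


CONTENT_ITEMS = (
    "iron_supplementation",
    "weight_measured",
    "bp_measured",
    "blood_sample",
    "urine_sample",
)

# Microdata column used for each content item.
ITEM_COLUMNS = {
    "iron_supplementation": "iron",
    "weight_measured": "weight_measured",
    "bp_measured": "bp_measured",
    "blood_sample": "blood_sample",
    "urine_sample": "urine_sample",
}

INDICATORS: dict[str, IndicatorDef] = {
    "iron_supplementation": IndicatorDef(
        "iron_supplementation", "proportion", "all_livebirths", False),
    "weight_measured": IndicatorDef(
        "weight_measured", "proportion", "anc_attendees", True),
    "bp_measured": IndicatorDef(
        "bp_measured", "proportion", "anc_attendees", True),
    "blood_sample": IndicatorDef(
        "blood_sample", "proportion", "anc_attendees", True),
    "urine_sample": IndicatorDef(
        "urine_sample", "proportion", "anc_attendees", True),
    "content_proportion": IndicatorDef(
        "content_proportion", "proportion", "anc_attendees", True),
    "content_mean": IndicatorDef(
        "content_mean", "mean", "anc_attendees", True, upper=5.0),
    "early_initiation": IndicatorDef(
        "early_initiation", "proportion", "anc_attendees", True),
    "mean_visits": IndicatorDef(
        "mean_visits", "mean", "all_livebirths", False),
}

#: Alternate (abbreviated) composite definitions: name -> items included.
ALTERNATE_DEFINITIONS = {
    "four_item_no_weight": tuple(i for i in CONTENT_ITEMS if i != "weight_measured"),
    "four_item_no_iron": tuple(i for i in CONTENT_ITEMS if i != "iron_supplementation"),
    "four_item_no_bp": tuple(i for i in CONTENT_ITEMS if i != "bp_measured"),
    "four_item_no_blood": tuple(i for i in CONTENT_ITEMS if i != "blood_sample"),
    "four_item_no_urine": tuple(i for i in CONTENT_ITEMS if i != "urine_sample"),
}

#: Indicators whose estimates the composite definitions depend on.
COMPOSITES = ("content_proportion", "content_mean")
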