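"""Canonical outcome ordering and labels shared by every module.

The four WHOQOL-HIV BREF domains modelled jointly, in the fixed order
(physical health, psychological, level of independence, social
relationships).  Random effects are ordered intercept-block first, then
slope-block, both in domain order, so the 8x8 subject-level covariance
reads (u_ph, u_psy, u_ind, u_soc, v_ph, v_psy, v_ind, v_soc).
"""

# short column names used in data frames / CSV files
DOMAINS: tuple[str, ...] = ("ph", "psy", "ind", "soc")

DOMAIN_LABELS: dict[str, str] = {
    "ph": "Physical Health",
    "psy": "Psychological",
    "ind": "Level of Independence",
    "soc": "Social Relationship",
}

#: WHOQOL-HIV BREF item counts for the four in-scope domains (configurable
#: in the simulator; these follow the instrument's published structure).
DEFAULT_ITEMS_PER_DOMAIN: dict[str, int] = {"ph": 4, "psy": 5, "ind": 4, "soc": 4}

SUBJECT_COL = "subject_id"
TIME_COL = "visit_time_months"
COMPLETE_COL = "qol_complete"


def random_effect_labels(outcomes: tuple[str, ...] = DOMAINS) -> list[str]:
    """Labels for the stacked random-effect vector: intercepts then slopes."""
    return [f"intercept_{k}" for k in outcomes] + [f"slope_{k}" for k in outcomes]
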