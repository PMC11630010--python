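"""Published reference values from the 2020 US county multimorbidity analysis.

These are the printed summary tables of the county-level study this package
re-implements (12 chronic conditions, 10 risk factors, 3,143 counties):
node strength / influence of each disease in the multimorbidity network, the
four overlapping MCC communities with their attached risk factors, and the
resulting core / bridge / general role classification. They serve as fixed
inputs for checking the role-classification rule and as a comparison point
for full pipeline runs; they are not recomputed here.
"""

from __future__ import annotations

from .community import Community, CommunityCover
from .importance import NodeImportance

#: disease -> (node strength, node influence) in the disease-disease network
NODE_METRICS: dict[str, tuple[float, float]] = {
    "arthritis": (7.149, 1.1096588),
    "asthma": (5.568, 0.8389998),
    "cancer": (2.742, 0.404974),
    "chd": (7.696, 1.1699424),
    "ckd": (7.414, 1.1769223),
    "copd": (7.179, 1.1250683),
    "depression": (5.043, 0.8000157),
    "diabetes": (7.404, 1.2024869),
    "high_cholesterol": (5.958, 0.9062387),
    "hypertension": (7.47, 1.153484),
    "obesity": (6.357, 0.9511319),
    "stroke": (7.571, 1.1610772),
}

#: the four published MCC patterns: diseases plus their attached risk factors
COMMUNITIES: list[dict] = [
    {
        "diseases": ["hypertension", "cancer", "diabetes", "ckd", "stroke"],
        "factors": ["minority", "sedentary_behavior", "smoking"],
    },
    {
        "diseases": ["arthritis", "asthma", "chd", "copd", "high_cholesterol", "hypertension"],
        "factors": ["impoverishment", "poor_mental_health", "smoking", "lacking_education", "uninsured"],
    },
    {
        "diseases": ["arthritis", "asthma", "obesity"],
        "factors": ["smoking", "poor_mental_health", "binge_drinking", "sedentary_behavior"],
    },
    {
        "diseases": ["depression", "stroke"],
        "factors": ["poor_mental_health", "ageing_population", "sleep_deficiency"],
    },
]

#: published role classification of the 12 diseases
ROLES: dict[str, str] = {
    "chd": "core", "ckd": "core", "diabetes": "core",
    "arthritis": "bridge", "asthma": "bridge", "stroke": "bridge", "hypertension": "bridge",
    "cancer": "general", "depression": "general", "copd": "general",
    "obesity": "general", "high_cholesterol": "general",
}

#: extreme pairwise prevalence correlations reported for the disease network
CORRELATION_EXTREMES = {
    "max": (("ckd", "stroke"), 0.96),
    "min": (("cancer", "diabetes"), -0.57),
}


def reference_metrics() -> list[NodeImportance]:
    """The published table as NodeImportance records (quotient influence)."""
    return [
        NodeImportance(node=d, node_class="disease", strength=s, influence=ni,
                       degree=0, variant="quotient")
        for d, (s, ni) in sorted(NODE_METRICS.items())
    ]


def reference_cover() -> CommunityCover:
    """The published four-community cover over disease and factor nodes."""
    comms = [
        Community(frozenset(c["diseases"]) | frozenset(c["factors"]), 0.0, 0.0, 0.0)
        for c in COMMUNITIES
    ]
    return CommunityCover(comms, alpha=1.0)
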