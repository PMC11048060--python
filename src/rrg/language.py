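"""The synthetic findings-report template language.

The toy corpus writes one sentence per mentioned pathology, instantiated from
a small bank of paraphrase templates.  Each sentence mentions exactly one
observation phrase (the pathology name) and one anatomy phrase, and encodes
the finding status lexically:

* definitely present -- plain assertion ("there is X at the Y.")
* definitely absent  -- negation cued by the token ``no``
* uncertain          -- hedging cued by ``possible`` / ``cannot``

These lexical cues are what the rule-based graph annotator keys on, so the
template bank and the annotator must stay in lockstep; both import this
module.  Pathology names come from the CheXpert label set for vocabulary
realism ("no finding" is excluded: it cannot be phrased without tripping the
negation cue).
"""

from __future__ import annotations

# CheXpert pathology labels usable as observation phrases, each with a fixed,
# distinct anatomy phrase.  Order matters: the default K pathologies are the
# first K entries.
PATHOLOGY_ANATOMY: dict[str, str] = {
    "atelectasis": "left lung base",
    "cardiomegaly": "cardiac silhouette",
    "consolidation": "right lower lobe",
    "edema": "interstitium",
    "pleural effusion": "pleural space",
    "pneumothorax": "lung apex",
    "enlarged cardiomediastinum": "mediastinum",
    "fracture": "posterior ribs",
    "lung lesion": "right upper lobe",
    "lung opacity": "left mid lung",
    "pneumonia": "lingula",
    "pleural other": "pleural surface",
    "support devices": "superior vena cava",
}

PATHOLOGIES: tuple[str, ...] = tuple(PATHOLOGY_ANATOMY)

MENTIONED_STATUSES = ("present", "absent", "uncertain")
STATUSES = MENTIONED_STATUSES + ("unmentioned",)

# >= 2 paraphrase templates per (pathology, status); shared across pathologies.
TEMPLATES: dict[str, tuple[str, ...]] = {
    "present": (
        "there is {obs} at the {anat}.",
        "{obs} is seen at the {anat}.",
    ),
    "absent": (
        "no {obs} at the {anat}.",
        "the {anat} shows no {obs}.",
    ),
    "uncertain": (
        "possible {obs} at the {anat}.",
        "{obs} at the {anat} cannot be excluded.",
    ),
}

TEMPLATE_BANK_VERSION = "toy-templates-1"

# Status -> observation entity label used in the report graphs.
STATUS_TO_OBS_LABEL = {
    "present": "OBS-DP",
    "absent": "OBS-DA",
    "uncertain": "OBS-U",
}

NEGATION_TOKEN = "no"
UNCERTAINTY_TOKENS = ("possible", "cannot")


def default_pathologies(k: int) -> tuple[str, ...]:
    """First ``k`` pathology names of the lexicon."""
    if not 1 <= k <= len(PATHOLOGIES):
        raise ValueError(f"k_pathologies must be in 1..{len(PATHOLOGIES)}, got {k}")
    return PATHOLOGIES[:k]
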