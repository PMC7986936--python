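"""Region and latent-state atlas.

The observation space is 55 regional volumes: 25 bilateral cortical pairs
(50 columns), left/right caudate, left/right putamen, and one global white
matter compartment.  Atrophy is assumed bilaterally symmetric, so each
bilateral pair is driven by a single latent state; caudate and putamen are
likewise one bilateral state each.  That yields 28 latent states
(25 cortical + caudate + putamen + white matter) mapped onto 55 columns.
"""

from __future__ import annotations

# (name, lobe) for the 25 bilateral cortical states
CORTICAL_STATES: list[tuple[str, str]] = [
    ("superior_frontal_gyrus", "frontal"),
    ("middle_frontal_gyrus", "frontal"),
    ("inferior_frontal_gyrus", "frontal"),
    ("orbital_gyrus", "frontal"),
    ("precentral_gyrus", "frontal"),
    ("supplementary_motor_cortex", "frontal"),
    ("postcentral_gyrus", "parietal"),
    ("superior_parietal_lobule", "parietal"),
    ("supramarginal_gyrus", "parietal"),
    ("angular_gyrus", "parietal"),
    ("precuneus", "parietal"),
    ("calcarine_cortex", "occipital"),
    ("cuneus", "occipital"),
    ("lingual_gyrus", "occipital"),
    ("occipital_gyrus", "occipital"),
    ("superior_temporal_gyrus", "temporal"),
    ("middle_temporal_gyrus", "temporal"),
    ("inferior_temporal_gyrus", "temporal"),
    ("fusiform_gyrus", "temporal"),
    ("temporal_pole", "temporal"),
    ("parahippocampal_gyrus", "temporal"),
    ("entorhinal_area", "temporal"),
    ("planum_temporale", "temporal"),
    ("cingulate_gyrus", "limbic"),
    ("insula", "limbic"),
]

SUBCORTICAL_STATES: list[tuple[str, str]] = [
    ("caudate", "striatal"),
    ("putamen", "striatal"),
]

#: ordered latent-state names (28)
STATE_NAMES: list[str] = (
    [name for name, _ in CORTICAL_STATES]
    + [name for name, _ in SUBCORTICAL_STATES]
    + ["white_matter"]
)

#: lobe assignment per state
STATE_LOBES: dict[str, str] = {
    **dict(CORTICAL_STATES),
    **dict(SUBCORTICAL_STATES),
    "white_matter": "white_matter",
}

N_STATES = len(STATE_NAMES)  # 28

#: state index -> observed region column names (bilateral pairs share a state)
STATE_TO_REGIONS: dict[str, list[str]] = {
    **{name: [f"{name}_l", f"{name}_r"] for name, _ in CORTICAL_STATES},
    **{name: [f"{name}_l", f"{name}_r"] for name, _ in SUBCORTICAL_STATES},
    "white_matter": ["white_matter"],
}

#: ordered list of the 55 observed region columns
REGION_COLUMNS: list[str] = [
    col for name in STATE_NAMES for col in STATE_TO_REGIONS[name]
]

N_REGIONS = len(REGION_COLUMNS)  # 55

#: index arrays: for each region column, the driving state index
REGION_STATE_INDEX: list[int] = [
    STATE_NAMES.index(col.rsplit("_l", 1)[0] if col.endswith("_l") else
                      col.rsplit("_r", 1)[0] if col.endswith("_r") else col)
    for col in REGION_COLUMNS
]

CORTICAL_STATE_INDICES = list(range(25))
CAUDATE_STATE = STATE_NAMES.index("caudate")
PUTAMEN_STATE = STATE_NAMES.index("putamen")
WHITE_MATTER_STATE = STATE_NAMES.index("white_matter")
STRIATAL_STATE_INDICES = [CAUDATE_STATE, PUTAMEN_STATE]

BEHAVIOR_CHANNELS = ["tms", "sdmt"]


def states_in_lobe(lobe: str) -> list[int]:
    """Indices of states belonging to a lobe label."""
    return [i for i, name in enumerate(STATE_NAMES) if STATE_LOBES[name] == lobe]


def region_table() -> "list[dict]":
    """Rows (region, state, hemisphere, lobe) for the documented constant table."""
    rows = []
    for col in REGION_COLUMNS:
        if col.endswith("_l") or col.endswith("_r"):
            state = col[:-2]
            hemi = col[-1]
        else:
            state, hemi = col, "bilateral"
        rows.append(
            {"region": col, "state": state, "hemisphere": hemi,
             "lobe": STATE_LOBES[state]}
        )
    return rows
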