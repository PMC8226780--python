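"""Tissue label dictionaries and the 12-to-3 compartment merge map."""

from __future__ import annotations

# 3-shell phantom
SCALP, SKULL, BRAIN = 1, 2, 3
LABELS_3 = {SCALP: "scalp", SKULL: "skull", BRAIN: "brain"}

# 12-tissue head segmentation
SKIN, MUSCLE, FAT, EYES = 1, 2, 3, 4
COMPACT_BONE, SPONGY_BONE = 5, 6
CSF, CORTICAL_GM, CORTICAL_WM = 7, 8, 9
CEREBELLAR_GM, CEREBELLAR_WM, BRAINSTEM = 10, 11, 12

LABELS_12 = {
    SKIN: "skin",
    MUSCLE: "muscle",
    FAT: "fat",
    EYES: "eyes",
    COMPACT_BONE: "compact bone",
    SPONGY_BONE: "spongy bone",
    CSF: "CSF",
    CORTICAL_GM: "cortical grey matter",
    CORTICAL_WM: "cortical white matter",
    CEREBELLAR_GM: "cerebellar grey matter",
    CEREBELLAR_WM: "cerebellar white matter",
    BRAINSTEM: "brainstem",
}

# brain: cortical/cerebellar grey and white matter, brainstem, CSF;
# skull: compact and spongy bone; scalp: skin, muscle, fat, eyes.
MERGE_12_TO_3 = {
    SKIN: SCALP, MUSCLE: SCALP, FAT: SCALP, EYES: SCALP,
    COMPACT_BONE: SKULL, SPONGY_BONE: SKULL,
    CSF: BRAIN, CORTICAL_GM: BRAIN, CORTICAL_WM: BRAIN,
    CEREBELLAR_GM: BRAIN, CEREBELLAR_WM: BRAIN, BRAINSTEM: BRAIN,
}

GREY_MATTER_3 = (BRAIN,)
GREY_MATTER_12 = (CORTICAL_GM, CEREBELLAR_GM)

# Default isotropic conductivities, S/m (configurable; literature-style values)
DEFAULT_CONDUCTIVITY_12 = {
    "skin": 0.43,
    "muscle": 0.1,
    "fat": 0.04,
    "eyes": 1.5,
    "spongy bone": 0.025,
    "compact bone": 0.008,
    "CSF": 1.79,
    "cortical grey matter": 0.33,
    "cortical white matter": 0.14,
    "cerebellar grey matter": 0.33,
    "cerebellar white matter": 0.14,
    "brainstem": 0.33,
}

DEFAULT_CONDUCTIVITY_3 = {"scalp": 0.43, "skull": 0.0063, "brain": 0.33}
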