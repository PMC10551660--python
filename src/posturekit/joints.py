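"""Fixed vocabularies: Azure Kinect joints, anatomical landmarks, marker names.

The body-tracking SDK reports 32 named joints per body in a fixed order;
that order is relied on when parsing ``joint_positions`` arrays. Landmark
names follow the anatomical reference points used for static posture
photography, split by the view (anterior / left-lateral / posterior) in
which they are visible.
"""

from __future__ import annotations

# Azure Kinect body-tracking joint order (index = SDK joint id).
JOINT_NAMES: tuple[str, ...] = (
    "PELVIS",
    "SPINE_NAVEL",
    "SPINE_CHEST",
    "NECK",
    "CLAVICLE_LEFT",
    "SHOULDER_LEFT",
    "ELBOW_LEFT",
    "WRIST_LEFT",
    "HAND_LEFT",
    "HANDTIP_LEFT",
    "THUMB_LEFT",
    "CLAVICLE_RIGHT",
    "SHOULDER_RIGHT",
    "ELBOW_RIGHT",
    "WRIST_RIGHT",
    "HAND_RIGHT",
    "HANDTIP_RIGHT",
    "THUMB_RIGHT",
    "HIP_LEFT",
    "KNEE_LEFT",
    "ANKLE_LEFT",
    "FOOT_LEFT",
    "HIP_RIGHT",
    "KNEE_RIGHT",
    "ANKLE_RIGHT",
    "FOOT_RIGHT",
    "HEAD",
    "NOSE",
    "EYE_LEFT",
    "EAR_LEFT",
    "EYE_RIGHT",
    "EAR_RIGHT",
)

N_JOINTS = len(JOINT_NAMES)

CONFIDENCE_LEVELS: tuple[str, ...] = ("none", "low", "medium", "high")

VIEWS: tuple[str, ...] = ("anterior", "lateral", "posterior")

# Landmark vocabulary per view. Anterior landmarks can be derived from the
# tracked skeleton; lateral earlobe/acromion likewise; the pelvic spines and
# every posterior landmark must come from a landmark table (markers placed on
# the subject and digitised, or manually identified).
ANTERIOR_LANDMARKS: tuple[str, ...] = (
    "LEFT_ACROMION",
    "RIGHT_ACROMION",
    "LEFT_ILIAC_CREST",
    "RIGHT_ILIAC_CREST",
    "LEFT_PATELLA",
    "RIGHT_PATELLA",
    "LEFT_MALLEOLUS",
    "RIGHT_MALLEOLUS",
)

LATERAL_LANDMARKS: tuple[str, ...] = (
    "EARLOBE",
    "ACROMION",
    "ASIS",
    "PSIS",
)

POSTERIOR_LANDMARKS: tuple[str, ...] = (
    "C7",
    "UPPER_T_SPINE",
    "MID_T_SPINE",
    "LOWER_T_SPINE",
    "L1",
    "LEFT_SIA",
    "RIGHT_SIA",
)

LANDMARKS_BY_VIEW: dict[str, tuple[str, ...]] = {
    "anterior": ANTERIOR_LANDMARKS,
    "lateral": LATERAL_LANDMARKS,
    "posterior": POSTERIOR_LANDMARKS,
}

# Skeleton joint backing each automatically derivable landmark, per view.
SKELETON_LANDMARK_SOURCES: dict[str, dict[str, str]] = {
    "anterior": {
        "LEFT_ACROMION": "SHOULDER_LEFT",
        "RIGHT_ACROMION": "SHOULDER_RIGHT",
        "LEFT_ILIAC_CREST": "HIP_LEFT",
        "RIGHT_ILIAC_CREST": "HIP_RIGHT",
        "LEFT_PATELLA": "KNEE_LEFT",
        "RIGHT_PATELLA": "KNEE_RIGHT",
        "LEFT_MALLEOLUS": "ANKLE_LEFT",
        "RIGHT_MALLEOLUS": "ANKLE_RIGHT",
    },
    # Left-lateral photograph: the camera sees the subject's left side.
    "lateral": {
        "EARLOBE": "EAR_LEFT",
        "ACROMION": "SHOULDER_LEFT",
    },
    # Spinal landmarks cannot be located from the tracked skeleton.
    "posterior": {},
}

# Default mapping from a Plug-in-Gait-style 39-marker optical set onto the
# 32 Kinect joints. A joint mapped to several markers takes their centroid.
# This table is data, not algorithm: override it freely via
# skeleton.load_marker_mapping.
DEFAULT_MARKER_MAPPING: dict[str, list[str]] = {
    "PELVIS": ["LASI", "RASI", "LPSI", "RPSI"],
    "SPINE_NAVEL": ["T10", "STRN"],
    "SPINE_CHEST": ["CLAV", "STRN"],
    "NECK": ["C7"],
    "CLAVICLE_LEFT": ["CLAV", "LSHO"],
    "SHOULDER_LEFT": ["LSHO"],
    "ELBOW_LEFT": ["LELB"],
    "WRIST_LEFT": ["LWRA", "LWRB"],
    "HAND_LEFT": ["LFIN"],
    "HANDTIP_LEFT": ["LFIN"],
    "THUMB_LEFT": ["LWRA"],
    "CLAVICLE_RIGHT": ["CLAV", "RSHO"],
    "SHOULDER_RIGHT": ["RSHO"],
    "ELBOW_RIGHT": ["RELB"],
    "WRIST_RIGHT": ["RWRA", "RWRB"],
    "HAND_RIGHT": ["RFIN"],
    "HANDTIP_RIGHT": ["RFIN"],
    "THUMB_RIGHT": ["RWRA"],
    "HIP_LEFT": ["LASI", "LPSI"],
    "KNEE_LEFT": ["LKNE"],
    "ANKLE_LEFT": ["LANK"],
    "FOOT_LEFT": ["LTOE", "LHEE"],
    "HIP_RIGHT": ["RASI", "RPSI"],
    "KNEE_RIGHT": ["RKNE"],
    "ANKLE_RIGHT": ["RANK"],
    "FOOT_RIGHT": ["RTOE", "RHEE"],
    "HEAD": ["LFHD", "RFHD", "LBHD", "RBHD"],
    "NOSE": ["LFHD", "RFHD"],
    "EYE_LEFT": ["LFHD"],
    "EAR_LEFT": ["LBHD"],
    "EYE_RIGHT": ["RFHD"],
    "EAR_RIGHT": ["RBHD"],
}
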