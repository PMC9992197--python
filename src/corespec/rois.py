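"""The 26 bilateral cognitive regions of interest.

Thirteen Desikan-Killiany labels, left and right, spanning the triple
network of neurocognitive core systems: default mode (DMN), central
executive (CEN), and salience (SN) networks.  ROI order is fixed and used
for every exported table.
"""

from __future__ import annotations

#: Base label order (fixed contract for all outputs).
ROI_BASENAMES: tuple[str, ...] = (
    "CAC",   # caudal anterior cingulate cortex
    "CMF",   # caudal middle frontal cortex
    "IPL",   # inferior parietal lobule
    "IC",    # insula cortex
    "MT",    # middle temporal cortex
    "PaH",   # parahippocampal cortex
    "PCC",   # posterior cingulate cortex
    "PCu",   # precuneus
    "RACC",  # rostral anterior cingulate cortex
    "RMF",   # rostral middle frontal cortex
    "SF",    # superior frontal cortex
    "ST",    # superior temporal cortex
    "SM",    # supramarginal cortex
)

HEMISPHERES: tuple[str, str] = ("L", "R")

#: The 26 ROI names in canonical order: CAC.L, CAC.R, CMF.L, ...
ROI_NAMES: tuple[str, ...] = tuple(
    f"{base}.{hemi}" for base in ROI_BASENAMES for hemi in HEMISPHERES
)

#: Rough triple-network membership (documentation / grouping aid only).
NETWORKS: dict[str, tuple[str, ...]] = {
    "DMN": ("PCC", "PCu", "IPL", "MT", "ST", "PaH", "SM"),
    "CEN": ("CMF", "RMF", "SF"),
    "SN": ("CAC", "RACC", "IC"),
}

#: Regions showing high-frequency (beta and above) power decrease in patients.
HIGH_BAND_DECREASE_ROIS: tuple[str, ...] = ("IC", "ST", "MT", "PaH")


def basename(roi: str) -> str:
    """Return the label without hemisphere suffix ('PCC.L' -> 'PCC')."""
    return roi.rsplit(".", 1)[0]


def hemisphere(roi: str) -> str:
    """Return 'L' or 'R' for a canonical ROI name."""
    hemi = roi.rsplit(".", 1)[1]
    if hemi not in HEMISPHERES:
        raise ValueError(f"not a canonical ROI name: {roi!r}")
    return hemi


def mirror(roi: str) -> str:
    """Return the contralateral ROI name ('PCC.L' -> 'PCC.R')."""
    base, hemi = roi.rsplit(".", 1)
    return f"{base}.{'R' if hemi == 'L' else 'L'}"
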