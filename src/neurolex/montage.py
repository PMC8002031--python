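"""64-channel 10/20 montage and the electrode groups used for planted ERP components.

The labels follow the standard 64-electrode actiCAP/EasyCap layout (10/20
extended positions, Cz recorded then average-referenced).
"""

from __future__ import annotations

ACTICAP_64: tuple[str, ...] = (
    "Fp1", "Fz", "F3", "F7", "FT9", "FC5", "FC1", "C3", "T7", "TP9",
    "CP5", "CP1", "Pz", "P3", "P7", "O1", "Oz", "O2", "P4", "P8",
    "TP10", "CP6", "CP2", "Cz", "C4", "T8", "FT10", "FC6", "FC2", "F4",
    "F8", "Fp2", "AF7", "AF3", "AFz", "F1", "F5", "FT7", "FC3", "C1",
    "C5", "TP7", "CP3", "P1", "P5", "PO7", "PO3", "POz", "PO4", "PO8",
    "P6", "P2", "CPz", "CP4", "TP8", "C6", "C2", "FC4", "FT8", "F6",
    "AF8", "AF4", "F2", "Iz",
)

# Electrode groups where the classic lexical-decision ERP components are
# largest: N170 over bilateral occipito-parietal sites, P200 fronto-central,
# N400 (left) frontal, LPC centro-parietal/parietal.
COMPONENT_CHANNELS: dict[str, tuple[str, ...]] = {
    "N170": ("P7", "P8", "PO7", "PO8", "O1", "O2"),
    "P200": ("Fz", "F1", "F2", "FC1", "FC2"),
    "N400": ("F3", "F1", "Fz", "FC3", "FC1"),
    "LPC": ("CP1", "CP2", "CPz", "Pz", "P1", "P2", "P3", "P4"),
}


def validate_channels(channels, montage=ACTICAP_64) -> None:
    """Raise ValueError if any label is not in the montage."""
    unknown = [ch for ch in channels if ch not in montage]
    if unknown:
        raise ValueError(f"unknown channel label(s): {unknown}")
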