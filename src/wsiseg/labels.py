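"""Label conventions shared across the pipeline.

Raw masks follow the Radboud convention used for prostate-biopsy
annotations: 0 = background (glass / unannotated), 1 = stroma,
2 = benign epithelium, and 3/4/5 = Gleason growth patterns 3-5.
For region segmentation the three Gleason patterns are merged into a
single "cancer" class, so the network's target space is
{stroma, benign, cancer}; background pixels carry no tissue label and
are ignored by the loss and the metrics.
"""

from __future__ import annotations

# Raw (Radboud) codes
RAW_BACKGROUND = 0
RAW_STROMA = 1
RAW_BENIGN = 2
RAW_GLEASON_3 = 3
RAW_GLEASON_4 = 4
RAW_GLEASON_5 = 5
RAW_LABELS = (0, 1, 2, 3, 4, 5)

# Merged training/evaluation codes
STROMA = 0
BENIGN = 1
CANCER = 2
N_CLASSES = 3
CLASS_NAMES = ("stroma", "benign", "cancer")

#: Sentinel used in merged label maps for pixels that carry no tissue
#: label (raw background, or slide areas no tile covered).
IGNORE = 255

#: Raw -> merged lookup. Raw background maps to IGNORE.
MERGE_TABLE = {
    RAW_BACKGROUND: IGNORE,
    RAW_STROMA: STROMA,
    RAW_BENIGN: BENIGN,
    RAW_GLEASON_3: CANCER,
    RAW_GLEASON_4: CANCER,
    RAW_GLEASON_5: CANCER,
}
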