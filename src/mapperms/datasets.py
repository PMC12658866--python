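"""Bundled reference summaries from a published 34-sample botrytized-wine study.

The raw chromatograms behind these numbers are not publicly deposited, but
the published per-sample summary counts and the consistency-score row are
useful as self-contained inputs: the counts exercise the pooling
conservation law (their sum is the study's total unique-marker count) and
the consistency row exercises the optimal-cluster-count selection rule.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["wine_marker_counts", "wine_consistency_scores"]

# per-sample counts: sample code, |rMS| representatives, |ruMS| unique markers
_WINE_COUNTS = [
    ("AU1", 964, 65), ("AU2", 1757, 620), ("AU3", 828, 105), ("AU4", 613, 14),
    ("AU5", 743, 13), ("AU6", 682, 7), ("AU7", 1087, 19), ("AU8", 1081, 34),
    ("FR1", 981, 10), ("FR2", 928, 19), ("FR3", 715, 1), ("FR4", 1419, 142),
    ("FR5", 1308, 170), ("FR6", 1149, 101), ("FR7", 1040, 22), ("FR8", 836, 10),
    ("HU1", 977, 29), ("HU2", 1417, 125), ("HU3", 1272, 133), ("HU4", 1205, 61),
    ("HU5", 1252, 42), ("HU6", 1339, 78), ("SK1", 1144, 34), ("SK2", 1151, 73),
    ("SK3", 1075, 30), ("SK4", 1100, 64), ("SK5", 840, 9), ("SK6", 998, 11),
    ("SK7", 1168, 62), ("SK8", 1375, 219), ("SK9", 1300, 291), ("SK10", 1256, 61),
    ("SK11", 1331, 82), ("SK12", 978, 36),
]

# consistency scores P(Q) over the scanned cluster counts Q = 2..15
_WINE_PQ = {
    2: 34, 3: 795, 4: 871, 5: 924, 6: 971, 7: 980, 8: 981, 9: 976,
    10: 986, 11: 993, 12: 991, 13: 970, 14: 928, 15: 755,
}


def wine_marker_counts() -> pd.DataFrame:
    """Per-sample representative (rMS) and unique (ruMS) vector counts.

    Columns: ``sample_id``, ``n_rms``, ``n_rums``; 34 rows.
    """
    return pd.DataFrame(_WINE_COUNTS, columns=["sample_id", "n_rms", "n_rums"])


def wine_consistency_scores() -> dict[int, int]:
    """Published consistency scores P(Q), Q = 2..15, from S = 1000 views."""
    return dict(_WINE_PQ)
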