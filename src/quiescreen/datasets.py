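"""Bundled reference data: published screen-hit potencies.

``hit_ec50_tg1()`` returns the published EC50 values (uM) of the 20
confirmed screen hits on proliferating (P) and quiescent (Q) TG1
glioblastoma stem-like cells, as printed (rounded) in the source study's
potency table, together with the published selectivity group.  Censored
potencies are the bound string "> 100" (highest tested concentration
100 uM).  These printed values feed the worked classification example; note
that ratios recomputed from rounded values can land in the two-fold boundary
band even when the original (unrounded) classification did not.
"""

from __future__ import annotations

import pandas as pd

_HITS = [
    # compound_id, ec50 P TG1, ec50 Q TG1, published group
    ("amiodarone", 10.0, 10.0, "group1"),
    ("prenylamine", 22.0, 27.0, "group1"),
    ("suloctidil", 11.0, 13.0, "group1"),
    ("felodipine", 38.0, 30.0, "group1"),
    ("fendiline", 22.0, 32.0, "group1"),
    ("perhexiline", 10.0, 14.0, "group1"),
    ("lynestrenol", 36.0, 43.0, "group1"),
    ("ellipticine", 13.0, 19.0, "group1"),
    ("tamoxifen", 14.0, 20.0, "group1"),
    ("sertraline", 19.0, 39.0, "group1"),
    ("ivermectin", 3.0, 4.0, "group1"),
    ("beta-escin", 17.0, 12.0, "group1"),
    ("zuclopenthixol", 20.0, 52.0, "group2"),
    ("astemizole", 12.0, 28.0, "group2"),
    ("terfenadine", 8.0, 17.0, "group2"),
    ("parthenolide", 15.0, 48.0, "group2"),
    ("bisacodyl", "> 100", 1.07, "group3"),
    ("ethacrynic acid", 81.0, 41.0, "group3"),
    ("luteolin", "> 100", 20.0, "group3"),
    ("progesterone", "> 100", 25.0, "group3"),
]

#: published EC50 (uM) of bisacodyl on quiescent TG1 cells
BISACODYL_EC50_Q_TG1_UM = 1.07
#: published EC50 (uM) of the mono-hydroxy DDPM analogue ("compound 7")
COMPOUND7_EC50_Q_TG1_UM = 17.1
#: published parent half-lives (hours) of bisacodyl hydrolysis
BISACODYL_HALF_LIFE_H = {"proliferating_medium": 4.0, "quiescent_conditioned_medium": 2.0}
#: maximum tested concentration (uM) behind the "> 100" censoring convention
MAX_TESTED_UM = 100.0


def hit_ec50_tg1() -> pd.DataFrame:
    """The 20 confirmed hits with published P/Q TG1 potencies and groups."""
    return pd.DataFrame(
        _HITS, columns=["compound_id", "ec50_p", "ec50_q", "published_group"]
    )
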