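"""Optional cross-checks against the study's published per-participant tables.

The open-access supplementary archive ships CSV tables with per-participant
outcome values; this module loads the per-subject pre/post response-rate
table so published cohort statistics can be reproduced end to end.  The
table is not redistributed here — download the supplementary archive and
drop ``ResponseRatesBySubject.csv`` into ``data/supplementary/``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

#: Repo-relative location where the supplementary table is expected.
RESPONSE_RATES_PATH = Path("data") / "supplementary" / "ResponseRatesBySubject.csv"


def load_response_rates_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load per-participant (pre, post) cue rates, in percent.

    Column names are matched case-insensitively on the substrings "pre" and
    "post" so minor naming differences in the released table do not matter.
    Values on a 0-1 scale are rescaled to percent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found: download the study's supplementary data archive "
            "and place ResponseRatesBySubject.csv there"
        )
    df = pd.read_csv(path)
    pre_col = next((c for c in df.columns if "pre" in c.lower()), None)
    post_col = next((c for c in df.columns if "post" in c.lower()), None)
    if pre_col is None or post_col is None:
        raise ValueError(f"{path}: could not identify pre/post rate columns in {list(df.columns)}")
    pre = pd.to_numeric(df[pre_col], errors="coerce").dropna().to_numpy(dtype=float)
    post = pd.to_numeric(df[post_col], errors="coerce").dropna().to_numpy(dtype=float)
    if len(pre) != len(post) or len(pre) == 0:
        raise ValueError(f"{path}: pre/post columns misaligned or empty")
    if np.nanmax(np.concatenate([pre, post])) <= 1.0:
        pre, post = pre * 100.0, post * 100.0
    return pre, post
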