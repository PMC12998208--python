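"""Model-matrix construction: fixed categorical codings shared by every
model in the battery, so estimates are comparable across strata and runs."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["CATEGORICAL_LEVELS", "build_design"]

# reference level first; dummies drop it
CATEGORICAL_LEVELS = {
    "sex": ["male", "female"],
    "ethnicity": ["white", "other"],
    "education": ["post_secondary", "high_school_or_less", "secondary"],
    "marital": ["married_common_law", "widowed_sep_div", "single"],
    "smoking": ["never", "ever"],
    "country_of_birth": ["canada", "foreign"],
    "survey_cycle": [2, 5, 6],
    "parity": ["0", "1", "2", "3+"],
}


def build_design(
    data: pd.DataFrame, terms: list[str], add_intercept: bool = True
) -> pd.DataFrame:
    """Expand ``terms`` into a numeric model matrix.

    Categorical terms (per CATEGORICAL_LEVELS) become treatment dummies
    against the first listed level; unseen categories raise.  Continuous
    terms pass through as float.
    """
    cols: dict[str, np.ndarray] = {}
    if add_intercept:
        cols["(Intercept)"] = np.ones(len(data))
    for t in terms:
        if t not in data.columns:
            raise KeyError(f"term {t!r} missing from data")
        if t in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[t]
            vals = data[t]
            if t == "survey_cycle":
                vals = vals.astype(int)
            else:
                vals = vals.astype(str)
            unseen = set(vals.unique()) - set(levels)
            if unseen:
                raise ValueError(f"unknown levels {sorted(map(str, unseen))} in {t!r}")
            for lev in levels[1:]:
                cols[f"{t}[{lev}]"] = (vals == lev).to_numpy(dtype=float)
        else:
            cols[t] = data[t].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=data.index)
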