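"""Cohort logic: response classification, vitamin D status bins, summaries.

Serum 25-hydroxyvitamin D (25(OH)D, ng/mL) is the circulating biomarker of
vitamin D status.  Participants are classified after supplementation as
responders (R) when their level reaches the 20 ng/mL threshold and
non-responders (NR) otherwise.  Status bins follow the deficient (≤ 20) /
sufficient (21–30) / above-sufficient (> 30) convention; note the two rules
meet differently at exactly 20: status calls it deficient while response
calls it R (the boundary belongs to the responders).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RESPONSE_THRESHOLD = 20.0  # ng/mL

BMI_BINS = {"underweight": (0.0, 18.5), "normal": (18.5, 25.0),
            "overweight/obese": (25.0, np.inf)}


def classify_response(post_level: float,
                      threshold: float = RESPONSE_THRESHOLD) -> str:
    """R if the post-supplementation level reaches ``threshold``, else NR."""
    if not post_level > 0:
        raise ValueError(f"25(OH)D level must be positive, got {post_level}")
    return "R" if post_level >= threshold else "NR"


def status_bin(level: float) -> str:
    """Vitamin D status: deficient ≤ 20 < sufficient ≤ 30 < above-sufficient."""
    if not level > 0:
        raise ValueError(f"25(OH)D level must be positive, got {level}")
    if level <= 20.0:
        return "deficient"
    if level <= 30.0:
        return "sufficient"
    return "above-sufficient"


def bmi_category(bmi: float) -> str:
    for name, (lo, hi) in BMI_BINS.items():
        if lo <= bmi < hi:
            return name
    raise ValueError(f"BMI out of range: {bmi}")


def level_histogram(levels, bin_width: float = 2.0) -> pd.DataFrame:
    """Histogram of 25(OH)D levels with bins centered on multiples of the
    width (a level of 20 falls in the bin centered at 20, i.e. (19, 21])."""
    levels = np.asarray(levels, dtype=float)
    centers = bin_width * np.round(levels / bin_width)
    counts = pd.Series(centers).value_counts().sort_index()
    return pd.DataFrame({"bin_center": counts.index.to_numpy(),
                         "count": counts.to_numpy()})


def summarize_cohort(table: pd.DataFrame, bin_width: float = 2.0) -> dict:
    """Counts, means, ranges and histograms describing a cohort table.

    Expects columns ``pre_25OHD``, ``post_25OHD`` and optionally ``age``,
    ``bmi``, ``sun_exposure``, ``response``.  If ``response`` is absent it is
    derived from the post levels.
    """
    if table.empty:
        raise ValueError("empty cohort table")
    out: dict = {"n": len(table)}
    for col in ("pre_25OHD", "post_25OHD", "age", "bmi"):
        if col in table:
            vals = table[col].astype(float)
            out[col] = {"mean": float(vals.mean()),
                        "min": float(vals.min()),
                        "max": float(vals.max())}
    response = (table["response"] if "response" in table
                else table["post_25OHD"].map(classify_response))
    out["response_counts"] = response.value_counts().to_dict()
    if "bmi" in table:
        cats = table["bmi"].map(bmi_category)
        out["bmi_counts"] = {k: int((cats == k).sum()) for k in BMI_BINS}
    if "sun_exposure" in table:
        out["sun_exposure_counts"] = table["sun_exposure"].value_counts().to_dict()
    out["status_pre_counts"] = (
        table["pre_25OHD"].map(status_bin).value_counts().to_dict())
    out["status_post_counts"] = (
        table["post_25OHD"].map(status_bin).value_counts().to_dict())
    out["hist_pre"] = level_histogram(table["pre_25OHD"], bin_width)
    out["hist_post"] = level_histogram(table["post_25OHD"], bin_width)
    return out


def summary_frame(summary: dict) -> pd.DataFrame:
    """Flatten a cohort summary into a two-column key/value table."""
    rows = []
    for key, val in summary.items():
        if isinstance(val, pd.DataFrame):
            for r in val.itertuples(index=False):
                rows.append({"key": f"{key}[{r.bin_center:g}]",
                             "value": r.count})
        elif isinstance(val, dict):
            for k, v in val.items():
                rows.append({"key": f"{key}.{k}", "value": v})
        else:
            rows.append({"key": key, "value": val})
    return pd.DataFrame(rows)
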