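"""Regional group statistics for cohorts of quantified subjects.

Works on a long-format regional table with one row per
subject x region x measure, where measure is one of BP_ND, R1, sCBF, SUVR.
Provides healthy-control-normalised deviation profiles (how far each
subject's regional value lies from the control mean, in control SD units)
and per-region two-group significance by Student's t-test, plus the
reciprocal-P panel used to compare the discriminating power of the
measures across regions and diagnostic groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSignalError, WarmPetError

__all__ = [
    "MEASURES",
    "regional_table",
    "hc_normalized_deviation",
    "group_ttest",
    "significance_panel",
]

MEASURES = ("BP_ND", "R1", "sCBF", "SUVR")

_REQUIRED_COLUMNS = {"subject_id", "group", "region", "measure", "value"}


def _check_table(table: pd.DataFrame) -> None:
    missing = _REQUIRED_COLUMNS - set(table.columns)
    if missing:
        raise WarmPetError(f"regional table lacks columns {sorted(missing)}")
    dup = table.duplicated(subset=["subject_id", "region", "measure"])
    if dup.any():
        raise WarmPetError("regional table has duplicate subject x region x measure rows")


def regional_table(results: dict, suvr_values: dict | None = None) -> pd.DataFrame:
    """Assemble a long-format regional table from per-subject results.

    ``results[(group, subject_id)][region]`` is a
    :class:`~warmpet.quantify.WarmResult`; ``suvr_values`` optionally maps
    the same keys to SUVR floats per region.
    """
    rows = []
    for (group, subject_id), regions in results.items():
        for region, res in regions.items():
            rows.append({"subject_id": subject_id, "group": group,
                         "region": region, "measure": "BP_ND", "value": res.bpnd})
            rows.append({"subject_id": subject_id, "group": group,
                         "region": region, "measure": "R1", "value": res.r1})
            rows.append({"subject_id": subject_id, "group": group,
                         "region": region, "measure": "sCBF", "value": res.scbf})
            if suvr_values is not None:
                rows.append({"subject_id": subject_id, "group": group,
                             "region": region, "measure": "SUVR",
                             "value": suvr_values[(group, subject_id)][region]})
    table = pd.DataFrame(rows)
    _check_table(table)
    return table


def hc_normalized_deviation(table: pd.DataFrame, hc_group: str = "HC") -> pd.DataFrame:
    """Deviation of every subject's regional value from the healthy-control
    mean, in units of the healthy-control SD (sample SD, n-1 denominator).

    Healthy-control subjects are normalised against their own group, so
    their z-scores have sample mean 0 and SD 1 per region x measure.
    """
    _check_table(table)
    hc = table[table["group"] == hc_group]
    if hc.empty:
        raise WarmPetError(f"no subjects in normalisation group {hc_group!r}")
    stats_hc = hc.groupby(["region", "measure"])["value"].agg(["mean", "std", "count"])
    out = table.merge(stats_hc, left_on=["region", "measure"], right_index=True,
                      how="left")
    bad = out["count"].isna() | (out["count"] < 2)
    if bad.any():
        rows = out.loc[bad, ["region", "measure"]].drop_duplicates()
        raise WarmPetError(
            f"normalisation group {hc_group!r} has fewer than 2 subjects for "
            f"{rows.to_dict('records')}"
        )
    degenerate = out["std"] <= 0
    if degenerate.any():
        row = out.loc[degenerate].iloc[0]
        raise DegenerateSignalError(
            f"zero spread in {hc_group!r} for region {row['region']!r}, "
            f"measure {row['measure']!r}: z-scores undefined"
        )
    out["z"] = (out["value"] - out["mean"]) / out["std"]
    return out[["subject_id", "group", "region", "measure", "value", "z"]]


def group_ttest(table: pd.DataFrame, group_a: str, group_b: str,
                region: str, measure: str, welch: bool = False
                ) -> tuple[float, float]:
    """Two-sample Student t-test (two-sided) between two groups for one
    region and measure. Equal-variance (pooled) by default; ``welch=True``
    switches to the unequal-variance variant."""
    _check_table(table)
    sel = (table["region"] == region) & (table["measure"] == measure)
    a = table.loc[sel & (table["group"] == group_a), "value"].to_numpy()
    b = table.loc[sel & (table["group"] == group_b), "value"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise WarmPetError(
            f"t-test needs >= 2 subjects per group for {region}/{measure}: "
            f"{group_a} has {len(a)}, {group_b} has {len(b)}"
        )
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def significance_panel(table: pd.DataFrame, hc_group: str = "HC",
                       reference_region: str = "CERB",
                       welch: bool = False) -> pd.DataFrame:
    """Reciprocal-P panel: 1/p of each patient group versus healthy
    controls, for every region x measure.

    Large values flag measures/regions that separate a diagnostic group
    from controls. The reference region's rows are flagged
    (``is_reference``) since no specific binding — hence no BP_ND group
    difference — is expected there.
    """
    _check_table(table)
    groups = [g for g in table["group"].unique() if g != hc_group]
    rows = []
    for group in groups:
        for region in table["region"].unique():
            for measure in table["measure"].unique():
                t, p = group_ttest(table, group, hc_group, region, measure,
                                   welch=welch)
                rows.append({"group": group, "region": region,
                             "measure": measure, "t": t, "p": p,
                             "inverse_p": np.inf if p == 0 else 1.0 / p,
                             "is_reference": region == reference_region})
    return pd.DataFrame(rows)
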