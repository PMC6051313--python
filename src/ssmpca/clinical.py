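"""Clinical statistics layer: group comparisons and score-clinical correlations.

The test mapping follows standard practice for this kind of cohort:
parametric tests (t-test, Pearson) for approximately normal demographics,
non-parametric tests (Mann-Whitney U, Spearman) for ordinal or skewed
clinical scales.  Correlations of expression z-scores with clinical
variables are Bonferroni-guarded at alpha = 0.005 (= 0.05/10) by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import NEUROPSYCH_COLUMNS, SARA_ITEMS

__all__ = [
    "correlate_clinical",
    "compare_groups",
    "DEFAULT_ALPHA_CLINICAL",
    "PEARSON_VARIABLES",
    "SPEARMAN_VARIABLES",
]

DEFAULT_ALPHA_CLINICAL = 0.005  # 0.05 Bonferroni-divided by 10 planned tests

#: approximately normal demographics correlate via Pearson's r
PEARSON_VARIABLES = ("age", "age_at_onset", "disease_duration")

#: ordinal / non-normal scales correlate via Spearman's rho
SPEARMAN_VARIABLES = (
    "sara_total",
    *(f"sara_{item}" for item in SARA_ITEMS),
    "cag_repeats",
    "education",
    "hads_anxiety",
    "hads_depression",
    *NEUROPSYCH_COLUMNS,
)

#: group-comparison test mapping
_GROUP_TEST_TTEST = ("age",)
_GROUP_TEST_CHI2 = ("sex",)


def _pairwise(x: pd.Series, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = x.notna().to_numpy() & np.isfinite(y)
    return x.to_numpy(dtype=float)[ok], y[ok]


def correlate_clinical(
    z_scores,
    clinical: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA_CLINICAL,
    variables: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Correlate expression z-scores with clinical variables.

    ``variables`` maps column name -> method ("pearson"/"spearman"); the
    default covers demographics (Pearson) and all ordinal scales
    (Spearman).  Rows with a missing value in either member of a pair are
    dropped pairwise; variables with fewer than 3 complete pairs are
    reported as skipped.  Returns a tidy frame with one row per variable.
    """
    z = np.asarray(z_scores, dtype=float)
    if len(z) != len(clinical):
        raise ValueError("z_scores and clinical table must align row-wise")
    if variables is None:
        variables = {v: "pearson" for v in PEARSON_VARIABLES if v in clinical}
        variables.update({v: "spearman" for v in SPEARMAN_VARIABLES if v in clinical})
    rows = []
    for var, method in variables.items():
        x, zz = _pairwise(clinical[var], z)
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(zz) == 0:
            rows.append({"variable": var, "method": method, "n": len(x),
                         "coefficient": np.nan, "p": np.nan,
                         "significant": False, "skipped": True})
            continue
        if method == "pearson":
            r, p = stats.pearsonr(x, zz)
        elif method == "spearman":
            r, p = stats.spearmanr(x, zz)
        else:
            raise ValueError(f"unknown method {method!r} for {var!r}")
        rows.append({"variable": var, "method": method, "n": len(x),
                     "coefficient": float(r), "p": float(p),
                     "significant": bool(p < alpha), "skipped": False})
    return pd.DataFrame(rows)


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U with exact p for small tie-free samples.

    Exact enumeration applies when the combined sample size is <= 20 and
    there are no ties; otherwise the normal approximation with continuity
    correction and midrank tie handling is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    has_ties = len(np.unique(np.r_[x, y])) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_groups(clinical: pd.DataFrame) -> pd.DataFrame:
    """Patient-vs-control comparison of every clinical variable.

    t-test for age, chi-square (2x2, uncorrected) for sex, Mann-Whitney U
    for the remaining variables.  Variables constant overall or present in
    only one group are skipped with a reason.
    """
    if "group" not in clinical:
        raise ValueError("clinical table needs a 'group' column")
    grp = clinical["group"].to_numpy()
    if not (np.any(grp == "patient") and np.any(grp == "control")):
        raise ValueError("both groups must be present")
    rows = []
    skip_cols = {"subject_id", "group", "label"}
    for var in clinical.columns:
        if var in skip_cols:
            continue
        if var in _GROUP_TEST_CHI2:
            tab = pd.crosstab(clinical["group"], clinical[var])
            if tab.shape != (2, 2):
                rows.append(_skip(var, "chi2", "not a 2x2 table"))
                continue
            chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
            rows.append({"variable": var, "test": "chi2", "statistic": float(chi2),
                         "p": float(p), "skipped": False, "reason": ""})
            continue
        x, _ = _pairwise(clinical.loc[grp == "patient", var], np.zeros(np.count_nonzero(grp == "patient")))
        y, _ = _pairwise(clinical.loc[grp == "control", var], np.zeros(np.count_nonzero(grp == "control")))
        test = "t" if var in _GROUP_TEST_TTEST else "mannwhitney"
        if len(x) < 2 or len(y) < 2:
            rows.append(_skip(var, test, "fewer than 2 values in a group"))
            continue
        if np.ptp(np.r_[x, y]) == 0:
            rows.append(_skip(var, test, "constant variable"))
            continue
        if test == "t":
            t, p = stats.ttest_ind(x, y, equal_var=True)
            rows.append({"variable": var, "test": "t", "statistic": float(t),
                         "p": float(p), "skipped": False, "reason": ""})
        else:
            u, p = mann_whitney(x, y)
            rows.append({"variable": var, "test": "mannwhitney", "statistic": u,
                         "p": p, "skipped": False, "reason": ""})
    return pd.DataFrame(rows)


def _skip(var: str, test: str, reason: str) -> dict:
    return {"variable": var, "test": test, "statistic": np.nan, "p": np.nan,
            "skipped": True, "reason": reason}
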