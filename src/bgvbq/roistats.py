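"""Subregion-level statistics on extracted seed values.

For each parameter (MT %, R1 s^-1, R2* s^-1) the three seed subregions are
compared with a one-way repeated-measures ANOVA (subject as blocking
factor, F on (2, 2(n-1)) degrees of freedom) followed by the three pairwise
two-tailed paired t-tests (motor vs associative, associative vs limbic,
limbic vs motor), reported at raw p without multiplicity adjustment.
Summary means and SDs use the sample (n-1) convention.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import PARAMETERS

SUBREGIONS = ("motor", "associative", "limbic")
PAIRS = (("motor", "associative"), ("associative", "limbic"),
         ("limbic", "motor"))


def _columns(cohort: pd.DataFrame, parameter: str) -> np.ndarray:
    cols = []
    for s in SUBREGIONS:
        col = f"{s}_{parameter}"
        if col not in cohort.columns:
            raise KeyError(f"cohort table lacks subregion column {col!r}")
        cols.append(cohort[col].to_numpy(dtype=float))
    data = np.column_stack(cols)
    if np.isnan(data).any():
        raise ValueError("missing subregion values")
    return data


def anova_subregions(cohort: pd.DataFrame, parameter: str,
                     method: str = "rm") -> tuple[float, float, bool]:
    """One-way ANOVA across the three subregions. Returns (F, p, degenerate).

    ``rm`` (default) is the repeated-measures form with subject as blocking
    factor; ``independent`` treats subregions as independent groups.
    """
    data = _columns(cohort, parameter)
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if method == "independent":
        f, p = stats.f_oneway(*[data[:, i] for i in range(3)])
        return float(f), float(p), False
    if method != "rm":
        raise ValueError(f"unknown ANOVA method {method!r}")
    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_subj = 3 * ((subj_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df_cond, df_err = 2, 2 * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        if ms_cond == 0:
            return 0.0, 1.0, True
        return float("inf"), 0.0, True
    f = ms_cond / ms_err
    p = float(stats.f.sf(f, df_cond, df_err))
    return float(f), p, False


def paired_tests(cohort: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Two-tailed paired t-tests for the three subregion pairs."""
    data = _columns(cohort, parameter)
    idx = {s: i for i, s in enumerate(SUBREGIONS)}
    rows = []
    n = data.shape[0]
    for a, b in PAIRS:
        d = data[:, idx[a]] - data[:, idx[b]]
        sd = d.std(ddof=1)
        degenerate = sd == 0
        if degenerate:
            if d.mean() == 0:
                t, p = 0.0, 1.0
            else:
                t, p = np.sign(d.mean()) * np.inf, 0.0
        else:
            t = d.mean() * np.sqrt(n) / sd
            p = float(2.0 * stats.t.sf(abs(t), n - 1))
        rows.append({"pair": f"{a} vs {b}", "t": float(t), "p": p,
                     "df": n - 1, "degenerate": bool(degenerate)})
    return pd.DataFrame(rows)


@dataclass
class SubregionSummary:
    """Mean (SD) per subregion and parameter, plus ANOVA and paired tests."""

    summary: pd.DataFrame  # subregion x parameter: mean, sd
    anova: pd.DataFrame  # per parameter: F, p, degenerate
    paired: pd.DataFrame  # per (parameter, pair): t, p
    n_subjects: int

    def to_table(self) -> pd.DataFrame:
        """Wide layout mirroring the published subregion table."""
        rows = []
        for s in ("limbic", "associative", "motor"):
            row = {"subregion": s}
            for p in PARAMETERS:
                sel = self.summary[(self.summary["subregion"] == s)
                                   & (self.summary["parameter"] == p)]
                row[f"{p}_mean"] = float(sel["mean"].iloc[0])
                row[f"{p}_sd"] = float(sel["sd"].iloc[0])
            rows.append(row)
        return pd.DataFrame(rows)


def summarize_table1(cohort: pd.DataFrame) -> SubregionSummary:
    """Mean/SD per (subregion, parameter) with ANOVA and paired tests."""
    n = len(cohort)
    rows = []
    for s in SUBREGIONS:
        for p in PARAMETERS:
            vals = cohort[f"{s}_{p}"].to_numpy(dtype=float)
            rows.append({"subregion": s, "parameter": p,
                         "mean": float(vals.mean()),
                         "sd": float(vals.std(ddof=1)) if n > 1 else np.nan})
    anova_rows, paired_frames = [], []
    if n >= 3:
        for p in PARAMETERS:
            f, pv, degen = anova_subregions(cohort, p)
            anova_rows.append({"parameter": p, "F": f, "p": pv,
                               "degenerate": degen})
            pt = paired_tests(cohort, p)
            pt.insert(0, "parameter", p)
            paired_frames.append(pt)
    return SubregionSummary(
        summary=pd.DataFrame(rows),
        anova=pd.DataFrame(anova_rows),
        paired=(pd.concat(paired_frames, ignore_index=True)
                if paired_frames else pd.DataFrame()),
        n_subjects=n,
    )
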