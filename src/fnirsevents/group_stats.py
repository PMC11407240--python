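"""Group-level statistics.

Channel-wise paired t-tests of Fragranced vs Unfragranced per condition
cell and parameter, Kolmogorov-Smirnov normality screening of the paired
differences, Benjamini-Hochberg FDR correction within each
parameter x contrast family of channels, and Pearson correlations
between the dynamic-phase brain parameters and the questionnaire scores
(wash <-> liquid, dry_hang <-> wet, fold <-> dry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import QUESTIONNAIRE_ATTRIBUTES
from .summary_metrics import NORM_PARAMETERS, PARAMETERS

# the six contrasts: (phase, task), each Fragranced vs Unfragranced
CONTRASTS = (("dynamic", "wash"), ("dynamic", "dry_hang"), ("dynamic", "fold"),
             ("static", "liquid"), ("static", "wet"), ("static", "dry"))

# dynamic stage <-> static questionnaire form pairing
STAGE_FORM_MAP = {"wash": "liquid", "dry_hang": "wet", "fold": "dry"}


@dataclass
class PairedTestResult:
    channel: int
    parameter: str
    phase: str
    task: str
    n_pairs: int
    t: float
    df: int
    p: float
    significant_unc: bool
    significant_fdr: bool
    ks_normal: bool
    degenerate: bool


def ks_normality(values: np.ndarray, alpha: float = 0.05
                 ) -> tuple[float, float, bool]:
    """One-sample KS test against a normal law with sample-estimated mean
    and sd. Returns (statistic, p, normal flag at ``alpha``); a
    zero-variance sample is flagged not normal (degenerate)."""
    v = np.asarray(values, float)
    if len(v) < 4:
        raise ValueError("need at least 4 values for the normality screen")
    sd = v.std(ddof=1)
    if sd == 0:
        return float("nan"), float("nan"), False
    stat, p = stats.kstest(v, "norm", args=(v.mean(), sd))
    return float(stat), float(p), bool(p >= alpha)


def paired_t(values_f: np.ndarray, values_u: np.ndarray
             ) -> tuple[float, int, float]:
    """Paired t-test: t = mean(d) / (sd(d)/sqrt(n)), d = f - u, two-sided p
    on n - 1 degrees of freedom. Returns (t, df, p); t is NaN when sd(d)
    is zero (degenerate)."""
    f = np.asarray(values_f, float)
    u = np.asarray(values_u, float)
    if f.shape != u.shape or f.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-d arrays")
    n = len(f)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = f - u
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        return float("nan"), df, float("nan")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level ``q``."""
    p = np.asarray(p_values, float)
    if len(p) == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def paired_tests(param_table: pd.DataFrame, alpha: float = 0.05,
                 q: float = 0.05) -> pd.DataFrame:
    """All channel-wise Fragranced vs Unfragranced comparisons.

    One row per contrast x parameter x channel with >= 2 complete pairs;
    FDR families are the channels within one parameter x contrast.
    """
    rows: list[PairedTestResult] = []
    for phase, task in CONTRASTS:
        sub = param_table[(param_table["phase"] == phase)
                          & (param_table["task"] == task)]
        for parameter in (*PARAMETERS, *NORM_PARAMETERS):
            family: list[PairedTestResult] = []
            for channel in sorted(sub["channel"].unique()):
                cs = sub[sub["channel"] == channel]
                f = cs[cs["condition"] == "fragranced"].set_index("participant")
                u = cs[cs["condition"] == "unfragranced"].set_index("participant")
                common = f.index.intersection(u.index)
                if len(common) < 2:
                    continue
                fv = f.loc[common, parameter].to_numpy(float)
                uv = u.loc[common, parameter].to_numpy(float)
                t, df, p = paired_t(fv, uv)
                degenerate = not np.isfinite(t)
                if len(common) >= 4 and not degenerate:
                    _s, _p, normal = ks_normality(fv - uv)
                else:
                    normal = False
                family.append(PairedTestResult(
                    channel=int(channel), parameter=parameter, phase=phase,
                    task=task, n_pairs=int(len(common)), t=t, df=df, p=p,
                    significant_unc=bool(np.isfinite(p) and p < alpha),
                    significant_fdr=False, ks_normal=normal,
                    degenerate=degenerate))
            ps = [r.p for r in family if np.isfinite(r.p)]
            if ps:
                flags = fdr_bh(ps, q)
                it = iter(flags)
                for r in family:
                    if np.isfinite(r.p):
                        r.significant_fdr = bool(next(it))
            rows.extend(family)
    return pd.DataFrame([r.__dict__ for r in rows])


def correlate_brain_behaviour(param_table: pd.DataFrame,
                              scores: pd.DataFrame,
                              pool_conditions: bool = True) -> pd.DataFrame:
    """Pearson correlations between dynamic-stage parameters and the
    questionnaire scores of the paired static form.

    With ``pool_conditions`` each participant contributes up to two
    points (one per detergent condition); otherwise separate rows are
    produced per condition. Pairs need n >= 3 and non-zero variance on
    both sides.
    """
    rows = []
    condition_groups = ([None] if pool_conditions
                        else ["fragranced", "unfragranced"])
    for task, form in STAGE_FORM_MAP.items():
        brain = param_table[(param_table["phase"] == "dynamic")
                            & (param_table["task"] == task)]
        for cond in condition_groups:
            b = brain if cond is None else brain[brain["condition"] == cond]
            s = scores[scores["form"] == form]
            s = s if cond is None else s[s["condition"] == cond]
            merged = b.merge(s, on=["participant", "condition"], how="inner")
            for channel in sorted(merged["channel"].unique()):
                cm = merged[merged["channel"] == channel]
                for parameter in PARAMETERS:
                    for attribute in QUESTIONNAIRE_ATTRIBUTES:
                        pair = cm[[parameter, attribute]].dropna()
                        if len(pair) < 3:
                            continue
                        x = pair[parameter].to_numpy(float)
                        yv = pair[attribute].to_numpy(float)
                        if x.std() == 0 or yv.std() == 0:
                            continue
                        r, p = stats.pearsonr(x, yv)
                        rows.append({
                            "channel": int(channel), "parameter": parameter,
                            "attribute": attribute, "task": task,
                            "form": form,
                            "condition": cond if cond else "pooled",
                            "n": int(len(pair)),
                            "r": float(r), "p": float(p),
                        })
    return pd.DataFrame(rows)
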