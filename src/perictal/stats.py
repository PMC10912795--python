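"""Group-comparison statistics for per-seizure LFP metrics.

The experimental design has four groups (control, DBS, Pilo, Pilo+DBS)
and one value per seizure (or per time-matched sample) for each metric:
band power, band coherence, or band MI.  The analysis chain is the
classical one — Kolmogorov–Smirnov normality check, one-way ANOVA, then
Tukey's HSD post-hoc for all pairwise contrasts.

Per-seizure values are treated as independent samples.  With multiple
seizures per animal this is pseudo-replication; that caveat is inherent
to the design being mirrored and is documented, not corrected, here.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.diagnostic import lilliefors

from .errors import InsufficientDataError, ValidationError

GROUPS = ("control", "DBS", "Pilo", "Pilo+DBS")


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(out) < 2:
        raise ValidationError("need >= 2 groups")
    for k, v in out.items():
        if v.size < 2:
            raise ValidationError(f"group {k!r} has {v.size} values; need >= 2")
    return out


def ks_normality(values: Sequence[float]) -> dict:
    """KS test of normality with mean and SD estimated from the sample.

    Uses the Lilliefors correction for the estimated parameters (the
    plain KS null distribution is wrong when mean/SD come from the same
    data); p-values follow the standard table/approximation scheme.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientDataError(f"normality test needs n >= 3, got {x.size}")
    if np.std(x) == 0:
        raise ValidationError("zero-variance sample — normality test undefined")
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    return {"statistic": float(stat), "p": float(p), "n": int(x.size)}


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> dict:
    """Classical one-way ANOVA: F = MS_between / MS_within.

    Returns F, the degrees of freedom (k−1, N−k) and the p-value.
    """
    g = _as_groups(groups)
    arrays = list(g.values())
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    f, p = scipy.stats.f_oneway(*arrays)
    return {
        "F": float(f),
        "df_between": k - 1,
        "df_within": n_total - k,
        "p": float(p),
    }


def tukey_hsd(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (studentized-range adjusted p).

    One row per unordered pair: mean difference, the studentized-range
    statistic q = |diff| / sqrt(MS_within/2 · (1/n_i + 1/n_j)), and the
    family-wise adjusted p-value.
    """
    g = _as_groups(groups)
    names = list(g)
    arrays = [g[n] for n in names]
    res = scipy.stats.tukey_hsd(*arrays)
    # MS_within for the q statistic
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ms_within = ss_within / (n_total - k)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = arrays[i].mean() - arrays[j].mean()
            se = np.sqrt(
                ms_within / 2.0 * (1.0 / arrays[i].size + 1.0 / arrays[j].size)
            )
            q = abs(diff) / se if se > 0 else 0.0
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": float(diff),
                    "q": float(q),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def compare_groups(metric_values: Mapping[str, Sequence[float]]) -> dict:
    """Full chain for one metric: normality per group, ANOVA, Tukey."""
    g = _as_groups(metric_values)
    normality = {}
    for name, vals in g.items():
        try:
            normality[name] = ks_normality(vals)
        except (ValidationError, InsufficientDataError) as exc:
            normality[name] = {"error": str(exc)}
    return {
        "normality": normality,
        "anova": one_way_anova(g),
        "tukey": tukey_hsd(g),
    }
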