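"""Statistical comparison layer for subgroup metric distributions.

Per-metric distributions of the AA/AO/OO maximum pairs are summarized
(n, mean, median) and compared with the two-sample Kolmogorov–Smirnov test
for each subgroup pairing, plus a one-way ANOVA across the three subgroups.
Significance is flagged at α = 0.05 with no multiple-testing correction;
D'Agostino–Pearson is available to check normality assumptions. scipy.stats
provides the test machinery behind this surface.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

ALPHA = 0.05
SUBGROUPS = ("AA", "AO", "OO")


def ks_two_sample(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test.

    D is the supremum distance between the two empirical CDFs. With
    ``method='auto'`` the p-value is exact for small samples and comes from
    the asymptotic Kolmogorov distribution (effective n = nx·ny/(nx+ny))
    otherwise; ``'asymp'`` forces the asymptotic form.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = sps.ks_2samp(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def dagostino_pearson(x) -> tuple[float, float]:
    """D'Agostino–Pearson omnibus normality test (K² and chi²(2) p-value)."""
    x = np.asarray(x, float)
    if len(x) < 20:
        raise ValueError(
            "D'Agostino–Pearson needs n >= 20; the skewness/kurtosis "
            "z-transformations are invalid for smaller samples"
        )
    if np.ptp(x) == 0:
        raise ValueError("constant sample has no defined skewness/kurtosis")
    k2, p = sps.normaltest(x)
    return float(k2), float(p)


def one_way_anova(groups: list) -> tuple[float, float]:
    """One-way ANOVA: F = MS_between / MS_within, p from F(k−1, N−k)."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("each group needs at least 2 observations")
    if all(np.ptp(g) == 0 for g in arrays):
        raise ValueError("zero within-group variance in every group")
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


@dataclass
class ComparisonReport:
    """Per-metric subgroup summaries, KS pairings and ANOVA results."""

    alpha: float = ALPHA
    metrics: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "metrics": self.metrics}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def compare_subgroups(
    pair_table: pd.DataFrame,
    metrics: list[str],
    alpha: float = ALPHA,
    subgroup_col: str = "subgroup",
) -> ComparisonReport:
    """Compare metric distributions across the AA/AO/OO subgroups.

    ``pair_table`` has one row per maximum pair with a subgroup tag and one
    column per metric. Pairings with fewer than 2 entries on either side
    are reported as absent.
    """
    report = ComparisonReport(alpha=alpha)
    for metric in metrics:
        entry: dict = {"subgroups": {}, "ks": {}, "anova": None}
        samples: dict[str, np.ndarray] = {}
        for sg in SUBGROUPS:
            vals = pair_table.loc[
                pair_table[subgroup_col] == sg, metric
            ].dropna().to_numpy(dtype=float)
            samples[sg] = vals
            entry["subgroups"][sg] = {
                "n": int(len(vals)),
                "mean": float(np.mean(vals)) if len(vals) else None,
                "median": float(np.median(vals)) if len(vals) else None,
            }
        for a, b in (("AA", "AO"), ("AA", "OO"), ("AO", "OO")):
            if len(samples[a]) >= 2 and len(samples[b]) >= 2:
                d, p = ks_two_sample(samples[a], samples[b])
                entry["ks"][f"{a}_vs_{b}"] = {
                    "D": d, "p": p, "significant": bool(p < alpha)
                }
            else:
                log.info("%s: %s vs %s skipped (too few pairs)", metric, a, b)
                entry["ks"][f"{a}_vs_{b}"] = None
        populated = [s for s in samples.values() if len(s) >= 2]
        if len(populated) >= 2 and not all(np.ptp(s) == 0 for s in populated):
            f, p = one_way_anova(populated)
            entry["anova"] = {"F": f, "p": p, "significant": bool(p < alpha)}
        report.metrics[metric] = entry
    return report
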