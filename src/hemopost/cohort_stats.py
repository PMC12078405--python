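"""Cohort assembly and thrombosed-vs-control group comparison.

One row per aneurysm (case id, group label, optional pair id, feature
values); per-feature two-sided Wilcoxon tests between the thrombosed and
control groups:

* ``ranksum`` — unpaired Wilcoxon rank-sum (Mann-Whitney), exact
  distribution for combined n <= 30 without ties, normal approximation
  with tie correction otherwise;
* ``signed_rank`` — paired Wilcoxon signed-rank on within-pair
  differences, exact when sample size permits.

Summaries are mean ± sample SD (n−1 denominator) per group.  No
multiple-testing correction drives the significance flag (the comparison
is exploratory); a Benjamini-Hochberg adjusted column is emitted alongside
for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CohortTable",
    "ComparisonResult",
    "compare_groups",
    "summarize_table",
]

GROUPS = ("thrombosed", "control")

# deterministic report ordering: conventional parameter families first,
# then velocity-informatics channels
CONVENTIONAL_ORDER = [
    "SA_OSI", "Max_ECAP", "SA_ECAP", "Min_ECAP", "Max_RRT", "SA_RRT",
    "Mean_TAWSS", "TA_LSA", "TA_LSA_fraction", "STAWSS", "Systole_STAWSS",
    "STAWSS_min", "STAWSS_max", "TADVO", "TADVO_std", "Vortex_V", "Num_core",
    "Mean_NWSS_Div", "Mean_TSVI",
]


@dataclass
class CohortTable:
    """Per-case feature rows with group labels (and pair ids when matched)."""

    frame: pd.DataFrame  # columns: case_id, group, [pair_id], features...

    def __post_init__(self) -> None:
        required = {"case_id", "group"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        bad = set(self.frame["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}")

    @property
    def feature_names(self) -> list[str]:
        return [
            c for c in self.frame.columns
            if c not in ("case_id", "group", "pair_id")
        ]

    @property
    def is_paired(self) -> bool:
        if "pair_id" not in self.frame.columns:
            return False
        g = self.frame.groupby("pair_id")["group"].agg(lambda s: sorted(set(s)))
        return bool((g.map(tuple) == tuple(sorted(GROUPS))).all())

    def group_frame(self, group: str) -> pd.DataFrame:
        return self.frame[self.frame["group"] == group]


@dataclass
class ComparisonResult:
    """Per-feature group summaries and test results."""

    table: pd.DataFrame  # index: feature; columns: means, SDs, stat, p, flags
    mode: str
    alpha: float
    n_thrombosed: int
    n_control: int
    notes: dict[str, str] = field(default_factory=dict)


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum via Mann-Whitney U; exact when possible."""
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 30 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _signed_rank_p(diff: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank on paired differences."""
    if np.all(diff == 0):
        return 0.0, 1.0
    res = stats.wilcoxon(diff, alternative="two-sided", zero_method="wilcox",
                         method="auto")
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    table: CohortTable,
    mode: str = "auto",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Per-feature two-group comparison.

    ``mode``: ``ranksum`` (unpaired), ``signed_rank`` (paired; requires a
    perfect pair matching), or ``auto`` (paired when pair ids form a
    perfect matching — the matched-cohort default — else unpaired).
    Missing and non-finite values are excluded pairwise, with counts noted.
    A feature constant across both groups gets p = 1 and a degeneracy flag.
    """
    if mode == "auto":
        mode = "signed_rank" if table.is_paired else "ranksum"
    if mode not in ("ranksum", "signed_rank"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "signed_rank" and not table.is_paired:
        raise ValueError("signed_rank mode requires complete pairs (pair_id)")

    thr = table.group_frame("thrombosed")
    ctl = table.group_frame("control")
    if len(thr) < 2 or len(ctl) < 2:
        raise ValueError("need at least 2 cases per group")

    rows = []
    notes: dict[str, str] = {}
    for feat in table.feature_names:
        xt = thr[feat].to_numpy(dtype=float)
        xc = ctl[feat].to_numpy(dtype=float)
        ft, fc = np.isfinite(xt), np.isfinite(xc)
        n_excl = int((~ft).sum() + (~fc).sum())
        if n_excl:
            notes[feat] = f"excluded {n_excl} non-finite values"

        degenerate = False
        if mode == "ranksum":
            xt_v, xc_v = xt[ft], xc[fc]
            if len(xt_v) < 2 or len(xc_v) < 2:
                stat, p, degenerate = np.nan, np.nan, True
            elif np.unique(np.concatenate([xt_v, xc_v])).size == 1:
                stat, p, degenerate = 0.0, 1.0, True
            else:
                stat, p = _ranksum_p(xt_v, xc_v)
        else:
            merged = pd.merge(
                thr[["pair_id", feat]], ctl[["pair_id", feat]],
                on="pair_id", suffixes=("_t", "_c"),
            )
            d = (merged[f"{feat}_t"] - merged[f"{feat}_c"]).to_numpy(dtype=float)
            d = d[np.isfinite(d)]
            if len(d) < 2:
                stat, p, degenerate = np.nan, np.nan, True
            else:
                stat, p = _signed_rank_p(d)
                degenerate = bool(np.all(d == 0))

        rows.append({
            "feature": feat,
            "mean_thrombosed": float(np.mean(xt[ft])) if ft.any() else np.nan,
            "sd_thrombosed": float(np.std(xt[ft], ddof=1)) if ft.sum() > 1 else np.nan,
            "mean_control": float(np.mean(xc[fc])) if fc.any() else np.nan,
            "sd_control": float(np.std(xc[fc], ddof=1)) if fc.sum() > 1 else np.nan,
            "statistic": stat,
            "p_value": p,
            "degenerate": degenerate,
        })

    df = pd.DataFrame(rows).set_index("feature")
    finite_p = df["p_value"].notna()
    p_bh = np.full(len(df), np.nan)
    if finite_p.any():
        p_bh[finite_p.to_numpy()] = multipletests(
            df.loc[finite_p, "p_value"], method="fdr_bh"
        )[1]
    df["p_bh"] = p_bh
    df["significant"] = df["p_value"] < alpha
    return ComparisonResult(
        table=df, mode=mode, alpha=alpha,
        n_thrombosed=len(thr), n_control=len(ctl), notes=notes,
    )


def _feature_sort_key(name: str) -> tuple[int, int, str]:
    if name in CONVENTIONAL_ORDER:
        return (0, CONVENTIONAL_ORDER.index(name), name)
    if name.startswith("Magnitude_"):
        return (1, 0, name)
    if name.startswith("Direction_"):
        return (2, 0, name)
    return (3, 0, name)


def summarize_table(
    table: CohortTable, result: ComparisonResult
) -> pd.DataFrame:
    """Report frame in the cohort-comparison layout (one row per feature).

    Columns: parameter, thrombosed / non-thrombosed ``mean ± SD`` strings,
    P-value, significance flag; conventional parameters first, then the
    magnitude and direction velocity-informatics blocks.  Deterministic
    ordering; empty feature sets yield an empty frame.
    """
    feats = sorted(result.table.index, key=_feature_sort_key)
    rows = []
    for feat in feats:
        r = result.table.loc[feat]
        rows.append({
            "parameter": feat,
            "thrombosed": f"{r['mean_thrombosed']:.4g} ± {r['sd_thrombosed']:.4g}",
            "non_thrombosed": f"{r['mean_control']:.4g} ± {r['sd_control']:.4g}",
            "p_value": r["p_value"],
            "p_bh": r["p_bh"],
            "significant": bool(r["significant"]),
            "test": result.mode,
        })
    return pd.DataFrame(rows)
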