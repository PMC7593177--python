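"""Environmental characterization of zones.

Kira's warmth index (WI) and coldness index (CI) summarize the annual march
of monthly mean temperature t against a 5 degC physiological threshold:

    WI = sum over months with t > 5 of (t - 5)      [degC * month]
    CI = -sum over months with t < 5 of (t - 5)     [degC * month]

Months at exactly 5 degC contribute to neither index.  Continuous
per-zone comparisons use one-way ANOVA with Tukey's HSD (Tukey-Kramer form
for unequal group sizes) and a compact letter display; categorical factors
are summarized as per-zone composition ratios.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regionalize import ZoneMap

KIRA_THRESHOLD = 5.0  # degC

MONTH_COLUMNS = [f"t{m:02d}" for m in range(1, 13)]


def _check_monthly(monthly_temp: Sequence[float]) -> np.ndarray:
    t = np.asarray(monthly_temp, dtype=float)
    if t.shape != (12,):
        raise ValueError("need exactly 12 monthly temperatures")
    if not np.all(np.isfinite(t)):
        raise ValueError("monthly temperatures must be finite")
    return t


def warmth_index(monthly_temp: Sequence[float]) -> float:
    """Kira warmth index: annual heat sum above 5 degC (degC * month)."""
    t = _check_monthly(monthly_temp)
    warm = t > KIRA_THRESHOLD
    return float((t[warm] - KIRA_THRESHOLD).sum())


def coldness_index(monthly_temp: Sequence[float]) -> float:
    """Kira coldness index: annual cold sum below 5 degC, reported >= 0."""
    t = _check_monthly(monthly_temp)
    cold = t < KIRA_THRESHOLD
    return float(-(t[cold] - KIRA_THRESHOLD).sum())


def add_kira_indices(env: pd.DataFrame) -> pd.DataFrame:
    """Append ``wi`` and ``ci`` columns computed from t01..t12."""
    missing = [c for c in MONTH_COLUMNS if c not in env.columns]
    if missing:
        raise KeyError(f"missing monthly temperature columns: {missing}")
    out = env.copy()
    T = env[MONTH_COLUMNS].to_numpy(dtype=float)
    excess = T - KIRA_THRESHOLD
    out["wi"] = np.where(excess > 0, excess, 0.0).sum(axis=1)
    out["ci"] = -np.where(excess < 0, excess, 0.0).sum(axis=1)
    return out


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass
class TukeyResult:
    """Pairwise Tukey-Kramer comparisons and a compact letter display.

    ``pairs`` columns: group_i, group_j, mean_diff, q, p_adj, significant.
    ``letters`` maps group index -> letter string; groups sharing any letter
    are not significantly different at ``alpha``.
    """

    pairs: pd.DataFrame
    letters: dict[int, str]
    alpha: float
    ms_within: float
    df_within: int


def _group_arrays(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for g in gs:
        if g.size < 2:
            raise ValueError("each group needs at least 2 observations")
    return gs


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Fixed-effects one-way ANOVA from sums of squares.

    Raises on zero within-group variance (the F statistic is undefined).
    """
    gs = _group_arrays(groups)
    k = len(gs)
    n_total = sum(g.size for g in gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b, df_w = k - 1, n_total - k
    if ss_within <= 0:
        raise ValueError("zero within-group variance: F undefined")
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p)


def tukey_hsd(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> TukeyResult:
    """All-pairs Tukey HSD with studentized-range p-values and letters.

    For groups i, j with means m and sizes n, the statistic is

        q = |m_i - m_j| / sqrt(MS_within / 2 * (1/n_i + 1/n_j))

    (Tukey-Kramer for unequal sizes); the adjusted p comes from the
    studentized range distribution with k groups and the ANOVA's within
    degrees of freedom.
    """
    gs = _group_arrays(groups)
    k = len(gs)
    df_w = sum(g.size for g in gs) - k
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    if ss_within <= 0:
        raise ValueError("zero within-group variance: q undefined")
    ms_within = ss_within / df_w
    rows = []
    sig_pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = gs[i].mean() - gs[j].mean()
            se = np.sqrt(ms_within / 2.0 * (1.0 / gs[i].size + 1.0 / gs[j].size))
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df_w))
            p_adj = min(max(p_adj, 0.0), 1.0)
            sig = p_adj < alpha
            if sig:
                sig_pairs.append((i, j))
            rows.append(
                {
                    "group_i": i,
                    "group_j": j,
                    "mean_diff": float(diff),
                    "q": float(q),
                    "p_adj": p_adj,
                    "significant": sig,
                }
            )
    letters = _letter_display(k, sig_pairs)
    return TukeyResult(
        pairs=pd.DataFrame(rows),
        letters=letters,
        alpha=alpha,
        ms_within=float(ms_within),
        df_within=df_w,
    )


def _letter_display(k: int, sig_pairs: Sequence[tuple[int, int]]) -> dict[int, str]:
    """Insert-and-absorb letter display over the nonsignificance graph.

    Starts from one set of all groups; each significant pair splits every
    set containing both; subsets absorbed; letters assigned in order of the
    smallest group index in each set.
    """
    sets: list[set[int]] = [set(range(k))]
    for i, j in sig_pairs:
        new_sets: list[set[int]] = []
        for s in sets:
            if i in s and j in s:
                new_sets.append(s - {i})
                new_sets.append(s - {j})
            else:
                new_sets.append(s)
        # absorb: drop empty sets, duplicates and proper subsets
        pruned: list[set[int]] = []
        for s in new_sets:
            if not s or any(s < t for t in new_sets):
                continue
            if s not in pruned:
                pruned.append(s)
        sets = pruned
    sets.sort(key=lambda s: min(s))
    letters = {g: "" for g in range(k)}
    for letter, s in zip(string.ascii_lowercase, sets):
        for g in sorted(s):
            letters[g] += letter
    return letters


def zone_groups(
    env: pd.DataFrame, zm: ZoneMap, variable: str, cell_col: str = "cell_id"
) -> dict[int, np.ndarray]:
    """Values of ``variable`` grouped by zone for assigned cells."""
    if variable not in env.columns:
        raise KeyError(f"unknown variable {variable!r}")
    vals = env.set_index(cell_col)[variable]
    out: dict[int, np.ndarray] = {}
    for z in zm.zones:
        cells = np.flatnonzero(zm.labels == z)
        v = vals.reindex(cells).dropna().to_numpy(dtype=float)
        out[z] = v
    return out


def composition_ratio(
    env: pd.DataFrame, zm: ZoneMap, variable: str, cell_col: str = "cell_id"
) -> pd.DataFrame:
    """Per-zone percentage of cells in each class of a categorical variable.

    Rows (zones, plus ``Total`` over all assigned cells) sum to 100;
    missing values are excluded from the denominator.
    """
    if variable not in env.columns:
        raise KeyError(f"unknown variable {variable!r}")
    vals = env.set_index(cell_col)[variable]
    zones = zm.zones
    classes = sorted(vals.dropna().astype(str).unique())
    rows = {}
    for z in zones + ["Total"]:
        cells = np.flatnonzero(zm.assigned if z == "Total" else (zm.labels == z))
        v = vals.reindex(cells).dropna().astype(str)
        if len(v) == 0:
            rows[z] = {c: np.nan for c in classes}
            continue
        counts = v.value_counts()
        rows[z] = {c: 100.0 * counts.get(c, 0) / len(v) for c in classes}
    return pd.DataFrame.from_dict(rows, orient="index", columns=classes)
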