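"""Method-agreement statistics: MAE, ICC(2,1) with CI, one-way ANOVA,
Bland–Altman limits and success-rate curves.

The intraclass correlation is the two-way random-effects, absolute-agreement,
single-measure form — the standard choice for comparing an automated method
against human raters — with the usual F-based 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MeasurementTable",
    "mae",
    "icc",
    "anova_consistency",
    "bland_altman",
    "success_rate_curve",
    "agreement_report",
]

TABLE_COLUMNS = ["case", "jaw", "tooth", "source", "value"]


@dataclass
class MeasurementTable:
    """Long-format measurement table: one row per (case, jaw, tooth, source)."""

    data: pd.DataFrame

    def __post_init__(self):
        missing = set(TABLE_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"measurement table missing columns: {sorted(missing)}")
        if self.data.duplicated(subset=["case", "jaw", "tooth", "source"]).any():
            raise ValueError("duplicate (case, jaw, tooth, source) keys")
        if (self.data["value"] <= 0).any():
            raise ValueError("measurement values must be positive")

    @classmethod
    def from_records(cls, records) -> "MeasurementTable":
        return cls(pd.DataFrame.from_records(records, columns=TABLE_COLUMNS))

    def pivot(self, sources) -> pd.DataFrame:
        """Complete crossed design (rows = items, columns = sources)."""
        df = self.data[self.data["source"].isin(sources)]
        wide = df.pivot_table(
            index=["case", "jaw", "tooth"], columns="source", values="value", aggfunc="first"
        )
        wide = wide.reindex(columns=list(sources))
        if wide.isna().any().any():
            miss = wide[wide.isna().any(axis=1)].index.tolist()[:10]
            raise ValueError(f"incomplete crossed design; missing cells for items {miss}")
        return wide


def mae(a, b) -> float:
    """Mean absolute error between paired measurement vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("inputs must be equal-length and nonempty")
    return float(np.mean(np.abs(a - b)))


def _icc_from_matrix(Y: np.ndarray, alpha: float = 0.05):
    n, k = Y.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs at least 2 items and 2 sources")
    grand = Y.mean()
    row_m = Y.mean(axis=1)
    col_m = Y.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_err = np.sum((Y - row_m[:, None] - col_m[None, :] + grand) ** 2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    r = (msr - mse) / denom if denom > 0 else 1.0
    if mse == 0 and msc == 0:
        return 1.0, (1.0, 1.0)
    # F-based CI (McGraw & Wong, ICC(A,1)) with Satterthwaite df
    r = float(np.clip(r, -1.0, 1.0))
    if r >= 1.0 - 1e-12:
        return 1.0, (1.0, 1.0)
    a = k * r / (n * (1.0 - r))
    b = 1.0 + k * r * (n - 1.0) / (n * (1.0 - r))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return r, (float(lower), float(upper))


def icc(table: MeasurementTable, sources, alpha: float = 0.05):
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Returns (estimate, (ci_low, ci_high)).  The design must be completely
    crossed over the chosen sources.
    """
    wide = table.pivot(sources)
    return _icc_from_matrix(wide.to_numpy(float), alpha=alpha)


def anova_consistency(groups, alpha: float = 0.05):
    """One-way fixed-effects ANOVA with the critical F at the given level.

    Returns a dict with F, dfs, F_critical and the p-value.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(groups)
    N = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    df_b, df_w = k - 1, N - k
    msb, msw = ssb / df_b, ssw / df_w
    F = msb / msw if msw > 0 else (0.0 if msb == 0 else np.inf)
    p = float(stats.f.sf(F, df_b, df_w))
    f_crit = float(stats.f.ppf(1 - alpha, df_b, df_w))
    return {"F": float(F), "df": (df_b, df_w), "F_critical": f_crit, "p": p, "alpha": alpha}


def bland_altman(a, b):
    """Mean difference and mean ± 1.96·SD limits of agreement (sample SD)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("inputs must be equal-length with at least 2 pairs")
    d = a - b
    m = float(d.mean())
    s = float(d.std(ddof=1))
    return {"mean": m, "lower": m - 1.96 * s, "upper": m + 1.96 * s, "sd": s}


def success_rate_curve(errors, thresholds) -> np.ndarray:
    """Fraction of absolute errors strictly below each threshold."""
    errors = np.asarray(errors, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if errors.size == 0:
        raise ValueError("empty error list")
    return np.array([float(np.mean(errors < t)) for t in thresholds])


def agreement_report(
    table: MeasurementTable,
    source_a: str,
    source_b: str,
    by_tooth: bool = True,
    thresholds=None,
    alpha: float = 0.05,
) -> dict:
    """Full agreement report between two measurement sources."""
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.55, 0.1), 3)
    wide = table.pivot([source_a, source_b])
    a = wide[source_a].to_numpy(float)
    b = wide[source_b].to_numpy(float)
    est, ci = icc(table, [source_a, source_b], alpha=alpha)
    ba = bland_altman(a, b)
    errs = np.abs(a - b)
    rep = {
        "icc_form": "two-way random, absolute agreement, single measure (ICC(2,1))",
        "icc": est,
        "icc_ci95": ci,
        "mae": mae(a, b),
        "bland_altman": ba,
        "success_rate": {
            "thresholds_mm": list(map(float, thresholds)),
            "fractions": list(map(float, success_rate_curve(errs, thresholds))),
        },
        "n_pairs": int(len(a)),
    }
    if by_tooth:
        per = {}
        tooth_idx = wide.index.get_level_values("tooth")
        for tooth in sorted(set(tooth_idx)):
            sel = tooth_idx == tooth
            if sel.sum() >= 1:
                per[str(tooth)] = mae(a[sel], b[sel])
        rep["mae_by_tooth"] = per
    return rep
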