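"""Two-step feature screening and partial-correlation verification.

Step one drops candidate features whose Pearson correlation with LAI is
weak (|r| below threshold) in *every* phenological stage — a feature that
works in even one stage is kept. Step two removes severe multicollinearity
by iteratively eliminating the single feature with the highest variance
inflation factor (VIF) above threshold, recomputing after each removal.
A partial-correlation pass then verifies that each retained feature keeps
an independent association with LAI once its co-features are controlled
for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from canopylai.preprocessing import feature_columns

__all__ = [
    "ScreeningReport",
    "pearson_by_stage",
    "screen_by_correlation",
    "compute_vif",
    "screen_by_vif",
    "partial_correlation",
    "screen_features",
]

#: VIF sentinel for perfect collinearity
VIF_INF = np.inf


@dataclass
class ScreeningReport:
    """Per-feature outcome of the full screening pass."""

    pearson: pd.DataFrame  # features x stages, signed r
    max_abs_r: pd.Series
    retained: list[str]
    eliminated: dict[str, str]  # feature -> single elimination reason
    vif_trace: list[tuple[str, float]] = field(default_factory=list)
    final_vif: pd.Series | None = None
    partial_r: pd.Series | None = None

    def summary(self) -> pd.DataFrame:
        rows = []
        for f in self.pearson.index:
            rows.append(
                {
                    "feature": f,
                    "max_abs_r": self.max_abs_r[f],
                    "retained": f in self.retained,
                    "reason": self.eliminated.get(f, ""),
                    "vif": (
                        self.final_vif.get(f, np.nan)
                        if self.final_vif is not None
                        else np.nan
                    ),
                    "partial_r": (
                        self.partial_r.get(f, np.nan)
                        if self.partial_r is not None
                        else np.nan
                    ),
                }
            )
        return pd.DataFrame(rows).set_index("feature")


def pearson_by_stage(table: pd.DataFrame) -> pd.DataFrame:
    """Signed Pearson r between every feature and LAI, within each stage.

    Constant columns (in a stage) get r = 0; a stage with fewer than 3
    rows is an error — a two-point correlation is always +/-1.
    """
    feats = feature_columns(table)
    stages = sorted(table["stage"].unique())
    out = pd.DataFrame(index=feats, columns=stages, dtype=float)
    for stage in stages:
        sub = table[table["stage"] == stage]
        if len(sub) < 3:
            raise ValueError(f"stage {stage} has fewer than 3 samples")
        y = sub["lai"].to_numpy(dtype=float)
        ys = y.std()
        for f in feats:
            x = sub[f].to_numpy(dtype=float)
            if x.std() == 0 or ys == 0:
                out.loc[f, stage] = 0.0
            else:
                out.loc[f, stage] = float(np.corrcoef(x, y)[0, 1])
    return out


def screen_by_correlation(
    pearson: pd.DataFrame, threshold: float = 0.10
) -> tuple[list[str], dict[str, str]]:
    """Keep features with |r| >= threshold in at least one stage.

    Elimination requires |r| < threshold in *all* stages (strict <, so a
    feature sitting exactly at the threshold is retained). Returns the
    retained names in table order and the elimination reasons.
    """
    retained, eliminated = [], {}
    for f in pearson.index:
        rs = pearson.loc[f].abs()
        if (rs < threshold).all():
            eliminated[f] = (
                f"|r| < {threshold} with LAI in all {pearson.shape[1]} stages"
            )
        else:
            retained.append(f)
    return retained, eliminated


def _r2_on_others(X: np.ndarray, k: int) -> float:
    """R^2 of column k regressed (with intercept) on the other columns."""
    y = X[:, k]
    others = np.delete(X, k, axis=1)
    design = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        return 0.0
    return 1.0 - float((resid**2).sum()) / sst


def compute_vif(table: pd.DataFrame, feature: str) -> float:
    """Variance inflation factor of one feature against its co-features.

    VIF = 1 / (1 - R^2) of the least-squares regression (with intercept)
    of the feature on all other candidate features; perfect collinearity
    returns the +inf sentinel.
    """
    feats = feature_columns(table)
    if feature not in feats:
        raise KeyError(feature)
    if len(feats) < 2:
        raise ValueError("VIF needs at least 2 features")
    n, p = len(table), len(feats)
    if n <= p:
        raise ValueError(f"rank deficiency: n={n} <= p={p}")
    X = table[feats].to_numpy(dtype=float)
    r2 = _r2_on_others(X, feats.index(feature))
    if r2 >= 1.0 - 1e-12:
        return VIF_INF
    return 1.0 / (1.0 - r2)


def screen_by_vif(
    table: pd.DataFrame, threshold: float = 10.0
) -> tuple[list[str], list[tuple[str, float]]]:
    """Iterative highest-VIF elimination.

    Removes the single feature with the largest VIF strictly above the
    threshold, recomputes all VIFs, and repeats; a VIF of exactly the
    threshold is retained. Ties break to the earliest column, for
    reproducibility. Returns retained names and the ordered elimination
    trace (feature, VIF at removal).
    """
    feats = feature_columns(table)
    trace: list[tuple[str, float]] = []
    current = list(feats)
    while len(current) >= 2:
        X = table[current].to_numpy(dtype=float)
        vifs = []
        for k in range(len(current)):
            r2 = _r2_on_others(X, k)
            vifs.append(VIF_INF if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
        vifs = np.array(vifs)
        worst = int(np.argmax(vifs))  # argmax takes the earliest tie
        if vifs[worst] <= threshold:
            break
        trace.append((current[worst], float(vifs[worst])))
        current.pop(worst)
    return current, trace


def partial_correlation(
    table: pd.DataFrame, feature: str, controls: list[str] | None = None
) -> float:
    """Partial Pearson r between a feature and LAI given control features.

    Both the feature and LAI are residualized on the controls by least
    squares (with intercept); the partial r is the plain correlation of
    the residuals. Zero-variance residuals (e.g. the feature is itself a
    control) give r = 0.
    """
    feats = feature_columns(table)
    if controls is None:
        controls = [f for f in feats if f != feature]
    if feature in controls:
        controls = [c for c in controls if c != feature]
    y = table["lai"].to_numpy(dtype=float)
    x = table[feature].to_numpy(dtype=float)
    x_scale, y_scale = max(x.std(), 1e-30), max(y.std(), 1e-30)
    if controls:
        Z = np.column_stack(
            [np.ones(len(table))] + [table[c].to_numpy(dtype=float) for c in controls]
        )
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("rank-deficient control set")
        x = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        y = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    # residuals that are pure numerical dust count as degenerate
    if x.std() <= 1e-10 * x_scale or y.std() <= 1e-10 * y_scale:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def screen_features(
    table: pd.DataFrame,
    r_threshold: float = 0.10,
    vif_threshold: float = 10.0,
) -> ScreeningReport:
    """Run the full two-step screening and partial-correlation check."""
    pearson = pearson_by_stage(table)
    kept_r, eliminated = screen_by_correlation(pearson, r_threshold)
    meta = [c for c in table.columns if c not in feature_columns(table)]
    sub = table[meta + kept_r]
    kept, trace = screen_by_vif(sub, vif_threshold)
    for name, vif in trace:
        eliminated[name] = f"VIF {vif:.3g} > {vif_threshold}"
    final = table[meta + kept]
    final_vif = pd.Series(
        {f: compute_vif(final, f) if len(kept) >= 2 else 1.0 for f in kept}
    )
    partial = pd.Series(
        {f: partial_correlation(final, f) for f in kept}, dtype=float
    )
    return ScreeningReport(
        pearson=pearson,
        max_abs_r=pearson.abs().max(axis=1),
        retained=kept,
        eliminated=eliminated,
        vif_trace=trace,
        final_vif=final_vif,
        partial_r=partial,
    )
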