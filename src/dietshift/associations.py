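"""Per-feature differential-change testing, trend tests and FDR control.

Differential change fits, per taxon, a model of abundance on
group + time + group:time with a per-subject random intercept.  With
exactly two timepoints this mixed model reduces algebraically to an
ordinary regression of the per-subject change score on group, which is
the path taken here (the equivalence is exercised in the test suite
against an explicit mixed-model fit).  Trend tests use Kendall's tau-b
with the intervention arms as a ranked variable; taxon-biomarker maps
use Spearman correlation.  All per-feature p-values are controlled by
Benjamini-Hochberg with the study-wide discovery target q < 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import FeatureTable, half_min_pseudocount, to_relative

FDR_TARGET = 0.25


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class FeatureAssocResult:
    """Per-feature test results with BH-adjusted q-values."""

    table: pd.DataFrame  # per feature: coefficients, p, q, direction, flag
    model: str
    transformation: str

    def hits(self, q_threshold: float = FDR_TARGET) -> pd.Index:
        return self.table.index[self.table["q"] < q_threshold]


def log_transform(table: FeatureTable, pseudocount: float | str = "half-min") -> pd.DataFrame:
    """Total-sum scaling then natural log with a half-minimum pseudocount."""
    rel = table if table.is_relative() else to_relative(table)
    eps = (
        half_min_pseudocount(rel.data)
        if pseudocount == "half-min"
        else float(pseudocount)
    )
    return np.log(rel.data + eps)


def differential_change(
    table: FeatureTable, transformation: str = "log-tss"
) -> FeatureAssocResult:
    """Group x time interaction test per taxon with subject random effect.

    Returns per-feature interaction p (joint F over the group contrasts
    of the change score), BH q across features, per-arm change
    coefficients, and the direction of the strongest arm's change.
    Features constant after transformation get p = 1 with a flag.
    """
    if transformation != "log-tss":
        raise ValueError(f"unknown transformation {transformation!r}")
    logged = log_transform(table)
    meta = table.meta

    wide = {}
    for tp in ("t0", "t6"):
        sub = meta[meta["timepoint"] == tp]
        frame = logged.loc[sub.index]
        frame.index = sub["subject"].to_numpy()
        wide[tp] = frame
    common = wide["t0"].index.intersection(wide["t6"].index)
    if len(common) < 3:
        raise ValueError("need at least 3 subjects with both timepoints")
    delta = wide["t6"].loc[common] - wide["t0"].loc[common]

    groups = (
        meta[meta["subject"].isin(common)][["subject", "group"]]
        .drop_duplicates("subject")
        .set_index("subject")
        .loc[common, "group"]
    )
    levels = list(pd.unique(groups))
    dummies = pd.get_dummies(groups, drop_first=True).astype(float)
    x = np.hstack([np.ones((len(common), 1)), dummies.to_numpy()])
    n, k = x.shape
    df_res = n - k
    if df_res < 1:
        raise ValueError("not enough subjects for the group model")

    xtx_inv = np.linalg.inv(x.T @ x)
    hat = x @ xtx_inv @ x.T
    y = delta.to_numpy()  # subjects x features
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    sigma2 = (resid**2).sum(axis=0) / df_res

    # joint F over the group-contrast coefficients (the interaction)
    c = np.zeros((k - 1, k))
    c[:, 1:] = np.eye(k - 1)
    cb = c @ beta  # contrasts x features
    cvc = c @ xtx_inv @ c.T
    cvc_inv = np.linalg.inv(cvc)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.einsum("cf,cd,df->f", cb, cvc_inv, cb)
        f_stat = wald / (k - 1) / sigma2
    constant = sigma2 <= 1e-24
    p = np.where(
        constant, 1.0, stats.f.sf(np.where(constant, np.nan, f_stat), k - 1, df_res)
    )

    # per-arm mean change and direction of the largest-|shift| arm
    arm_means = pd.DataFrame(
        {lvl: delta.loc[groups == lvl].mean(axis=0) for lvl in levels}
    )
    rel_to_ref = arm_means.sub(arm_means[levels[0]], axis=0)
    strongest = rel_to_ref.abs().to_numpy().argmax(axis=1)
    direction = np.sign(
        rel_to_ref.to_numpy()[np.arange(len(delta.columns)), strongest]
    )

    out = pd.DataFrame(
        {
            "p": p,
            "q": bh_adjust(p),
            "direction": direction,
            "constant": constant,
        },
        index=delta.columns,
    )
    for lvl in levels:
        out[f"change_{lvl}"] = arm_means[lvl]
    return FeatureAssocResult(out, model="change-score OLS (== 2-timepoint LMM)", transformation="log-tss")


def trend_test(values, group_rank) -> tuple[float, float]:
    """Kendall tau-b between a per-subject quantity and ranked groups.

    Exact p when feasible (small n, no ties), tie-corrected normal
    approximation otherwise — scipy picks per its documented rule.
    """
    v = np.asarray(values, dtype=float)
    r = np.asarray(group_rank, dtype=float)
    ok = np.isfinite(v) & np.isfinite(r)
    v, r = v[ok], r[ok]
    if len(np.unique(r)) < 2:
        raise ValueError("need at least 2 distinct group ranks")
    if np.ptp(v) == 0:
        raise ValueError("all values identical: trend undefined")
    res = stats.kendalltau(v, r, variant="b", method="auto")
    return float(res.statistic), float(res.pvalue)


def trend_test_batch(values: pd.DataFrame, group_rank: pd.Series) -> pd.DataFrame:
    """trend_test per column, BH across columns; constant columns flagged."""
    rows = {}
    for col in values.columns:
        try:
            tau, p = trend_test(values[col], group_rank.loc[values.index])
        except ValueError:
            tau, p = np.nan, 1.0
        rows[col] = (tau, p)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["tau_b", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def taxon_biomarker_map(
    change_values: pd.DataFrame, biomarker_changes: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rho per (taxon, biomarker) pair, BH across the grid.

    Both frames are indexed by subject; pairs are computed on the
    common subjects, pairwise-complete per biomarker.
    """
    common = change_values.index.intersection(biomarker_changes.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired subjects")
    taxa = change_values.loc[common]
    marks = biomarker_changes.loc[common]
    rows = []
    for marker in marks.columns:
        y = marks[marker]
        ok = y.notna().to_numpy()
        n = int(ok.sum())
        if n < 3:
            raise ValueError(f"fewer than 3 paired observations for {marker!r}")
        # Spearman = Pearson on midranks; p from the t approximation
        rx = stats.rankdata(taxa.loc[ok].to_numpy(), axis=0)
        ry = stats.rankdata(y[ok].to_numpy())
        rx = rx - rx.mean(axis=0)
        ry = ry - ry.mean()
        denom = np.sqrt((rx**2).sum(axis=0) * (ry**2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = np.where(denom > 0, rx.T @ ry / denom, np.nan)
            rho = np.clip(rho, -1.0, 1.0)
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = np.where(
            np.isnan(rho), 1.0, np.where(np.abs(rho) >= 1.0, 0.0, 2 * stats.t.sf(np.abs(t), n - 2))
        )
        for taxon, r_, p_ in zip(taxa.columns, rho, p):
            rows.append({"taxon": taxon, "marker": marker, "rho": r_, "p": p_})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
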