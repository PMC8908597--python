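"""Causal mediation: how much of the diet-adherence effect on a
cardiometabolic outcome passes through microbiome change.

Two estimators:

* :func:`mediate_summary` — single-mediator linear mediation with
  quasi-Bayesian uncertainty.  Fit M ~ X (+Z) and Y ~ X + M (+Z) by
  OLS, draw coefficient vectors from their estimated sampling
  distributions, and summarize the average causal mediation effect
  (ACME = a*b for linear models), the direct effect (ADE = c'), the
  total effect and the proportion mediated with percentile intervals.

* :func:`mediate_highdim` — per-taxon mediation over a high-dimensional
  change matrix: sure-independence screening to ~n/log(n) candidates,
  L1-penalized joint outcome model to select mediators, then
  joint-significance testing (p = max of the two path p-values) with BH
  correction and a per-taxon proportion mediated a*b / total effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LassoCV

from .associations import bh_adjust
from .tables import ChangeMatrix


@dataclass
class MediationResult:
    acme: float
    ade: float
    total: float
    proportion_mediated: float  # NaN when the total effect is unstable
    ci: dict = field(default_factory=dict)  # name -> (lo, hi), 95% percentile
    n_simulations: int = 0
    labels: dict = field(default_factory=dict)
    pm_stable: bool = True

    def summary(self) -> str:
        lines = [
            f"exposure={self.labels.get('exposure')} mediator={self.labels.get('mediator')} "
            f"outcome={self.labels.get('outcome')}",
            f"  ACME  {self.acme: .4f}  CI {self.ci.get('acme')}",
            f"  ADE   {self.ade: .4f}  CI {self.ci.get('ade')}",
            f"  Total {self.total: .4f}  CI {self.ci.get('total')}",
        ]
        if self.pm_stable:
            lines.append(
                f"  Prop. mediated {self.proportion_mediated: .4f}  CI {self.ci.get('proportion_mediated')}"
            )
        else:
            lines.append("  Prop. mediated: unstable (total-effect CI covers 0)")
        return "\n".join(lines)


def _design(x: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(x), x]
    if covariates is not None:
        cols.append(covariates)
    return np.column_stack(cols)


def _complete_cases(*arrays):
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        if a is None:
            continue
        a2 = np.atleast_2d(np.asarray(a, dtype=float).T).T
        mask &= np.isfinite(a2).all(axis=1)
    return mask


def mediate_summary(
    exposure,
    mediator,
    outcome,
    covariates=None,
    n_sim: int = 1000,
    seed: int | np.random.Generator | None = None,
    labels: dict | None = None,
) -> MediationResult:
    """Linear-model causal mediation with quasi-Bayesian intervals.

    For the two linear models without exposure-mediator interaction the
    simulated potential-outcome contrasts reduce to products of drawn
    coefficients: ACME = a*b, ADE = c', total = a*b + c'.  Percentile
    CIs come from ``n_sim`` multivariate-normal coefficient draws.  The
    proportion mediated is reported only when the total-effect CI
    excludes zero; otherwise it is flagged unstable.
    """
    x = np.asarray(exposure, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    z = None if covariates is None else np.asarray(covariates, dtype=float)
    mask = _complete_cases(x, m, y, z)
    x, m, y = x[mask], m[mask], y[mask]
    if z is not None:
        z = np.atleast_2d(z.T).T[mask]
    if len(x) < 10:
        raise ValueError("need at least 10 complete cases")
    if n_sim < 100:
        warnings.warn("n_sim < 100 gives unreliable intervals", stacklevel=2)

    # collinearity guard: mediator must have variance beyond the exposure
    xm_r = np.corrcoef(x, m)[0, 1]
    if not np.isfinite(xm_r) or abs(xm_r) > 1 - 1e-10:
        raise ValueError("exposure and mediator are collinear")

    med_fit = sm.OLS(m, _design(x, z)).fit()
    out_fit = sm.OLS(y, np.column_stack([_design(x, z), m])).fit()
    a_hat, b_hat, c_hat = med_fit.params[1], out_fit.params[-1], out_fit.params[1]

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a_draw = rng.multivariate_normal(med_fit.params, med_fit.cov_params(), size=n_sim)[:, 1]
    out_draws = rng.multivariate_normal(out_fit.params, out_fit.cov_params(), size=n_sim)
    b_draw, c_draw = out_draws[:, -1], out_draws[:, 1]

    acme_d = a_draw * b_draw
    ade_d = c_draw
    total_d = acme_d + ade_d
    ci = {
        "acme": tuple(np.percentile(acme_d, [2.5, 97.5])),
        "ade": tuple(np.percentile(ade_d, [2.5, 97.5])),
        "total": tuple(np.percentile(total_d, [2.5, 97.5])),
    }
    total_hat = a_hat * b_hat + c_hat
    stable = ci["total"][0] > 0 or ci["total"][1] < 0
    if stable:
        pm_d = acme_d / total_d
        ci["proportion_mediated"] = tuple(np.percentile(pm_d, [2.5, 97.5]))
        pm = float(a_hat * b_hat / total_hat)
    else:
        pm = float("nan")
    return MediationResult(
        acme=float(a_hat * b_hat),
        ade=float(c_hat),
        total=float(total_hat),
        proportion_mediated=pm,
        ci=ci,
        n_simulations=n_sim,
        labels=labels or {},
        pm_stable=stable,
    )


@dataclass
class HighDimMediationResult:
    table: pd.DataFrame  # per selected taxon: alpha, beta, ab, p_joint, q, prop_mediated
    screened: list  # taxa passing the marginal screen
    n_screened: int
    total_effect: float

    def significant(self, q_threshold: float = 0.25) -> pd.Index:
        return self.table.index[self.table["q"] < q_threshold]


def mediate_highdim(
    exposure,
    mediators: ChangeMatrix | pd.DataFrame,
    outcome,
    covariates=None,
    seed: int | np.random.Generator | None = None,
    n_cv_folds: int = 5,
) -> HighDimMediationResult:
    """Identify individual taxa whose change mediates exposure -> outcome.

    Three stages: (1) screen to the top ceil(n / log n) taxa by the
    marginal taxon-outcome association adjusted for the exposure;
    (2) select mediators by L1-penalized regression of the outcome on
    the screened taxa plus exposure, penalty chosen by cross-validation;
    (3) for every selected taxon report a (exposure->taxon), b
    (taxon->outcome in the joint model), joint-significance
    p = max(p_a, p_b), BH q across selected taxa, and a*b / total
    effect as the per-taxon proportion mediated.
    """
    values = mediators.values if isinstance(mediators, ChangeMatrix) else mediators
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    mmat = values.to_numpy(dtype=float)
    z = None if covariates is None else np.atleast_2d(np.asarray(covariates, float).T).T
    mask = _complete_cases(x, y, mmat, z)
    x, y, mmat = x[mask], y[mask], mmat[mask]
    if z is not None:
        z = z[mask]
    taxa = list(values.columns)
    n = len(x)
    if n < 4 * n_cv_folds:
        raise ValueError(f"too few subjects (n={n}) for screening + cross-validation")
    d = int(np.ceil(n / np.log(n)))
    if d < 2:
        raise ValueError("too few subjects for screening (ceil(n/log n) < 2)")
    d = min(d, len(taxa))

    # stage 1: sure-independence screening on outcome | exposure
    base = _design(x, z)
    t_abs = np.empty(len(taxa))
    for j in range(mmat.shape[1]):
        fit = sm.OLS(y, np.column_stack([base, mmat[:, j]])).fit()
        t_abs[j] = abs(fit.tvalues[-1])
    screen_idx = np.argsort(t_abs)[::-1][:d]
    screened = [taxa[j] for j in screen_idx]

    # stage 2: L1 selection in the joint outcome model (exposure partialled out)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    resid_proj = np.eye(n) - base @ np.linalg.pinv(base)
    y_r = resid_proj @ y
    m_r = resid_proj @ mmat[:, screen_idx]
    lasso = LassoCV(
        cv=n_cv_folds, random_state=int(rng.integers(2**31 - 1)), alphas=50
    ).fit(m_r, y_r)
    sel = np.flatnonzero(lasso.coef_ != 0)
    selected_idx = screen_idx[sel]
    selected = [taxa[j] for j in selected_idx]

    total_fit = sm.OLS(y, base).fit()
    total_effect = float(total_fit.params[1])

    rows = []
    if len(selected_idx) > 0:
        joint = sm.OLS(
            y, np.column_stack([base, mmat[:, selected_idx]])
        ).fit()
        for pos, j in enumerate(selected_idx):
            a_fit = sm.OLS(mmat[:, j], base).fit()
            a, p_a = float(a_fit.params[1]), float(a_fit.pvalues[1])
            b = float(joint.params[base.shape[1] + pos])
            p_b = float(joint.pvalues[base.shape[1] + pos])
            ab = a * b
            rows.append(
                {
                    "taxon": taxa[j],
                    "alpha": a,
                    "beta": b,
                    "ab": ab,
                    "p_joint": max(p_a, p_b),
                    "prop_mediated": ab / total_effect if total_effect != 0 else np.nan,
                }
            )
    table = pd.DataFrame(rows).set_index("taxon") if rows else pd.DataFrame(
        columns=["alpha", "beta", "ab", "p_joint", "prop_mediated"]
    )
    if len(table):
        table["q"] = bh_adjust(table["p_joint"].to_numpy())
        table = table.sort_values("q")
    else:
        table["q"] = pd.Series(dtype=float)
    return HighDimMediationResult(table, screened, d, total_effect)
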