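"""Community-level permutation tests on distance matrices.

PERMANOVA partitions the sums of squares of a dissimilarity matrix by
sequential (Type-I) design terms, with a pseudo-F per term and
permutation p-values.  On top of that sit the group x time interaction
model for two-timepoint intervention cohorts, leave-one-out group-pair
contrasts, single-covariate variance-explained tests, and the
convergence test that compares within- vs between-group dissimilarity
against a label-permutation null.

All p-values use the add-one convention p = (1 + exceedances) / (1 + B),
so no permutation p is ever exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
import itertools

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .associations import bh_adjust
from .distances import gower_center

GROUP_ORDER_KEY = "group"


# ---------------------------------------------------------------------
# design-matrix construction (sequential terms, adonis convention)
# ---------------------------------------------------------------------

def _term_columns(design: pd.DataFrame, term: str) -> np.ndarray:
    """Columns for one term: treatment-coded dummies, products for a:b."""

    def encode(name: str) -> np.ndarray:
        if name not in design.columns:
            raise ValueError(f"term {name!r} not in design")
        col = design[name]
        if col.dtype.kind in "if":
            x = col.to_numpy(dtype=float)[:, None]
            if np.ptp(x) == 0:
                raise ValueError(f"constant covariate {name!r}")
            return x - x.mean()
        levels = pd.unique(col)
        if len(levels) < 2:
            raise ValueError(f"categorical term {name!r} has < 2 levels")
        return pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)

    parts = term.split(":")
    cols = encode(parts[0])
    for part in parts[1:]:
        other = encode(part)
        cols = np.einsum("ni,nj->nij", cols, other).reshape(len(design), -1)
    return cols


def _sequential_projectors(
    design: pd.DataFrame, terms: list[str]
) -> tuple[list[np.ndarray], np.ndarray, list[int]]:
    """Per-term projector increments, residual projector, and term dfs."""
    n = len(design)
    x = np.ones((n, 1))
    h_prev = np.full((n, n), 1.0 / n)
    rank_prev = 1
    projectors, dfs = [], []
    for term in terms:
        x = np.hstack([x, _term_columns(design, term)])
        q, r = np.linalg.qr(x)
        keep = np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(r).max())
        rank = int(keep.sum())
        qk = q[:, keep]
        h = qk @ qk.T
        df = rank - rank_prev
        if df < 1:
            raise ValueError(f"term {term!r} adds no rank (singular design)")
        projectors.append(h - h_prev)
        dfs.append(df)
        h_prev, rank_prev = h, rank
    residual = np.eye(n) - h_prev
    if n - rank_prev < 1:
        raise ValueError("saturated design: no residual degrees of freedom")
    return projectors, residual, dfs


@dataclass
class PermanovaResult:
    """Sequential-SS partition of a distance matrix with permutation p."""

    table: pd.DataFrame  # per term + Residual + Total: df, SS, R2, F, p
    n_permutations: int
    scheme: str
    formula: list[str]

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def r2(self, term: str) -> float:
        return float(self.table.loc[term, "R2"])


def _subject_block_permutation(
    meta: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Sample permutation exchanging whole subjects, timepoints kept in place."""
    blocks = [np.flatnonzero(meta["subject"].to_numpy() == s) for s in pd.unique(meta["subject"])]
    sizes = {len(b) for b in blocks}
    if len(sizes) != 1:
        raise ValueError("subject-block permutation needs balanced subjects")
    order = rng.permutation(len(blocks))
    perm = np.empty(len(meta), dtype=int)
    for slot, src in zip(blocks, (blocks[i] for i in order)):
        perm[slot] = src
    return perm


def permanova(
    d: DistanceMatrix,
    design: pd.DataFrame,
    formula: list[str],
    n_perm: int | str = 999,
    scheme: str = "free",
    seed: int | np.random.Generator | None = None,
) -> PermanovaResult:
    """Sequential-terms PERMANOVA on a distance matrix.

    Parameters
    ----------
    d:
        Distance matrix; its ids must index ``design``.
    formula:
        Ordered term list, e.g. ``["group", "time", "group:time"]``.
        Interactions use ``:``; continuous columns enter as-is.
    n_perm:
        Number of random permutations, or ``"exact"`` to enumerate all
        n! sample permutations (free scheme, small n only); the exact p
        is then the fraction of permutations, identity included, with
        F at least the observed.
    scheme:
        ``"free"`` permutes samples freely (the common adonis usage);
        ``"subjects"`` permutes subjects as whole units so both
        timepoints travel together, respecting repeated measures.
    """
    ids = list(d.ids)
    if set(ids) - set(design.index):
        missing = sorted(set(ids) - set(design.index))
        raise ValueError(f"design rows missing for ids: {missing[:10]}")
    design = design.loc[ids]
    g = gower_center(np.asarray(d.data, dtype=float))
    projectors, residual, dfs = _sequential_projectors(design, formula)

    ss_total = float(np.trace(g))
    ss_terms = np.array([np.sum(p * g) for p in projectors])
    ss_res = float(np.sum(residual * g))
    df_res = int(round(np.trace(residual)))
    f_obs = (ss_terms / dfs) / (ss_res / df_res)

    def perm_f(perm: np.ndarray) -> np.ndarray:
        gp = g[np.ix_(perm, perm)]
        ss_p = np.array([np.sum(p * gp) for p in projectors])
        return (ss_p / dfs) / (np.sum(residual * gp) / df_res)

    if n_perm == "exact":
        # enumerate every sample permutation; the identity is included,
        # so the exact p already carries the add-one convention
        if scheme != "free":
            raise ValueError("exact enumeration is only supported for the free scheme")
        if len(ids) > 8:
            raise ValueError("exact enumeration is limited to n <= 8 samples")
        tol = 1e-9 * np.maximum(1.0, np.abs(f_obs))
        count = np.zeros(len(formula))
        n_draws = 0
        for perm in itertools.permutations(range(len(ids))):
            count += perm_f(np.array(perm)) >= f_obs - tol
            n_draws += 1
        p = count / n_draws
        n_perm_label = n_draws
    else:
        rng = (
            seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        )
        exceed = np.zeros(len(formula))
        for _ in range(n_perm):
            if scheme == "subjects":
                perm = _subject_block_permutation(design, rng)
            elif scheme == "free":
                perm = rng.permutation(len(ids))
            else:
                raise ValueError(f"unknown permutation scheme {scheme!r}")
            exceed += perm_f(perm) >= f_obs
        p = (1.0 + exceed) / (1.0 + n_perm)
        n_perm_label = n_perm

    rows = {
        term: (dfs[i], ss_terms[i], ss_terms[i] / ss_total, f_obs[i], p[i])
        for i, term in enumerate(formula)
    }
    rows["Residual"] = (df_res, ss_res, ss_res / ss_total, np.nan, np.nan)
    rows["Total"] = (len(ids) - 1, ss_total, 1.0, np.nan, np.nan)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["df", "SS", "R2", "F", "p"]
    )
    return PermanovaResult(table, n_perm_label, scheme, list(formula))


def interaction_permanova(
    d: DistanceMatrix,
    design: pd.DataFrame,
    n_perm: int = 999,
    scheme: str = "subjects",
    seed: int | np.random.Generator | None = None,
) -> PermanovaResult:
    """group + time + group:time PERMANOVA for a two-timepoint cohort.

    The interaction p answers whether compositional change over time
    differs between intervention arms.  Every subject must appear at
    both timepoints.
    """
    ids = list(d.ids)
    meta = design.loc[ids].copy()
    if "time" not in meta.columns:
        meta["time"] = meta["timepoint"]
    counts = meta.groupby("subject")["time"].nunique()
    incomplete = counts.index[counts < 2].tolist()
    if incomplete:
        raise ValueError(f"subject(s) lacking both timepoints: {incomplete[:10]}")
    return permanova(
        d, meta, ["group", "time", "group:time"], n_perm=n_perm, scheme=scheme, seed=seed
    )


def pairwise_permanova(
    d: DistanceMatrix,
    design: pd.DataFrame,
    n_perm: int = 999,
    scheme: str = "subjects",
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Leave-one-out interaction PERMANOVA on every group pair, BH-corrected."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups = list(pd.unique(design["group"]))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for pairwise contrasts")
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            pair = {groups[i], groups[j]}
            keep = [s for s in d.ids if design.loc[s, "group"] in pair]
            res = interaction_permanova(
                d.filter(keep), design.loc[keep], n_perm=n_perm, scheme=scheme, seed=rng
            )
            rows.append(
                {
                    "group_a": groups[i],
                    "group_b": groups[j],
                    "R2": res.r2("group:time"),
                    "p": res.p_value("group:time"),
                    "n_samples": len(keep),
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def variance_explained(
    d: DistanceMatrix,
    covariate: pd.Series,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> PermanovaResult:
    """R^2 and permutation p of one continuous covariate against d."""
    name = covariate.name or "covariate"
    design = covariate.to_frame(name)
    design[name] = design[name].astype(float)
    if design[name].isna().any():
        keep = design.index[design[name].notna()]
        d = d.filter([i for i in d.ids if i in set(keep)])
        design = design.loc[list(d.ids)]
    return permanova(d, design, [name], n_perm=n_perm, scheme="free", seed=seed)


def variance_explained_batch(
    d: DistanceMatrix,
    covariates: pd.DataFrame,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """variance_explained per column, BH correction across covariates."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for name in covariates.columns:
        res = variance_explained(d, covariates[name], n_perm=n_perm, seed=rng)
        rows.append({"covariate": name, "R2": res.r2(name), "p": res.p_value(name)})
    out = pd.DataFrame(rows).set_index("covariate")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------
# convergence test
# ---------------------------------------------------------------------

@dataclass
class ConvergenceResult:
    """Within- vs between-group dissimilarity contrast and its null."""

    table: pd.DataFrame  # per group: delta, within, between, p, null summary
    n_permutations: int
    stratum: str

    def delta(self, group: str) -> float:
        return float(self.table.loc[group, "delta"])

    def p_value(self, group: str) -> float:
        return float(self.table.loc[group, "p"])


def _group_deltas(dm: np.ndarray, z: np.ndarray) -> np.ndarray:
    """delta_g = mean between-group - mean within-group distance.

    ``z`` is an n x g 0/1 membership matrix (one column per group, or a
    batch of stacked permutations).  Vectorized through one D @ Z
    product per call.
    """
    n = dm.shape[0]
    n_g = z.sum(axis=0)
    dz = dm @ z
    within_sum = np.einsum("ng,ng->g", z, dz)  # counts each pair twice
    col_sum = dz.sum(axis=0)
    between_sum = col_sum - within_sum
    within_mean = within_sum / (n_g * (n_g - 1))
    between_mean = between_sum / (n_g * (n - n_g))
    return between_mean - within_mean


def convergence_test(
    d: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 100_000,
    stratum: str = "all",
    seed: int | np.random.Generator | None = None,
    chunk: int = 2_000,
) -> ConvergenceResult:
    """Test whether group members became compositionally similar.

    For each group the statistic is delta = mean between-group minus
    mean within-group dissimilarity; a large positive delta means the
    group's members resemble each other more than outsiders.  The null
    reassigns group labels at random (group sizes preserved); the
    one-sided p asks for delta at least as large as observed.
    """
    ids = list(d.ids)
    labels = groups.loc[ids].to_numpy()
    dm = np.asarray(d.data, dtype=float)
    names, inverse = np.unique(labels, return_inverse=True)
    sizes = np.bincount(inverse)
    if (sizes < 2).any():
        small = names[sizes < 2].tolist()
        raise ValueError(f"group(s) of size < 2: {small}")
    n, g = len(ids), len(names)

    z_obs = np.zeros((n, g))
    z_obs[np.arange(n), inverse] = 1.0
    obs = _group_deltas(dm, z_obs)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = np.zeros(g)
    null_sum = np.zeros(g)
    null_sq = np.zeros(g)
    null_q: list[np.ndarray] = []
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        z = np.zeros((n, g * b))
        for k in range(b):
            perm = rng.permutation(inverse)
            z[np.arange(n), g * k + perm] = 1.0
        deltas = _group_deltas(dm, z).reshape(b, g)
        exceed += (deltas >= obs).sum(axis=0)
        null_sum += deltas.sum(axis=0)
        null_sq += (deltas**2).sum(axis=0)
        null_q.append(deltas)
        done += b
    nulls = np.concatenate(null_q, axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    mean = null_sum / n_perm
    sd = np.sqrt(np.maximum(null_sq / n_perm - mean**2, 0.0))
    q025, q975 = np.quantile(nulls, [0.025, 0.975], axis=0)

    # recompute observed within/between means for reporting
    n_g = z_obs.sum(axis=0)
    dz = dm @ z_obs
    within = np.einsum("ng,ng->g", z_obs, dz) / (n_g * (n_g - 1))
    between = (dz.sum(axis=0) - np.einsum("ng,ng->g", z_obs, dz)) / (n_g * (n - n_g))

    table = pd.DataFrame(
        {
            "delta": obs,
            "within_mean": within,
            "between_mean": between,
            "p": p,
            "null_mean": mean,
            "null_sd": sd,
            "null_q025": q025,
            "null_q975": q975,
            "n": n_g.astype(int),
        },
        index=pd.Index(names, name="group"),
    )
    return ConvergenceResult(table, n_perm, stratum)
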