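"""Abundance-table algebra for two-timepoint intervention cohorts.

The central object is :class:`FeatureTable`, a samples x taxa matrix of
counts or relative abundances paired with per-sample metadata (subject,
intervention group, timepoint).  Operations cover relative-abundance
conversion, prevalence, the core / non-core partition, the abundance
filter applied before per-feature testing, per-subject log2 change
matrices, and biomarker percent change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: metadata columns every FeatureTable carries
META_COLS = ("subject", "group", "timepoint")
TIMEPOINTS = ("t0", "t6")


@dataclass
class FeatureTable:
    """Samples x taxa abundance matrix with sample metadata.

    Parameters
    ----------
    data:
        Non-negative matrix, index = sample ids, columns = taxon ids.
    meta:
        Per-sample metadata with columns ``subject``, ``group``,
        ``timepoint`` (values ``t0``/``t6``), indexed by sample id.
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dups}")
        if (self.data.to_numpy() < 0).any():
            bad = np.argwhere(self.data.to_numpy() < 0)[0]
            raise ValueError(
                "negative abundance at sample "
                f"{self.data.index[bad[0]]!r}, taxon {self.data.columns[bad[1]]!r}"
            )
        missing = [c for c in META_COLS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if not self.meta.index.equals(self.data.index):
            self.meta = self.meta.loc[self.data.index]

    # -- basic views --------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def taxon_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def is_relative(self, atol: float = 1e-6) -> bool:
        return bool(np.allclose(self.data.sum(axis=1).to_numpy(), 1.0, atol=atol))

    def select_taxa(self, taxa) -> "FeatureTable":
        return FeatureTable(self.data.loc[:, list(taxa)], self.meta.copy())

    def select_samples(self, samples) -> "FeatureTable":
        samples = list(samples)
        return FeatureTable(self.data.loc[samples], self.meta.loc[samples])

    def at_timepoint(self, timepoint: str) -> "FeatureTable":
        keep = self.meta.index[self.meta["timepoint"] == timepoint]
        return self.select_samples(keep)


@dataclass
class ChangeMatrix:
    """Subjects x taxa matrix of log2(t6 / t0) relative-abundance change."""

    values: pd.DataFrame  # index = subject ids, columns = taxon ids
    subject_meta: pd.DataFrame  # per-subject metadata (group)
    pseudocount: float
    dropped_subjects: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite entries in change matrix")

    @property
    def subject_ids(self) -> pd.Index:
        return self.values.index

    @property
    def taxon_ids(self) -> pd.Index:
        return self.values.columns

    def select_taxa(self, taxa) -> "ChangeMatrix":
        return ChangeMatrix(
            self.values.loc[:, list(taxa)],
            self.subject_meta.copy(),
            self.pseudocount,
            list(self.dropped_subjects),
        )


def to_relative(table: FeatureTable) -> FeatureTable:
    """Convert counts to relative abundances (rows sum to one).

    Idempotent on tables already in relative form.  A sample whose row
    sums to zero has no defined composition and is rejected by name.
    """
    sums = table.data.sum(axis=1)
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise ValueError(f"zero-sum sample(s), composition undefined: {zero}")
    return FeatureTable(table.data.div(sums, axis=0), table.meta.copy())


def prevalence(table: FeatureTable) -> pd.Series:
    """Fraction of samples in which each taxon is detected (value > 0)."""
    if table.n_samples == 0:
        raise ValueError("prevalence undefined for an empty table")
    return (table.data > 0).sum(axis=0) / table.n_samples


def split_core(
    table: FeatureTable, cutoff: float = 0.5
) -> tuple[FeatureTable, FeatureTable]:
    """Partition taxa into core (prevalence strictly > cutoff) and non-core.

    The boundary is strict: a taxon at exactly the cutoff lands in the
    non-core (rare, person-specific) fraction.
    """
    if not 0 < cutoff < 1:
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    prev = prevalence(table)
    core_taxa = prev.index[prev > cutoff]
    non_core_taxa = prev.index[~(prev > cutoff)]
    return table.select_taxa(core_taxa), table.select_taxa(non_core_taxa)


def abundance_filter(
    table: FeatureTable, min_rel: float = 1e-5, min_frac: float = 0.05
) -> FeatureTable:
    """Keep taxa at relative abundance >= ``min_rel`` in >= ``min_frac`` of samples.

    Both thresholds are inclusive.  Filtering is computed on the relative
    form but applied to the table as given, so counts stay counts.
    """
    rel = table if table.is_relative() else to_relative(table)
    hits = (rel.data.to_numpy() >= min_rel).mean(axis=0)
    keep = table.taxon_ids[hits >= min_frac]
    return table.select_taxa(keep)


def half_min_pseudocount(data: pd.DataFrame) -> float:
    """Half the smallest nonzero value in the matrix (scale-adaptive)."""
    vals = data.to_numpy()
    nz = vals[vals > 0]
    if nz.size == 0:
        raise ValueError("all-zero table: pseudocount undefined")
    return float(nz.min()) / 2.0


def log2_change(
    table: FeatureTable, pseudocount: float | str = "half-min"
) -> ChangeMatrix:
    """Per-subject log2((rel_t6 + eps) / (rel_t0 + eps)) change matrix.

    ``pseudocount`` is either ``"half-min"`` (half the smallest nonzero
    relative abundance in the table) or a fixed positive float.  Subjects
    missing one of the two timepoints are dropped and logged; a subject
    with duplicate samples at a timepoint is an error.
    """
    rel = table if table.is_relative() else to_relative(table)
    if pseudocount == "half-min":
        eps = half_min_pseudocount(rel.data)
    else:
        eps = float(pseudocount)
        if eps <= 0:
            raise ValueError("pseudocount must be positive")

    by_tp: dict[str, pd.DataFrame] = {}
    for tp in TIMEPOINTS:
        sub = rel.meta[rel.meta["timepoint"] == tp]
        if sub["subject"].duplicated().any():
            dup = sub.loc[sub["subject"].duplicated(), "subject"].tolist()
            raise ValueError(f"duplicate {tp} sample for subject(s): {dup}")
        frame = rel.data.loc[sub.index]
        frame.index = pd.Index(sub["subject"].to_numpy(), name="subject")
        by_tp[tp] = frame

    common = by_tp["t0"].index.intersection(by_tp["t6"].index)
    dropped = sorted(
        set(by_tp["t0"].index).symmetric_difference(by_tp["t6"].index)
    )
    if dropped:
        logger.info("dropping %d subject(s) missing a timepoint: %s", len(dropped), dropped)
    if len(common) == 0:
        raise ValueError("no subject has both timepoints")

    t0 = by_tp["t0"].loc[common]
    t6 = by_tp["t6"].loc[common]
    values = np.log2((t6 + eps) / (t0 + eps))

    meta = (
        rel.meta[rel.meta["subject"].isin(common)][["subject", "group"]]
        .drop_duplicates("subject")
        .set_index("subject")
        .loc[common]
    )
    return ChangeMatrix(values, meta, eps, dropped)


def percent_change(biomarkers: pd.DataFrame) -> pd.DataFrame:
    """100 * (t6 - t0) / t0 per subject and marker.

    ``biomarkers`` is long-form with columns ``subject``, ``marker``,
    ``t0``, ``t6``.  A zero baseline makes the ratio undefined; such
    entries come back as NaN (flagged missing) rather than +/-inf.
    Returns a subjects x markers wide frame.
    """
    required = {"subject", "marker", "t0", "t6"}
    missing = required - set(biomarkers.columns)
    if missing:
        raise ValueError(f"biomarker table missing columns: {sorted(missing)}")
    b = biomarkers.copy()
    zero = b["t0"] == 0
    if zero.any():
        logger.warning(
            "%d biomarker record(s) with zero baseline flagged missing", int(zero.sum())
        )
    pct = 100.0 * (b["t6"] - b["t0"]) / b["t0"].where(~zero)
    b["pct_change"] = pct
    return b.pivot(index="subject", columns="marker", values="pct_change")
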