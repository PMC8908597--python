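"""Reading and writing the pipeline's plain-text formats.

Counts are TSV (sample rows, taxon columns), trees Newick with branch
lengths, metadata / biomarkers / intake TSV, and the simulator truth
record JSON.  Readers validate ids and numeric content and report the
offending row/column by name.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .simulate import SyntheticCohort
from .tables import FeatureTable


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort as TSV/Newick/JSON; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "tree": out / "tree.nwk",
        "metadata": out / "metadata.tsv",
        "biomarkers": out / "biomarkers.tsv",
        "intake": out / "intake.tsv",
        "truth": out / "truth.json",
    }
    cohort.counts.data.to_csv(paths["counts"], sep="\t")
    cohort.tree.write(str(paths["tree"]))
    cohort.metadata.to_csv(paths["metadata"], sep="\t")
    cohort.biomarkers.to_csv(paths["biomarkers"], sep="\t", index=False)
    cohort.intake.to_csv(paths["intake"], sep="\t")
    truth = cohort.truth
    payload = {
        "core_taxa": truth.core_taxa,
        "non_core_taxa": truth.non_core_taxa,
        "responder_taxa": truth.responder_taxa,
        "responder_directions": truth.responder_directions,
        "mediator_taxa": truth.mediator_taxa,
        "outcome_effects": truth.outcome_effects,
        "groups": truth.groups.to_dict(),
        "adherence_score": truth.adherence_score.to_dict(),
    }
    paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths


def read_feature_table(counts_path: str | Path, metadata_path: str | Path) -> FeatureTable:
    """Load a counts TSV plus its sample metadata TSV into a FeatureTable."""
    data = pd.read_csv(counts_path, sep="\t", index_col=0)
    non_numeric = [c for c in data.columns if not np.issubdtype(data[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric count column(s): {non_numeric[:10]}")
    meta = read_metadata(metadata_path)
    missing = sorted(set(data.index) - set(meta.index))
    if missing:
        raise ValueError(f"samples without metadata: {missing[:10]}")
    return FeatureTable(data, meta.loc[data.index])


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    required = {"subject", "group", "timepoint"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing column(s): {sorted(missing)}")
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample id(s) in metadata: {dups[:10]}")
    return meta


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted Newick tree; every branch must carry a length."""
    try:
        tree = TreeNode.read(str(path))
    except Exception as exc:  # skbio raises several parse error types
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(
                f"branch without length (node {node.name!r}): UniFrac undefined"
            )
    return tree


def read_biomarkers(path: str | Path) -> pd.DataFrame:
    b = pd.read_csv(path, sep="\t")
    required = {"subject", "marker", "t0", "t6"}
    missing = required - set(b.columns)
    if missing:
        raise ValueError(f"biomarker table missing column(s): {sorted(missing)}")
    for col in ("t0", "t6"):
        if not np.issubdtype(b[col].dtype, np.number):
            bad = b.index[pd.to_numeric(b[col], errors="coerce").isna()].tolist()
            raise ValueError(f"non-numeric {col} at row(s) {bad[:10]}")
    return b


def read_intake(path: str | Path) -> pd.DataFrame:
    from .adherence import COMPONENTS, ENERGY_COL

    intake = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in COMPONENTS + (ENERGY_COL,) if c not in intake.columns]
    if missing:
        raise ValueError(f"intake table missing column(s): {missing}")
    return intake


def tree_to_newick(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf)
    return buf.getvalue()
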