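import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from dietshift.simulate import CohortSpec, generate_cohort
from dietshift.tables import FeatureTable


def make_table(values, sample_ids=None, taxon_ids=None, meta=None) -> FeatureTable:
    values = np.asarray(values, dtype=float)
    n, t = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    taxon_ids = taxon_ids or [f"T{i:04d}" for i in range(t)]
    data = pd.DataFrame(values, index=sample_ids, columns=taxon_ids)
    if meta is None:
        meta = pd.DataFrame(
            {
                "subject": [f"subj{i}" for i in range(n)],
                "group": ["A"] * n,
                "timepoint": ["t0"] * n,
            },
            index=data.index,
        )
    return FeatureTable(data, meta)


def paired_table(t0_rows, t6_rows, groups=None) -> FeatureTable:
    """Two-timepoint table: one t0 and one t6 sample per subject."""
    t0_rows, t6_rows = np.asarray(t0_rows, float), np.asarray(t6_rows, float)
    n = t0_rows.shape[0]
    groups = groups or ["A"] * n
    values = np.vstack([t0_rows, t6_rows])
    ids = [f"subj{i}_t0" for i in range(n)] + [f"subj{i}_t6" for i in range(n)]
    meta = pd.DataFrame(
        {
            "subject": [f"subj{i}" for i in range(n)] * 2,
            "group": list(groups) * 2,
            "timepoint": ["t0"] * n + ["t6"] * n,
        },
        index=ids,
    )
    data = pd.DataFrame(
        values, index=ids, columns=[f"T{i:04d}" for i in range(values.shape[1])]
    )
    return FeatureTable(data, meta)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort with all planted effects switched on."""
    spec = CohortSpec(
        n_subjects_per_arm=12,
        n_taxa=60,
        n_core_taxa=15,
        library_size_mean=5000,
        convergence_strength=0.6,
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture
def cherry_tree():
    """Two-leaf tree with unit branch lengths."""
    t = TreeNode.read(["(T0000:1.0,T0001:1.0):0.0;"])
    t.length = None
    return t
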