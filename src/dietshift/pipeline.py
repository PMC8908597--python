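"""End-to-end orchestration: from input files to a stage-by-stage report.

Stage order follows the analysis narrative: community composition change
(UniFrac, PCoA, group x time PERMANOVA, pairwise contrasts) -> core /
non-core stratification and convergence at month six -> per-subject
log2 change matrix -> variance explained by biomarker / adherence
changes -> per-feature differential change and trend tests -> adherence
score -> mediation (summary and high-dimensional).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adherence as adh
from . import associations as assoc
from . import community as comm
from . import distances as dist
from . import io as dio
from . import tables
from .simulate import GROUP_RANK

logger = logging.getLogger(__name__)
__version__ = "0.1.0"


def stage_rng(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible sub-stream of the pipeline seed."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(name.encode())])
    )


@dataclass
class PipelineConfig:
    counts: str
    tree: str
    metadata: str
    biomarkers: str
    intake: str
    out_dir: str = "dietshift_out"
    prevalence_cutoff: float = 0.5
    min_rel_abundance: float = 1e-5
    min_sample_fraction: float = 0.05
    fdr_target: float = 0.25
    n_perm_permanova: int = 999
    n_perm_convergence: int = 10_000
    n_sim_mediation: int = 1000
    permutation_scheme: str = "subjects"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.prevalence_cutoff < 1:
            raise ValueError("prevalence_cutoff must be in (0, 1)")
        if not 0 < self.fdr_target <= 1:
            raise ValueError("fdr_target must be in (0, 1]")
        if min(self.n_perm_permanova, self.n_perm_convergence) < 1:
            raise ValueError("permutation counts must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def digest(self) -> str:
        # out_dir is where the report lands, not part of its identity
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class AnalysisReport:
    results: dict
    provenance: dict
    out_dir: Path
    tables: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"provenance": self.provenance, "results": self.results},
            indent=1,
            sort_keys=True,
            default=float,
        )


def _permanova_dict(res: comm.PermanovaResult) -> dict:
    return {
        "table": {
            term: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
            for term, row in res.table.to_dict(orient="index").items()
        },
        "n_permutations": res.n_permutations,
        "scheme": res.scheme,
    }


def _convergence_dict(res: comm.ConvergenceResult) -> dict:
    return {
        "table": res.table.to_dict(orient="index"),
        "n_permutations": res.n_permutations,
        "stratum": res.stratum,
    }


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    config.validate()
    t_start = time.monotonic()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    saved: dict = {}

    def stage(name):
        logger.info("stage %-24s %.1fs", name, time.monotonic() - t_start)

    # -- load ----------------------------------------------------------
    table = dio.read_feature_table(config.counts, config.metadata)
    tree = dio.read_tree(config.tree)
    biomarkers = dio.read_biomarkers(config.biomarkers)
    intake = dio.read_intake(config.intake)
    unresolved = sorted(set(biomarkers["subject"]) - set(table.meta["subject"]))
    if unresolved:
        raise ValueError(f"biomarker subjects not in metadata: {unresolved[:10]}")
    stage("load")

    # -- filter + community tests -------------------------------------
    filtered = tables.abundance_filter(
        table, config.min_rel_abundance, config.min_sample_fraction
    )
    rel = tables.to_relative(filtered)
    dm_all = dist.weighted_unifrac(rel, tree)
    ord_all = dist.pcoa(dm_all, k=2)
    inter = comm.interaction_permanova(
        dm_all,
        rel.meta,
        n_perm=config.n_perm_permanova,
        scheme=config.permutation_scheme,
        seed=stage_rng(config.seed, "interaction"),
    )
    pairs = comm.pairwise_permanova(
        dm_all,
        rel.meta,
        n_perm=config.n_perm_permanova,
        scheme=config.permutation_scheme,
        seed=stage_rng(config.seed, "pairwise"),
    )
    results["interaction_permanova"] = _permanova_dict(inter)
    results["pairwise_permanova"] = pairs.to_dict(orient="records")
    saved["pcoa_all"] = ord_all.coordinates
    stage("community")

    # -- core / non-core convergence at month six ---------------------
    core, non_core = tables.split_core(filtered, config.prevalence_cutoff)
    results["core_split"] = {
        "n_core": int(core.data.shape[1]),
        "n_non_core": int(non_core.data.shape[1]),
        "cutoff": config.prevalence_cutoff,
    }
    results["convergence"] = {}
    strata = {"all": filtered, "core": core, "non_core": non_core}
    groups_by_sample = filtered.meta["group"]
    for label, sub in strata.items():
        if sub.data.shape[1] < 2:
            continue
        t6 = sub.at_timepoint("t6")
        rel6 = tables.to_relative(t6)
        sheared = dist.shear_tree(tree, sub.taxon_ids)
        dm6 = dist.weighted_unifrac(rel6, sheared)
        conv = comm.convergence_test(
            dm6,
            groups_by_sample,
            n_perm=config.n_perm_convergence,
            stratum=label,
            seed=stage_rng(config.seed, f"convergence-{label}"),
        )
        results["convergence"][label] = _convergence_dict(conv)
    stage("convergence")

    # -- change matrix + variance explained ---------------------------
    change = tables.log2_change(rel)
    dm_change = dist.euclidean_distances(change)
    ord_change = dist.pcoa(dm_change, k=2)
    pct = tables.percent_change(biomarkers)
    score = adh.greenmed_score(intake).scores.astype(float)
    covs = pct.copy()
    covs["greenmed_score"] = score
    covs = covs.loc[covs.index.intersection(change.subject_ids)]
    var_exp = comm.variance_explained_batch(
        dm_change.filter(list(covs.index)),
        covs,
        n_perm=config.n_perm_permanova,
        seed=stage_rng(config.seed, "variance-explained"),
    )
    results["variance_explained"] = var_exp.to_dict(orient="index")
    saved["pcoa_change"] = ord_change.coordinates
    stage("variance-explained")

    # -- per-feature tests ---------------------------------------------
    diff = assoc.differential_change(filtered)
    results["differential_change"] = {
        "n_features": int(len(diff.table)),
        "n_hits": int(len(diff.hits(config.fdr_target))),
        "hits": diff.hits(config.fdr_target).tolist(),
        "model": diff.model,
    }
    saved["differential_change"] = diff.table

    rank = change.subject_meta["group"].map(GROUP_RANK)
    trend_bio = assoc.trend_test_batch(pct.loc[pct.index.intersection(rank.index)], rank)
    results["biomarker_trends"] = trend_bio.to_dict(orient="index")
    saved["taxon_biomarker_map"] = assoc.taxon_biomarker_map(
        change.values, pct.loc[pct.index.intersection(change.subject_ids)]
    )
    stage("per-feature")

    # -- adherence ------------------------------------------------------
    results["adherence"] = {
        "mean_score_by_group": score.groupby(change.subject_meta["group"]).mean().to_dict(),
        "trend": dict(
            zip(("tau_b", "p"), assoc.trend_test(score.loc[rank.index], rank))
        ),
    }
    stage("adherence")

    # -- mediation ------------------------------------------------------
    from . import mediation as med

    pc1 = ord_change.pc1
    common = score.index.intersection(pc1.index)
    results["mediation_summary"] = {}
    for marker in pct.columns:
        y = pct.loc[common, marker]
        ok = y.notna()
        if ok.sum() < 10:
            continue
        res = med.mediate_summary(
            score.loc[common][ok],
            pc1.loc[common][ok],
            y[ok],
            n_sim=config.n_sim_mediation,
            seed=stage_rng(config.seed, f"mediation-{marker}"),
            labels={"exposure": "greenmed_score", "mediator": "PCo1", "outcome": marker},
        )
        results["mediation_summary"][marker] = {
            "acme": res.acme,
            "ade": res.ade,
            "total": res.total,
            "proportion_mediated": res.proportion_mediated,
            "pm_stable": res.pm_stable,
            "ci": {k: list(v) for k, v in res.ci.items()},
        }
    first_marker = pct.columns[0]
    y0 = pct.loc[common, first_marker]
    ok = y0.notna()
    try:
        hd = med.mediate_highdim(
            score.loc[common][ok],
            change.values.loc[common][ok],
            y0[ok],
            seed=stage_rng(config.seed, "mediation-highdim"),
        )
        results["mediation_highdim"] = {
            "outcome": first_marker,
            "n_screened": hd.n_screened,
            "selected": hd.table.index.tolist(),
            "significant": hd.significant(config.fdr_target).tolist(),
            "total_effect": hd.total_effect,
        }
        saved["mediation_highdim"] = hd.table
    except ValueError as exc:
        results["mediation_highdim"] = {"skipped": str(exc)}
    stage("mediation")

    provenance = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "n_samples": int(table.n_samples),
        "n_taxa_input": int(table.data.shape[1]),
        "n_taxa_filtered": int(filtered.data.shape[1]),
    }  # no timings here: the report must be bit-identical across reruns
    report = AnalysisReport(results, provenance, out, saved)

    (out / "report.json").write_text(report.to_json())
    for name, frame in saved.items():
        frame.to_csv(out / f"{name}.tsv", sep="\t")
    logger.info("pipeline finished in %.1fs", time.monotonic() - t_start)
    return report
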