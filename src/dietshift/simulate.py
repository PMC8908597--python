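"""Synthetic 3-arm, two-timepoint intervention cohort with planted effects.

The generator emulates the structure of a dietary-intervention
microbiome trial: three arms of increasing intervention intensity
(healthy dietary guidance HDG, Mediterranean MED, green Mediterranean
GreenMED), stool profiles at baseline (t0) and month six (t6), a
food-frequency intake table, and biomarker measurements at both
timepoints.  Counts are Dirichlet-multinomial around per-subject latent
compositions, with a core/rare prevalence structure, an arm-graded
compositional shift planted mostly in rare taxa, optional convergence
of the strongest arm's rare fraction toward a shared attractor, and
biomarker changes partially mediated by a designated mediating taxon
set.  Every planted effect is recorded in a truth object so downstream
tests can verify recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import adherence as adh
from .tables import FeatureTable

GROUPS = ("HDG", "MED", "GreenMED")
#: arm rank used by trend tests (graded intervention intensity)
GROUP_RANK = {"HDG": 1, "MED": 2, "GreenMED": 3}

# per-component baseline grams/day and arm log-effects (HDG, MED, GreenMED);
# green components rise stepwise across arms, meats fall
_INTAKE_PROFILE = {
    "walnuts": (15.0, (0.0, 0.8, 0.8), +1),
    "vegetables": (300.0, (0.0, 0.3, 0.4), +1),
    "legumes": (30.0, (0.0, 0.4, 0.5), +1),
    "fruits": (200.0, (0.0, 0.2, 0.2), +1),
    "fish": (40.0, (0.0, 0.3, 0.3), +1),
    "green_tea": (5.0, (0.0, 0.3, 1.2), +1),
    "mankai": (2.0, (0.0, 0.2, 1.5), +1),
    "red_meat": (80.0, (0.0, -0.5, -1.0), -1),
    "processed_meat": (40.0, (0.0, -0.6, -1.2), -1),
}


@dataclass
class CohortSpec:
    """Fully specifies one synthetic cohort; same spec + seed => same cohort."""

    n_subjects_per_arm: int = 30
    n_taxa: int = 200
    n_core_taxa: int = 40
    library_size_mean: int = 20_000
    overdispersion: float = 300.0  # Dirichlet concentration: higher = tighter
    shift_magnitudes: tuple = (0.0, 0.5, 1.0)  # natural-log arm effects
    n_responder_taxa: int = 20
    responder_core_fraction: float = 0.25
    convergence_strength: float = 0.0  # pull of GreenMED rare taxa to attractor
    mediation_effects: dict = field(
        default_factory=lambda: {"weight": (1.0, 1.2, 0.5)}
    )  # outcome -> (a, b, c_prime); planted proportion mediated = a*b/(a*b+c')
    n_mediator_taxa: int = 3
    mediator_response: float = 1.2  # log-units of taxon shift per unit mediator path
    null_biomarkers: tuple = ("hdl_cholesterol", "crp")
    noise_sd: float = 1.0  # biological noise on the mediating paths
    outcome_noise_sd: float = 0.5  # biomarker percent-change measurement noise
    occupancy: float = 0.4  # per-subject presence probability of rare taxa
    core_mass: float = 0.7  # expected relative-abundance share of core taxa
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects_per_arm < 1 or self.n_taxa < 2 or self.library_size_mean < 1:
            raise ValueError("sizes must be positive (n_taxa >= 2)")
        if not 0 < self.n_core_taxa <= self.n_taxa:
            raise ValueError("need 0 < n_core_taxa <= n_taxa")
        if not 0.0 <= self.convergence_strength <= 1.0:
            raise ValueError("convergence_strength must lie in [0, 1]")
        if self.overdispersion <= 0 or self.noise_sd < 0:
            raise ValueError("overdispersion must be positive, noise_sd non-negative")
        if len(self.shift_magnitudes) != len(GROUPS):
            raise ValueError("need one shift magnitude per arm")
        if not all(np.isfinite(self.shift_magnitudes)):
            raise ValueError("shift magnitudes must be finite")
        if self.n_responder_taxa + self.n_mediator_taxa > self.n_taxa:
            raise ValueError("responders + mediators exceed n_taxa")


@dataclass
class CohortTruth:
    """Record of everything planted, for recovery testing."""

    core_taxa: list
    non_core_taxa: list
    responder_taxa: list
    responder_directions: dict  # taxon -> +1 / -1
    mediator_taxa: list
    attractor: pd.Series  # shared rare-taxon composition (sums to 1)
    groups: pd.Series  # subject -> arm
    adherence_score: pd.Series  # Green-MED score computed from the intake table
    mediator_latent: pd.DataFrame  # subjects x mediating paths, one per mediator taxon
    outcome_effects: dict  # outcome -> dict(a, b, c_prime, prop_mediated)
    latent_t0: pd.DataFrame  # subjects x taxa latent compositions
    latent_t6: pd.DataFrame


@dataclass
class SyntheticCohort:
    counts: FeatureTable  # both timepoints stacked; meta carries subject/group/timepoint
    tree: TreeNode
    biomarkers: pd.DataFrame  # long: subject, marker, t0, t6
    intake: pd.DataFrame  # subjects x 9 components + energy_kcal
    truth: CohortTruth

    @property
    def metadata(self) -> pd.DataFrame:
        return self.counts.meta


def taxon_labels(n_taxa: int) -> list[str]:
    return [f"T{i:04d}" for i in range(n_taxa)]


def generate_tree(n_taxa: int, seed: int) -> TreeNode:
    """Random rooted bifurcating tree by sequential random join.

    Leaves are labeled T0000..; every branch gets a strictly positive
    length.  The same seed yields an identical Newick string.
    """
    if n_taxa < 2:
        raise ValueError("a tree needs at least 2 leaves")
    rng = np.random.default_rng(seed)
    nodes = []
    for name in taxon_labels(n_taxa):
        tip = TreeNode(name=name)
        tip.length = float(rng.exponential(0.5) + 0.05)
        nodes.append(tip)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(children=[left, right])
        parent.length = float(rng.exponential(0.5) + 0.05)
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def _dirichlet_multinomial(
    latent: np.ndarray, concentration: float, library: int, rng: np.random.Generator
) -> np.ndarray:
    """One sample's counts around a latent composition."""
    counts = np.zeros(latent.shape[0], dtype=int)
    support = latent > 0
    alpha = concentration * latent[support]
    theta = rng.dirichlet(alpha)
    counts[support] = rng.multinomial(library, theta)
    return counts


def _generate_intake(
    spec: CohortSpec, subjects: list[str], arm_idx: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """FFQ-style intake with stepwise arm medians and a subject propensity."""
    n = len(subjects)
    propensity = rng.normal(0.0, 0.5, size=n)  # latent within-arm adherence
    cols = {}
    for comp, (base, arm_eff, sign) in _INTAKE_PROFILE.items():
        eff = np.array(arm_eff)[arm_idx]
        noise = rng.normal(0.0, 0.4, size=n)
        cols[comp] = base * np.exp(eff + 0.3 * sign * propensity + noise)
    cols[adh.ENERGY_COL] = np.clip(rng.normal(2500.0, 250.0, size=n), 1200.0, None)
    return pd.DataFrame(cols, index=pd.Index(subjects, name="subject"))


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw one complete synthetic cohort from a spec.

    Randomness flows through named sub-streams spawned from the spec
    seed, so components are independently reproducible.
    """
    spec.validate()
    streams = np.random.SeedSequence(spec.seed).spawn(6)
    rng_tree, rng_comp, rng_counts, rng_intake, rng_med, rng_bio = (
        np.random.default_rng(s) for s in streams
    )

    taxa = taxon_labels(spec.n_taxa)
    core = taxa[: spec.n_core_taxa]
    non_core = taxa[spec.n_core_taxa :]
    tree_seed = int(np.random.SeedSequence(spec.seed).generate_state(1)[0] % 2**31)
    tree = generate_tree(spec.n_taxa, tree_seed)

    n_subj = spec.n_subjects_per_arm * len(GROUPS)
    subjects = [f"S{i:03d}" for i in range(n_subj)]
    arm_idx = np.repeat(np.arange(len(GROUPS)), spec.n_subjects_per_arm)
    groups = pd.Series(
        [GROUPS[a] for a in arm_idx], index=pd.Index(subjects, name="subject"), name="group"
    )

    # -- baseline mean composition with a core / rare split -----------
    n_core, n_rare = len(core), len(non_core)
    m = np.empty(spec.n_taxa)
    core_w = rng_comp.lognormal(0.0, 1.0, size=n_core)
    m[:n_core] = spec.core_mass * core_w / core_w.sum()
    if n_rare:
        rare_w = rng_comp.lognormal(0.0, 1.0, size=n_rare)
        m[n_core:] = (1.0 - spec.core_mass) * rare_w / rare_w.sum()
    else:
        m[:n_core] /= m[:n_core].sum()

    # -- planted responder and mediator taxa --------------------------
    n_resp_core = int(round(spec.n_responder_taxa * spec.responder_core_fraction))
    n_resp_core = min(n_resp_core, n_core)
    n_resp_rare = min(spec.n_responder_taxa - n_resp_core, n_rare)
    resp_core = rng_comp.choice(n_core, size=n_resp_core, replace=False)
    resp_rare = n_core + rng_comp.choice(n_rare, size=n_resp_rare, replace=False) if n_resp_rare else np.array([], dtype=int)
    responder_idx = np.concatenate([resp_core, resp_rare]).astype(int)
    directions = rng_comp.choice([-1.0, 1.0], size=len(responder_idx))
    remaining_core = np.setdiff1d(np.arange(n_core), responder_idx)
    if len(remaining_core) < spec.n_mediator_taxa:
        raise ValueError("not enough core taxa left for the mediator set")
    # mediators sit in the upper-middle of the core abundance range:
    # abundant enough that their log2 change is quantified with little
    # counting noise, not so dominant that multiplicative shifts
    # saturate under compositional closure
    by_abundance = remaining_core[np.argsort(m[remaining_core])[::-1]]
    start = len(by_abundance) // 3
    if start + spec.n_mediator_taxa > len(by_abundance):
        start = len(by_abundance) - spec.n_mediator_taxa
    mediator_idx = by_abundance[start : start + spec.n_mediator_taxa]

    # shared attractor for the rare fraction (convergence target)
    if n_rare:
        attr_w = m[n_core:] * rng_comp.lognormal(0.0, 0.5, size=n_rare)
        attractor = attr_w / attr_w.sum()
    else:
        attractor = np.array([])

    # -- intake, adherence, mediator latent ---------------------------
    intake = _generate_intake(spec, subjects, arm_idx, rng_intake)
    score = adh.greenmed_score(intake).scores.astype(float)
    # exposure enters the planted models standardized; the proportion
    # mediated a*b/(a*b+c') is invariant to rescaling the exposure
    a_std = ((score - score.mean()) / score.std()).to_numpy()

    planted = {
        k: v for k, v in spec.mediation_effects.items() if any(x != 0 for x in v)
    }
    a_slopes = [v[0] for v in planted.values()]
    a_shared = a_slopes[0] if a_slopes else 0.0
    # one independent mediating path per designated taxon: M_k = a*A + eps_k.
    # The outcome takes b * mean_k(M_k), so the summed mediated effect stays
    # the analytic a*b while the paths remain separable per taxon.
    k_med = spec.n_mediator_taxa
    mediator_latent = pd.DataFrame(
        a_shared * a_std[:, None]
        + rng_med.normal(0.0, spec.noise_sd, (n_subj, k_med)),
        index=subjects,
        columns=[f"path{i}" for i in range(k_med)],
    )
    # alternate taxon shift directions so the mediating trio's total mass
    # does not co-swing with adherence (limits compositional closure)
    mediator_dirs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(k_med)])

    # -- latent compositions ------------------------------------------
    jitter = rng_comp.lognormal(0.0, 0.3, size=(n_subj, spec.n_taxa))
    mask = np.ones((n_subj, spec.n_taxa))
    if n_rare:
        mask[:, n_core:] = rng_comp.random((n_subj, n_rare)) < spec.occupancy
        # keep at least one rare taxon per subject so strata stay defined
        empty = mask[:, n_core:].sum(axis=1) == 0
        if empty.any():
            fill = rng_comp.integers(0, n_rare, size=int(empty.sum()))
            mask[np.flatnonzero(empty), n_core + fill] = 1.0
    latent_t0 = m * jitter * mask
    latent_t0 /= latent_t0.sum(axis=1, keepdims=True)

    shifts = np.asarray(spec.shift_magnitudes, dtype=float)[arm_idx]
    latent_t6 = latent_t0.copy()
    latent_t6[:, responder_idx] *= np.exp(np.outer(shifts, directions))
    if planted:  # no planted mediation -> taxa stay untouched under the null
        latent_t6[:, mediator_idx] *= np.exp(
            spec.mediator_response * mediator_latent.to_numpy() * mediator_dirs
        )

    if n_rare and spec.convergence_strength > 0:
        lam = spec.convergence_strength
        green = arm_idx == len(GROUPS) - 1
        rare_part = latent_t6[green][:, n_core:]
        rare_mass = rare_part.sum(axis=1, keepdims=True)
        rare_rel = np.divide(
            rare_part, rare_mass, out=np.zeros_like(rare_part), where=rare_mass > 0
        )
        mixed = (1.0 - lam) * rare_rel + lam * attractor
        latent_t6[np.ix_(green, np.arange(n_core, spec.n_taxa))] = mixed * rare_mass
    latent_t6 /= latent_t6.sum(axis=1, keepdims=True)

    # -- counts --------------------------------------------------------
    rows, ids, meta_rows = [], [], []
    for tp, latent in (("t0", latent_t0), ("t6", latent_t6)):
        for i, subj in enumerate(subjects):
            lib = max(int(rng_counts.poisson(spec.library_size_mean)), 1)
            rows.append(
                _dirichlet_multinomial(latent[i], spec.overdispersion, lib, rng_counts)
            )
            ids.append(f"{subj}_{tp}")
            meta_rows.append((subj, groups[subj], tp))
    counts = pd.DataFrame(rows, index=pd.Index(ids, name="sample"), columns=taxa)
    meta = pd.DataFrame(
        meta_rows, index=counts.index, columns=["subject", "group", "timepoint"]
    )
    table = FeatureTable(counts, meta)

    # -- biomarkers -----------------------------------------------------
    baseline_means = {"weight": (90.0, 12.0), "waist": (105.0, 10.0), "frs": (12.0, 4.0)}
    bio_rows = []
    outcome_truth = {}
    for name, (a, b, c_prime) in spec.mediation_effects.items():
        mu, sd = baseline_means.get(name, (100.0, 10.0))
        t0 = rng_bio.normal(mu, sd, size=n_subj)
        pct = (
            -3.0
            + b * mediator_latent.to_numpy().mean(axis=1)
            + c_prime * a_std
            + rng_bio.normal(0.0, spec.outcome_noise_sd, n_subj)
        )
        denom = a * b + c_prime
        outcome_truth[name] = {
            "a": a,
            "b": b,
            "c_prime": c_prime,
            "prop_mediated": (a * b / denom) if denom != 0 else float("nan"),
        }
        for subj, v0, p in zip(subjects, t0, pct):
            bio_rows.append((subj, name, v0, v0 * (1 + p / 100.0)))
    for name in spec.null_biomarkers:
        t0 = rng_bio.normal(100.0, 10.0, size=n_subj)
        pct = rng_bio.normal(0.0, 3.0, size=n_subj)
        for subj, v0, p in zip(subjects, t0, pct):
            bio_rows.append((subj, name, v0, v0 * (1 + p / 100.0)))
    biomarkers = pd.DataFrame(bio_rows, columns=["subject", "marker", "t0", "t6"])

    truth = CohortTruth(
        core_taxa=core,
        non_core_taxa=non_core,
        responder_taxa=[taxa[i] for i in responder_idx],
        responder_directions={taxa[i]: float(d) for i, d in zip(responder_idx, directions)},
        mediator_taxa=[taxa[i] for i in mediator_idx],
        attractor=pd.Series(attractor, index=non_core, name="attractor"),
        groups=groups,
        adherence_score=score,
        mediator_latent=mediator_latent,
        outcome_effects=outcome_truth,
        latent_t0=pd.DataFrame(latent_t0, index=subjects, columns=taxa),
        latent_t6=pd.DataFrame(latent_t6, index=subjects, columns=taxa),
    )
    return SyntheticCohort(table, tree, biomarkers, intake, truth)


def null_spec(seed: int, **overrides) -> CohortSpec:
    """A pure-null cohort spec: no shifts, no convergence, no mediation."""
    params = dict(
        shift_magnitudes=(0.0, 0.0, 0.0),
        convergence_strength=0.0,
        mediation_effects={"weight": (0.0, 0.0, 0.0)},
        seed=seed,
    )
    params.update(overrides)
    return CohortSpec(**params)
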