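"""Synthetic streamline-count cohorts with plantable group effects.

Patient diffusion-MRI connectomes cannot be shared, so every downstream
stage is exercised on simulated cohorts that reproduce the statistical
structure the inference assumes:

* a single symmetric log-normal "anatomy" template per cohort (heavy-tailed
  weights on a connected random graph) perturbed by independent
  multiplicative noise per direction per subject — heavy-tailed, asymmetric
  streamline counts without modeling tractography;
* waytotals distinct from row sums (a per-region seeding factor drawn once),
  so waytotal normalization is genuinely exercised;
* a group effect planted by uniformly scaling one node's incident counts in
  the affected group, with per-subject scales calibrated by bisection so the
  realized Cohen's d of that node's density-integrated degree matches a
  target;
* epilepsy durations coupled to the effect node's realized centrality
  through a Gaussian copula on ranks, targeting a chosen Spearman rho with
  right-skewed (log-normal) marginals;
* Table-1-like clinical marginals (sex, TLE laterality, MRI-lesion coding,
  onset age) and a logistic surgical-outcome model in which the probability
  of complete seizure freedom (ILAE class 1) decreases with effect-node
  centrality.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit
from scipy.stats import norm, rankdata

from .cohort import ClinicalRecord, RawConnectome, write_clinical, write_connectome
from .metrics import integrated_degree
from .parcellation import default_labels
from .processing import process_connectome, sorted_edges, target_edge_count
from .stats import cohens_d, spearman

_MAX_TEMPLATE_RETRIES = 50
_MAX_SUBJECT_RETRIES = 10


def derive_seed(base: int, *tags) -> int:
    """Stable per-purpose seed below 2**31 derived from one global seed."""
    digest = hashlib.blake2b(
        repr((int(base),) + tags).encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def _is_connected_pairs(ii: np.ndarray, jj: np.ndarray, n: int) -> bool:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    graph = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    return connected_components(graph, directed=False)[0] == 1


def _connected_at_density(weights: np.ndarray, density: float) -> bool:
    """Is the proportional-threshold graph at ``density`` connected?"""
    n = weights.shape[0]
    ei, ej = sorted_edges(weights)
    k = min(target_edge_count(n, density), len(ei))
    return _is_connected_pairs(ei[:k], ej[:k], n)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults emulate the study cohort the pipeline is designed for: an
    82-node connectome, 43 drug-resistant vs 19 drug-sensitive subjects
    (plus 2 with unknown resistance status who contribute only to the
    surgical subanalysis), a standardized degree effect of d = 0.85 at the
    left piriform cortex and a duration-centrality rank correlation of
    0.39 — the effect sizes the real analysis reported, used here as
    calibration values for the generator.
    """

    n_nodes: int = 82
    n_group_a: int = 43  # drug-resistant
    n_group_b: int = 19  # drug-sensitive
    n_unlabeled: int = 2  # resistance status unknown (surgery-only subjects)
    effect_node: str = "lh_piriform"
    degree_effect_d: float = 0.85
    duration_rho: float = 0.39
    base_density: float = 0.6
    weight_scale: float = 5000.0
    noise_cv: float = 0.3
    seed: int = 0
    n_missing_duration: int = 1
    operated_fraction: float = 0.42
    outcome_intercept: float = 0.0
    outcome_slope: float = 1.5
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.n_group_a + self.n_group_b < 4:
            raise ValueError("need at least 4 labeled subjects")
        if self.n_nodes < 3:
            raise ValueError("need at least 3 nodes")
        if not 0.4 < self.base_density <= 1.0:
            raise ValueError(
                "base_density must be in (0.4, 1] so networks stay connected "
                "at the 20% proportional threshold"
            )
        if not -1.0 <= self.duration_rho <= 1.0:
            raise ValueError("duration_rho must be in [-1, 1]")
        if self.noise_cv < 0 or self.weight_scale <= 0:
            raise ValueError("noise_cv must be >= 0 and weight_scale > 0")
        labels = self.labels or default_labels(self.n_nodes)
        if len(labels) != self.n_nodes or len(set(labels)) != self.n_nodes:
            raise ValueError("labels must be n_nodes unique names")
        if self.effect_node not in labels:
            raise ValueError(f"effect_node {self.effect_node!r} not in labels")
        object.__setattr__(self, "labels", tuple(labels))

    @property
    def n_subjects(self) -> int:
        return self.n_group_a + self.n_group_b + self.n_unlabeled


@dataclass(frozen=True)
class SyntheticCohort:
    connectomes: list[RawConnectome]
    clinical: list[ClinicalRecord]
    truth: dict

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for c in self.connectomes:
            write_connectome(c, directory)
        write_clinical(self.clinical, directory / "clinical.csv")
        (directory / "truth.json").write_text(
            json.dumps(self.truth, indent=2, sort_keys=True) + "\n"
        )


# ---------------------------------------------------------------------------
# base connectome generation


def _draw_template(
    n_nodes: int, base_density: float, weight_scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric latent weight template on a connected random graph."""
    m = n_nodes * (n_nodes - 1) // 2
    iu, ju = np.triu_indices(n_nodes, k=1)
    for _ in range(_MAX_TEMPLATE_RETRIES):
        present = rng.random(m) < base_density
        if present.sum() >= n_nodes - 1 and _is_connected_pairs(
            iu[present], ju[present], n_nodes
        ):
            break
    else:
        raise RuntimeError(
            f"latent graph disconnected after {_MAX_TEMPLATE_RETRIES} draws "
            f"(base_density={base_density})"
        )
    sigma = 1.5  # heavy-tailed streamline-count spread (log scale)
    w = np.zeros(m)
    w[present] = weight_scale * rng.lognormal(
        mean=-sigma**2 / 2, sigma=sigma, size=int(present.sum())
    )
    template = np.zeros((n_nodes, n_nodes))
    template[iu, ju] = w
    template[ju, iu] = w
    return template


def _draw_subject(
    subject_id: str,
    labels: tuple[str, ...],
    template: np.ndarray,
    seed_factor: np.ndarray,
    noise_cv: float,
    rng: np.random.Generator,
) -> RawConnectome:
    """Directional multiplicative noise on the template, rounded to counts.

    Present template edges never round to zero (at least one streamline is
    what made the connection observable), so subject-level connection
    density equals the template's. Connectivity at the 20% threshold is
    enforced by bounded regeneration of the noise.
    """
    n = template.shape[0]
    sig = np.sqrt(np.log1p(noise_cv**2))
    present = template > 0
    # below n-1 edges no graph is connected: the 20% guard is meaningful
    # only when the threshold retains at least a spanning tree
    check_connectivity = target_edge_count(n, 0.20) >= n - 1
    for _ in range(_MAX_SUBJECT_RETRIES):
        noise = rng.lognormal(mean=-sig**2 / 2, sigma=sig, size=(n, n))
        counts = _round_half_away(template * noise)
        counts[present & (counts < 1)] = 1
        counts[~present] = 0
        np.fill_diagonal(counts, 0)
        waytotals = seed_factor * counts.sum(axis=1)
        conn = RawConnectome(
            subject_id=subject_id,
            labels=labels,
            counts=counts.astype(np.int64),
            waytotals=waytotals,
        )
        if not check_connectivity or _connected_at_density(
            process_connectome(conn).weights, 0.20
        ):
            return conn
    raise RuntimeError(
        f"{subject_id}: network fragmented at 20% density after "
        f"{_MAX_SUBJECT_RETRIES} regenerations"
    )


def generate_base_connectome(
    n_nodes: int,
    base_density: float,
    weight_scale: float,
    seed: int,
    noise_cv: float = 0.3,
    labels: tuple[str, ...] | None = None,
    subject_id: str = "sub-000",
) -> RawConnectome:
    """One asymmetric streamline-count connectome (template + noise)."""
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    if not 0 < base_density <= 1:
        raise ValueError("base_density must be in (0, 1]")
    if weight_scale <= 0:
        raise ValueError("weight_scale must be positive")
    labels = tuple(labels) if labels is not None else default_labels(n_nodes)
    rng = np.random.default_rng(seed)
    template = _draw_template(n_nodes, base_density, weight_scale, rng)
    seed_factor = rng.uniform(1.2, 2.5, size=n_nodes)
    return _draw_subject(subject_id, labels, template, seed_factor, noise_cv, rng)


def plant_centrality_effect(
    connectome: RawConnectome, node: str, scale: float
) -> RawConnectome:
    """Multiply one node's incident streamline counts by ``scale``.

    Raises both degree and betweenness of the node after proportional
    thresholding without rewiring the graph. The affected row's waytotal is
    rescaled by the realized row-sum ratio, so its per-seed normalization is
    preserved; the effect therefore enters through the afferent (column)
    direction of the symmetrized weights.
    """
    if node not in connectome.labels:
        raise ValueError(f"unknown node label {node!r}")
    if scale <= 0:
        raise ValueError("scale must be positive")
    idx = connectome.labels.index(node)
    counts = connectome.counts.astype(float).copy()
    counts[idx, :] = _round_half_away(counts[idx, :] * scale)
    counts[:, idx] = _round_half_away(counts[:, idx] * scale)
    counts[idx, idx] = 0
    waytotals = connectome.waytotals.copy()
    old_rs = connectome.counts[idx].sum()
    new_rs = counts[idx].sum()
    if old_rs > 0:
        waytotals[idx] = waytotals[idx] * (new_rs / old_rs)
    return RawConnectome(
        subject_id=connectome.subject_id,
        labels=connectome.labels,
        counts=counts.astype(np.int64),
        waytotals=waytotals,
    )


def split_node(
    connectome: RawConnectome,
    node: str,
    new_labels: tuple[str, str],
    fraction: float = 0.5,
) -> RawConnectome:
    """Divide one node into two, sharing its streamline counts.

    Emulates re-parcellation into a finer atlas: the first half keeps
    ``fraction`` of every incident count (rounded), the second the
    remainder, and the waytotal is split in the same proportion. Used to
    check that a planted effect survives a node split.
    """
    if node not in connectome.labels:
        raise ValueError(f"unknown node label {node!r}")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    idx = connectome.labels.index(node)
    n = connectome.n_nodes
    old = connectome.counts
    new = np.zeros((n + 1, n + 1), dtype=np.int64)
    keep = [i for i in range(n) if i != idx]
    new[: n - 1, : n - 1] = old[np.ix_(keep, keep)]
    row_a = _round_half_away(old[idx, keep] * fraction).astype(np.int64)
    col_a = _round_half_away(old[keep, idx] * fraction).astype(np.int64)
    new[n - 1, : n - 1] = row_a
    new[: n - 1, n - 1] = col_a
    new[n, : n - 1] = old[idx, keep] - row_a
    new[: n - 1, n] = old[keep, idx] - col_a
    labels = tuple(connectome.labels[i] for i in keep) + tuple(new_labels)
    way = connectome.waytotals
    waytotals = np.concatenate(
        [way[keep], [way[idx] * fraction, way[idx] * (1 - fraction)]]
    )
    return RawConnectome(
        subject_id=connectome.subject_id,
        labels=labels,
        counts=new,
        waytotals=waytotals,
    )


# ---------------------------------------------------------------------------
# cohort generation


def _integrated_effect(conn: RawConnectome, node_idx: int) -> float:
    return float(integrated_degree(process_connectome(conn))[node_idx])


def _calibrate_scales(
    bases_a: list[RawConnectome],
    deg_b: np.ndarray,
    node: str,
    node_idx: int,
    target_d: float,
    u: np.ndarray,
    tol: float = 0.02,
    max_iter: int = 40,
) -> tuple[np.ndarray, float]:
    """Find gamma so that scales s_i(gamma) realize the target Cohen's d.

    s_i = 1 + gamma * u_i for gamma >= 0 and 1 / (1 - gamma * u_i) for
    gamma < 0; realized d is monotone in gamma for fixed noise, so plain
    bisection converges.
    """

    def scales_for(gamma: float) -> np.ndarray:
        if gamma >= 0:
            return 1.0 + gamma * u
        return 1.0 / (1.0 - gamma * u)

    def realized(gamma: float) -> float:
        s = scales_for(gamma)
        deg_a = np.array(
            [
                _integrated_effect(plant_centrality_effect(c, node, si), node_idx)
                for c, si in zip(bases_a, s)
            ]
        )
        return cohens_d(deg_a, deg_b)

    lo, hi = 0.0, 0.0
    f0 = realized(0.0)
    if abs(f0 - target_d) <= tol:
        return scales_for(0.0), f0
    if f0 < target_d:
        hi = 0.25
        while realized(hi) < target_d:
            hi *= 2.0
            if hi > 64:
                raise RuntimeError("effect calibration failed: target d unreachable")
    else:
        lo = -0.25
        while realized(lo) > target_d:
            lo *= 2.0
            if lo < -64:
                raise RuntimeError("effect calibration failed: target d unreachable")
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        d_mid = realized(mid)
        if abs(d_mid - target_d) <= tol:
            lo = hi = mid
            break
        if d_mid < target_d:
            lo = mid
        else:
            hi = mid
    gamma = (lo + hi) / 2.0
    return scales_for(gamma), realized(gamma)


def _copula_durations(
    centrality: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Durations (years) rank-coupled to centrality via a Gaussian copula.

    The latent Pearson correlation is chosen as 2*sin(pi*rho/6) so that the
    copula's population Spearman correlation equals ``rho``; marginals are
    log-normal (median ~14 years, right-skewed), applied by quantile
    transform of the coupled ranks.
    """
    n = len(centrality)
    if rho != 0 and np.ptp(centrality) == 0:
        raise ValueError(
            "infeasible spec: nonzero duration_rho with zero centrality variance"
        )
    z_c = norm.ppf((rankdata(centrality) - 0.5) / n)
    rho_p = 2.0 * np.sin(np.pi * rho / 6.0)
    if abs(rho) >= 1.0:
        z_d = np.sign(rho) * z_c
    else:
        z_d = rho_p * z_c + np.sqrt(1 - rho_p**2) * rng.standard_normal(n)
    quantiles = (rankdata(z_d) - 0.5) / n
    return np.exp(np.log(14.0) + 0.6 * norm.ppf(quantiles))


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Full synthetic cohort: connectomes, clinical table, planted truth."""
    rng = np.random.default_rng(spec.seed)
    labels = spec.labels
    node_idx = labels.index(spec.effect_node)
    n_total = spec.n_subjects

    template = _draw_template(spec.n_nodes, spec.base_density, spec.weight_scale, rng)
    seed_factor = rng.uniform(1.2, 2.5, size=spec.n_nodes)  # per-region, shared
    ids = [f"sub-{i:03d}" for i in range(n_total)]
    bases = [
        _draw_subject(sid, labels, template, seed_factor, spec.noise_cv, rng)
        for sid in ids
    ]
    group_a = list(range(spec.n_group_a))
    group_b = list(range(spec.n_group_a, spec.n_group_a + spec.n_group_b))
    unlabeled = list(range(spec.n_group_a + spec.n_group_b, n_total))

    deg_b = np.array([_integrated_effect(bases[i], node_idx) for i in group_b])
    u = rng.lognormal(mean=0.0, sigma=0.35, size=spec.n_group_a)
    if spec.degree_effect_d != 0.0:
        scales, realized_d = _calibrate_scales(
            [bases[i] for i in group_a],
            deg_b,
            spec.effect_node,
            node_idx,
            spec.degree_effect_d,
            u,
        )
    else:
        scales = np.ones(spec.n_group_a)
        deg_a0 = np.array([_integrated_effect(bases[i], node_idx) for i in group_a])
        realized_d = cohens_d(deg_a0, deg_b)

    connectomes = list(bases)
    for i, s in zip(group_a, scales):
        connectomes[i] = plant_centrality_effect(bases[i], spec.effect_node, float(s))

    effect_centrality = np.array(
        [_integrated_effect(c, node_idx) for c in connectomes]
    )

    durations = _copula_durations(effect_centrality, spec.duration_rho, rng)
    labeled = group_a + group_b
    realized_rho, _ = spearman(durations[labeled], effect_centrality[labeled])
    missing_duration: set[int] = set()
    if spec.n_missing_duration > 0 and len(labeled) > spec.n_missing_duration:
        missing_duration = set(
            rng.choice(labeled, size=spec.n_missing_duration, replace=False).tolist()
        )

    sexes = np.where(rng.random(n_total) < 0.581, "female", "male")
    laterality = rng.choice(
        ["left", "right", "bilateral", "unclear"],
        size=n_total,
        p=[0.597, 0.322, 0.065, 0.016],
    )
    lesion = (rng.random(n_total) < 0.25).astype(int)
    onset = np.clip(18.0 + 9.0 * rng.standard_normal(n_total), 1.0, None)
    age_at_mri = onset + durations + rng.uniform(0.0, 2.0, n_total)

    operated = rng.random(n_total) < spec.operated_fraction
    operated[unlabeled] = True  # surgery-only subjects
    followup = rng.uniform(0.5, 8.0, n_total)
    op_idx = np.flatnonzero(operated)
    ilae = np.full(n_total, -1)
    if len(op_idx) >= 2 and np.ptp(effect_centrality[op_idx]) > 0:
        z = (
            effect_centrality[op_idx] - effect_centrality[op_idx].mean()
        ) / effect_centrality[op_idx].std()
        p_free = expit(spec.outcome_intercept - spec.outcome_slope * z)
        seizure_free = rng.random(len(op_idx)) < p_free
        ilae[op_idx] = np.where(
            seizure_free, 1, rng.integers(2, 6, size=len(op_idx))
        )
    elif len(op_idx) > 0:
        ilae[op_idx] = rng.integers(1, 6, size=len(op_idx))

    clinical = []
    for i, sid in enumerate(ids):
        if i in group_a:
            resistant: bool | None = True
        elif i in group_b:
            resistant = False
        else:
            resistant = None
        clinical.append(
            ClinicalRecord(
                subject_id=sid,
                drug_resistant=resistant,
                duration_years=None if i in missing_duration else float(durations[i]),
                age_at_mri=float(age_at_mri[i]),
                sex=str(sexes[i]),
                laterality=str(laterality[i]),
                lesion_dummy=int(lesion[i]),
                onset_age=float(onset[i]),
                operated=bool(operated[i]),
                ilae_class=int(ilae[i]) if operated[i] else None,
                followup_years=float(followup[i]) if operated[i] else None,
            )
        )

    truth = {
        "effect_node": spec.effect_node,
        "target_degree_effect_d": spec.degree_effect_d,
        "realized_degree_effect_d": float(realized_d),
        "target_duration_rho": spec.duration_rho,
        "realized_duration_rho": float(realized_rho),
        "scales": {ids[i]: float(s) for i, s in zip(group_a, scales)},
        "seed": spec.seed,
    }
    return SyntheticCohort(connectomes=connectomes, clinical=clinical, truth=truth)
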