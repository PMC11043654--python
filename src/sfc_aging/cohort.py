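"""Synthetic three-group aging cohort with planted caudate-network effects.

The generator emulates the study conditions every downstream stage needs:

* a phantom atlas on a coarse (5 mm) voxel grid -- a central ventricle slab,
  bilateral caudate blocks whose medial wall touches the slab, and the
  remaining volume tiled into 6-connected cortical/subcortical parcels;
* per-subject node time series drawn from a stationary zero-mean multivariate
  Gaussian whose correlation structure is a community factor model (caudate,
  DMN, frontoparietal, sensorimotor, visual, limbic, subcortical), with
  group-dependent additive deltas on named community pairs planting the
  aging-related loss of direct caudate-cortex connectivity;
* regional morphometry (cortical thickness, normalized GM volumes) with a
  planted medial-vs-lateral atrophy gradient in the elderly group.

Medial/lateral differential *direct* connectivity is planted through an
idiosyncratic-pairing mechanism: a subset of voxels in each MCR-designated
parcel tracks the private (non-shared) signal components of a few medial
caudate voxels, and LCR-designated parcels pair with lateral voxels the same
way.  Partner windows are pairwise disjoint, so targets are uncorrelated
with each other and with everything except their own partners: the planted
medial-vs-lateral difference lives almost entirely in one-step walk counts.
A block factor model cannot do this (positive
semidefiniteness forces strongly seed-correlated targets to be strongly
intercorrelated, which leaks large walk-count differences into steps >= 2).

Group sizes default to 52 / 42 / 58 (young / middle-aged / elderly) with
demographic covariates (age bands, sex ratios, education means) typical of
a three-group aging study.  One RNG stream is derived per subject
from (master seed, subject index) so cohort subsets are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .inference import RegionSets
from .io import (
    LabelEntry,
    LabelVolume,
    NodeTable,
    RegionalTable,
    SubjectRecord,
    build_node_table,
    write_regional_table,
    write_volume,
)
from .sfc import partition_caudate

__all__ = [
    "ConfigError",
    "CapacityError",
    "CohortConfig",
    "SyntheticSubject",
    "Cohort",
    "build_phantom_atlas",
    "build_plan",
    "simulate_timeseries",
    "simulate_morphometry",
    "morphometry_baseline",
    "make_records",
    "generate_cohort",
]

logger = logging.getLogger(__name__)

ORDINARY_COMMUNITIES = ("dmn", "frontoparietal", "sensorimotor", "visual", "limbic", "subcortical")
#: communities whose member parcels are planted as MCR / LCR direct targets
TARGET_COMMUNITIES = ("mcr_target", "lcr_target")

# demographic anchors per group: (education mean, education sd, age low, age high)
_DEMOGRAPHICS = {
    "young": (15.6, 3.0, 21.0, 35.0),
    "middle": (13.6, 3.3, 36.0, 59.9),
    "elderly": (11.4, 3.8, 60.0, 85.0),
}
_FEMALE_FRACTION = {"young": 0.46, "middle": 0.64, "elderly": 0.67}


class ConfigError(ValueError):
    """The cohort configuration is internally inconsistent."""


class CapacityError(ValueError):
    """The voxel grid is too small to host the requested phantom structures."""


def _default_within_r() -> dict[str, float]:
    d = {c: 0.5 for c in ("caudate",) + ORDINARY_COMMUNITIES}
    d["subcortical"] = 0.4
    return d


def _default_seed_community_r() -> dict[str, float]:
    return {"dmn": 0.35, "frontoparietal": 0.35}


def _default_aging_deltas() -> dict[str, dict[tuple[str, str], float]]:
    return {
        "middle": {
            ("caudate", "dmn"): -0.15,
            ("caudate", "frontoparietal"): -0.15,
            ("caudate", "sensorimotor"): +0.15,
        },
        "elderly": {
            ("caudate", "dmn"): -0.25,
            ("caudate", "frontoparietal"): -0.25,
            ("caudate", "sensorimotor"): +0.20,
        },
    }


def _default_atrophy() -> dict[str, dict[str, float]]:
    return {
        "middle": {"MCR": -0.4, "LCR": -0.4, "rest": -0.4},
        "elderly": {"MCR": -0.8, "LCR": -0.4, "rest": -0.6},
    }


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults are the study conditions."""

    n_per_group: tuple[int, int, int] = (52, 42, 58)
    grid_dims: tuple[int, int, int] = (12, 12, 12)
    n_parcels: int = 20
    n_timepoints: int = 150
    seed: int = 0
    voxel_size_mm: tuple[float, float, float] = (5.0, 5.0, 5.0)
    community_spec: dict[str, str] | None = None  # parcel name -> community
    within_r: dict[str, float] = field(default_factory=_default_within_r)
    between_r: float = 0.10
    seed_community_r: dict[str, float] = field(default_factory=_default_seed_community_r)
    pair_r: float = 0.35
    n_pairs_per_target: int = 3
    target_frac: float = 0.1
    n_mcr_parcels: int = 3
    n_lcr_parcels: int = 3
    aging_edge_deltas: dict[str, dict[tuple[str, str], float]] = field(default_factory=_default_aging_deltas)
    atrophy_spec: dict[str, dict[str, float]] = field(default_factory=_default_atrophy)
    region_effect_sd: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 3 or any(n < 0 for n in self.n_per_group):
            raise ConfigError(f"n_per_group must be three non-negative counts, got {self.n_per_group}")
        if self.n_timepoints < 30:
            raise ConfigError(f"n_timepoints must be >= 30 for estimable correlations, got {self.n_timepoints}")
        for c, w in self.within_r.items():
            if not -1 < w < 1:
                raise ConfigError(f"within-community correlation for {c!r} must lie in (-1, 1), got {w}")
        rho_c = self.within_r.get("caudate", 0.5)
        if self.n_pairs_per_target < 1:
            raise ConfigError("n_pairs_per_target must be >= 1")
        if not 0 <= self.n_pairs_per_target * self.pair_r**2 < 1 - rho_c:
            raise ConfigError(
                f"pairing infeasible: n_pairs_per_target * pair_r^2 = "
                f"{self.n_pairs_per_target * self.pair_r ** 2:.3f} must be < 1 - within_r[caudate] "
                f"= {1 - rho_c:.3f} -- a unit-variance target cannot track more idiosyncratic "
                "seed variance than exists"
            )
        if not 0 < self.target_frac <= 1:
            raise ConfigError(f"target_frac must lie in (0, 1], got {self.target_frac}")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["aging_edge_deltas"] = {
            g: {"|".join(k): v for k, v in deltas.items()} for g, deltas in self.aging_edge_deltas.items()
        }
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_jsonable(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        for key in ("n_per_group", "grid_dims", "voxel_size_mm"):
            if key in d:
                d[key] = tuple(d[key])
        if "aging_edge_deltas" in d:
            d["aging_edge_deltas"] = {
                g: {tuple(k.split("|")) if isinstance(k, str) else tuple(k): v for k, v in deltas.items()}
                for g, deltas in d["aging_edge_deltas"].items()
            }
        return cls(**d)


@dataclass
class SyntheticSubject:
    record: SubjectRecord
    timeseries: np.ndarray | None = None


# ---------------------------------------------------------------------------
# phantom atlas

def _tile_box(box: tuple[int, int, int, int, int, int], n: int) -> list[tuple[int, int, int, int, int, int]]:
    """Recursively bisect a voxel box into n sub-boxes of near-equal volume."""
    if n == 1:
        return [box]
    x0, x1, y0, y1, z0, z1 = box
    ext = [x1 - x0, y1 - y0, z1 - z0]
    axis = int(np.argmax(ext))
    n1 = n // 2
    length = ext[axis]
    cut = max(1, min(length - 1, round(length * n1 / n)))
    if length < 2:
        raise CapacityError("grid too small: a parcel box cannot be split further (limiting structure: parcel)")
    lo = list(box)
    hi = list(box)
    lo[2 * axis + 1] = lo[2 * axis] + cut
    hi[2 * axis] = lo[2 * axis + 1]
    return _tile_box(tuple(lo), n1) + _tile_box(tuple(hi), n - n1)


PARCEL_LABEL_START = 10


def build_phantom_atlas(
    grid_dims: tuple[int, int, int],
    n_parcels: int = 20,
    seed: int = 0,
    n_subcortical: int | None = None,
    voxel_size_mm: tuple[float, float, float] = (5.0, 5.0, 5.0),
) -> LabelVolume:
    """Construct the phantom label volume the seed-partition rule operates on.

    A one-voxel ventricle slab spans the central sagittal plane; two-voxel
    deep caudate blocks sit against it on either side (so their ventricle-
    facing layer is the medial caudate); the hemispheres beyond the caudate
    layers are tiled into 6-connected rectangular parcels, the last
    ``n_subcortical`` of which are classed subcortical.
    """
    nx, ny, nz = grid_dims
    if n_parcels < 2:
        raise CapacityError("need at least 2 parcels (one per hemisphere)")
    cx = nx // 2
    if cx - 2 < 1 or nx - (cx + 3) < 1:
        raise CapacityError(
            f"grid x-dimension {nx} too small to host ventricle slab + caudate blocks + parcels "
            "(limiting structure: caudate)"
        )
    y0, y1 = ny // 4, ny - ny // 4
    z0, z1 = nz // 4, nz - nz // 4
    if y1 <= y0 or z1 <= z0:
        raise CapacityError(
            f"grid in-plane dims {(ny, nz)} too small for the caudate block (limiting structure: caudate)"
        )
    if n_subcortical is None:
        n_subcortical = max(1, round(0.15 * n_parcels))
    if n_subcortical >= n_parcels:
        raise CapacityError("n_subcortical must be smaller than n_parcels")

    labels = np.zeros(grid_dims, dtype=np.int32)
    labels[cx, :, :] = 1  # ventricle
    labels[cx - 2 : cx, y0:y1, z0:z1] = 2  # caudate_left
    labels[cx + 1 : cx + 3, y0:y1, z0:z1] = 3  # caudate_right

    left_box = (0, cx - 2, 0, ny, 0, nz)
    right_box = (cx + 3, nx, 0, ny, 0, nz)
    vol_l = (cx - 2) * ny * nz
    vol_r = (nx - cx - 3) * ny * nz
    n_left = int(np.clip(round(n_parcels * vol_l / (vol_l + vol_r)), 1, n_parcels - 1))
    boxes = _tile_box(left_box, n_left) + _tile_box(right_box, n_parcels - n_left)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_parcels)
    dictionary = {
        1: LabelEntry("ventricle", "ventricle"),
        2: LabelEntry("caudate_left", "caudate_left"),
        3: LabelEntry("caudate_right", "caudate_right"),
    }
    n_cortical = n_parcels - n_subcortical
    for rank, box_idx in enumerate(order):
        label = PARCEL_LABEL_START + rank
        x0b, x1b, y0b, y1b, z0b, z1b = boxes[box_idx]
        labels[x0b:x1b, y0b:y1b, z0b:z1b] = label
        if rank < n_cortical:
            dictionary[label] = LabelEntry(f"ctx_parcel_{rank + 1:02d}", "cortical_parcel")
        else:
            dictionary[label] = LabelEntry(f"subctx_parcel_{rank - n_cortical + 1:02d}", "subcortical_parcel")
    return LabelVolume(labels, dictionary, voxel_size_mm)


# ---------------------------------------------------------------------------
# community plan and time-series model

@dataclass
class CohortPlan:
    """Precomputed node-level recipe shared by every simulated subject."""

    node_table: NodeTable
    node_community: np.ndarray  # community name per node ("caudate" nodes split below)
    medial_nodes: np.ndarray
    lateral_nodes: np.ndarray
    pair_partners: dict[int, np.ndarray]  # target node -> its caudate partner nodes
    communities: list[str]  # factor communities in matrix order
    parcel_community: dict[str, str]
    mcr_parcels: list[str]
    lcr_parcels: list[str]


def default_community_spec(atlas: LabelVolume, config: CohortConfig) -> dict[str, str]:
    """Assign each parcel a community: planted targets first, then round-robin."""
    cortical = atlas.region_names("cortical_parcel")
    subcortical = atlas.region_names("subcortical_parcel")
    n_target = config.n_mcr_parcels + config.n_lcr_parcels
    if n_target >= len(cortical):
        raise ConfigError(
            f"{n_target} target parcels requested but only {len(cortical)} cortical parcels exist"
        )
    spec: dict[str, str] = {}
    for i, name in enumerate(cortical):
        if i < config.n_mcr_parcels:
            spec[name] = "mcr_target"
        elif i < n_target:
            spec[name] = "lcr_target"
        else:
            spec[name] = ORDINARY_COMMUNITIES[(i - n_target) % (len(ORDINARY_COMMUNITIES) - 1)]
    for name in subcortical:
        spec[name] = "subcortical"
    return spec


def build_plan(atlas: LabelVolume, config: CohortConfig) -> CohortPlan:
    node_table = build_node_table(atlas)
    spec = config.community_spec or default_community_spec(atlas, config)
    known = set(ORDINARY_COMMUNITIES) | set(TARGET_COMMUNITIES)
    bad = {c for c in spec.values() if c not in known}
    if bad:
        raise ConfigError(f"unknown community name(s) in community_spec: {sorted(bad)}")
    name_by_label = {l: e.name for l, e in atlas.dictionary.items()}
    node_community = np.empty(node_table.n_nodes, dtype=object)
    for i, label in enumerate(node_table.labels):
        entry = atlas.dictionary[int(label)]
        if entry.label_class in ("caudate_left", "caudate_right"):
            node_community[i] = "caudate"
        else:
            if entry.name not in spec:
                raise ConfigError(f"parcel {entry.name!r} missing from community_spec")
            node_community[i] = spec[entry.name]
    medial, lateral = partition_caudate(atlas, 6, node_table)

    # Within each target parcel, only ceil(target_frac * size) voxels become
    # paired targets; each tracks q seed voxels through a window DISJOINT from
    # every other target's window (a seed voxel serves at most one target).
    # Disjointness keeps targets pairwise uncorrelated: shared partners would
    # correlate targets with each other, and those target-target edges would
    # carry the seed asymmetry into length-2 walks -- the planted difference
    # must live on direct seed-target edges only.
    q = config.n_pairs_per_target
    pair_partners: dict[int, np.ndarray] = {}
    seeds_of = {"mcr_target": medial.nodes, "lcr_target": lateral.nodes}
    offsets = {"mcr_target": 0, "lcr_target": 0}
    filler = ORDINARY_COMMUNITIES[:-1]  # ordinary cortical communities
    for label in sorted(atlas.dictionary):
        entry = atlas.dictionary[label]
        tc = spec.get(entry.name)
        if tc not in TARGET_COMMUNITIES:
            continue
        nodes = node_table.nodes_with_label(label)
        n_t = int(np.ceil(config.target_frac * nodes.size))
        sel = nodes[np.unique(np.round(np.linspace(0, nodes.size - 1, n_t)).astype(int))]
        seeds = seeds_of[tc]
        for node in sel:
            off = offsets[tc]
            if off + q > len(seeds):
                raise ConfigError(
                    f"pairing capacity exceeded for {tc}: {len(seeds)} seed voxels support "
                    f"at most {len(seeds) // q} disjoint partner windows of size {q}; reduce "
                    "target_frac or n_pairs_per_target, or enlarge the caudate"
                )
            pair_partners[int(node)] = seeds[off : off + q]
            offsets[tc] = off + q
        rest = np.setdiff1d(nodes, sel)
        for j, node in enumerate(rest):
            node_community[node] = filler[j % len(filler)]
        node_community[sel] = tc

    communities = ["caudate", *ORDINARY_COMMUNITIES]
    mcr_parcels = sorted(name for name, c in spec.items() if c == "mcr_target")
    lcr_parcels = sorted(name for name, c in spec.items() if c == "lcr_target")
    return CohortPlan(
        node_table, node_community, medial.nodes, lateral.nodes, pair_partners, communities, spec,
        mcr_parcels, lcr_parcels,
    )


def factor_covariance(config: CohortConfig, group: str, communities: list[str]) -> np.ndarray:
    """Community factor covariance: Var(u_c) = within_r[c], Cov = pair targets + deltas.

    Slight indefiniteness (min eigenvalue > -0.05) is repaired by eigenvalue
    clipping; anything worse raises, reporting the most negative eigenvalue.
    """
    k = len(communities)
    psi = np.full((k, k), config.between_r)
    for i, c in enumerate(communities):
        psi[i, i] = config.within_r.get(c, 0.5)
    if "caudate" in communities:
        ic = communities.index("caudate")
        for c, r in config.seed_community_r.items():
            if c in communities:
                j = communities.index(c)
                psi[ic, j] = psi[j, ic] = r
    for (a, b), delta in config.aging_edge_deltas.get(group, {}).items():
        if a in communities and b in communities:
            i, j = communities.index(a), communities.index(b)
            psi[i, j] += delta
            if i != j:
                psi[j, i] += delta
    eigvals = np.linalg.eigvalsh(psi)
    if eigvals[0] < -0.05:
        raise ConfigError(
            f"community correlation targets are not positive semidefinite "
            f"(most negative eigenvalue {eigvals[0]:.4f})"
        )
    if eigvals[0] < 0:
        w, v = np.linalg.eigh(psi)
        d = np.diag(psi).copy()
        psi = (v * np.clip(w, 0, None)) @ v.T
        # restore the target within-community variances after clipping
        scale = np.sqrt(d / np.clip(np.diag(psi), 1e-12, None))
        psi = psi * np.outer(scale, scale)
        logger.info("projected community covariance to PSD (clipped eigenvalue %.4f)", eigvals[0])
    return psi


def simulate_timeseries(
    atlas: LabelVolume,
    config: CohortConfig,
    group: str,
    rng: np.random.Generator,
    plan: CohortPlan | None = None,
) -> np.ndarray:
    """One subject's node x time matrix with the group's target correlations.

    Draws are i.i.d. in time from a zero-mean, unit-variance multivariate
    normal: x_i(t) = u_{c(i)}(t) + sqrt(1 - rho_c) e_i(t) for community
    nodes, and paired-target voxels track the idiosyncratic component of
    their caudate partner so that corr(target, partner) = pair_r exactly.
    """
    if plan is None:
        plan = build_plan(atlas, config)
    psi = factor_covariance(config, group, plan.communities)
    chol = np.linalg.cholesky(psi + 1e-12 * np.eye(len(plan.communities)))
    T = config.n_timepoints
    n = plan.node_table.n_nodes
    u = rng.standard_normal((T, len(plan.communities))) @ chol.T  # factors per timepoint

    x = np.empty((n, T))
    comm_index = {c: i for i, c in enumerate(plan.communities)}
    rho = {c: config.within_r.get(c, 0.5) for c in plan.communities}

    # caudate voxels first: their idiosyncratic parts are reused by paired targets
    caud_nodes = np.flatnonzero(plan.node_community == "caudate")
    rho_c = rho["caudate"]
    e_caud = rng.standard_normal((len(caud_nodes), T)) * np.sqrt(1 - rho_c)
    x[caud_nodes] = u[:, comm_index["caudate"]][None, :] + e_caud
    idio_of = {int(node): e_caud[k] for k, node in enumerate(caud_nodes)}

    for c in ORDINARY_COMMUNITIES:
        nodes = np.flatnonzero(plan.node_community == c)
        if nodes.size == 0:
            continue
        x[nodes] = u[:, comm_index[c]][None, :] + rng.standard_normal((nodes.size, T)) * np.sqrt(1 - rho[c])

    # per-partner loading beta on the partner's *unit-variance* idiosyncratic
    # component gives corr(target, partner) = beta * sqrt(1 - rho_c) = pair_r
    beta = config.pair_r / np.sqrt(1 - rho_c)
    resid_sd = np.sqrt(1 - config.n_pairs_per_target * beta**2)
    unit_idio = {k: v / np.sqrt(1 - rho_c) for k, v in idio_of.items()}
    for community in TARGET_COMMUNITIES:
        nodes = np.flatnonzero(plan.node_community == community)
        for node in nodes:
            partners = plan.pair_partners[int(node)]
            tracked = sum(unit_idio[int(p)] for p in partners)
            x[node] = beta * tracked + resid_sd * rng.standard_normal(T)

    sd = x.std(axis=1)
    if np.any(sd == 0):
        raise ConfigError("degenerate configuration produced constant node series")
    return x


# ---------------------------------------------------------------------------
# morphometry

def morphometry_baseline(
    config: CohortConfig, regions: list[str], measure_kind: str
) -> tuple[pd.Series, pd.Series]:
    """Deterministic per-region young-baseline mean and SD (from the master seed)."""
    rng = np.random.default_rng([config.seed, 7])
    if measure_kind == "thickness_mm":
        mu = rng.uniform(2.0, 3.2, size=len(regions))
        sd = rng.uniform(0.12, 0.22, size=len(regions))
    else:
        mu = rng.uniform(1500.0, 8000.0, size=len(regions))
        sd = mu * rng.uniform(0.08, 0.15, size=len(regions))
    return pd.Series(mu, index=regions), pd.Series(sd, index=regions)


def simulate_morphometry(
    config: CohortConfig,
    group: str,
    region_sets: RegionSets,
    rng: np.random.Generator,
    records: list[SubjectRecord],
    measure_kind: str = "thickness_mm",
    baseline: tuple[pd.Series, pd.Series] | None = None,
) -> RegionalTable:
    """Regional measures for one group with the planted atrophy gradient.

    value = mu_region + (shift(group, set) + region_effect + subject_noise) * sd_region,
    where shift comes from ``atrophy_spec`` (z-units relative to young), the
    region effect ~ N(0, region_effect_sd) is drawn once per (cohort, group,
    region), and subject noise ~ N(0, noise_sd).  Non-positive thickness is
    resampled (truncation) and logged.
    """
    regions = region_sets.all_regions
    unknown = [s for shifts in config.atrophy_spec.values() for s in shifts if s not in ("MCR", "LCR", "rest")]
    if unknown:
        raise ConfigError(f"atrophy_spec names unknown region set(s): {sorted(set(unknown))}")
    if baseline is None:
        baseline = morphometry_baseline(config, regions, measure_kind)
    mu, sd = baseline
    shifts = config.atrophy_spec.get(group, {})
    set_shift = np.array([shifts.get(region_sets.set_of(r), 0.0) for r in regions])
    region_effect = rng.standard_normal(len(regions)) * config.region_effect_sd
    values = np.empty((len(records), len(regions)))
    n_resampled = 0
    for i in range(len(records)):
        noise = rng.standard_normal(len(regions)) * config.noise_sd
        row = mu.to_numpy() + (set_shift + region_effect + noise) * sd.to_numpy()
        if measure_kind == "thickness_mm":
            bad = row <= 0
            while bad.any():
                n_resampled += int(bad.sum())
                noise[bad] = rng.standard_normal(int(bad.sum())) * config.noise_sd
                row[bad] = mu.to_numpy()[bad] + (set_shift[bad] + region_effect[bad] + noise[bad]) * sd.to_numpy()[bad]
                bad = row <= 0
        values[i] = row
    if n_resampled:
        logger.info("resampled %d non-positive thickness draws (truncation)", n_resampled)
    frame = pd.DataFrame(values, index=[r.id for r in records], columns=regions)
    return RegionalTable(list(records), frame, measure_kind)


# ---------------------------------------------------------------------------
# full cohort

def make_records(config: CohortConfig, rng: np.random.Generator) -> list[SubjectRecord]:
    """Subject covariates for the three groups (ages in band, cohort-like demographics)."""
    records = []
    idx = 0
    for group, n in zip(("young", "middle", "elderly"), config.n_per_group):
        edu_mu, edu_sd, age_lo, age_hi = _DEMOGRAPHICS[group]
        for _ in range(n):
            age = float(rng.uniform(age_lo, age_hi))
            edu = float(np.clip(rng.normal(edu_mu, edu_sd), 5.0, 24.0))
            sex = "F" if rng.random() < _FEMALE_FRACTION[group] else "M"
            records.append(SubjectRecord(f"sub-{idx:04d}", group, sex, edu, round(age, 2)))
            idx += 1
    return records


@dataclass
class Cohort:
    atlas: LabelVolume
    plan: CohortPlan
    subjects: list[SyntheticSubject]
    thickness: RegionalTable
    volumes: RegionalTable
    planted_sets: RegionSets
    manifest: dict

    @property
    def node_table(self) -> NodeTable:
        return self.plan.node_table

    def records(self, group: str | None = None) -> list[SubjectRecord]:
        recs = [s.record for s in self.subjects]
        return recs if group is None else [r for r in recs if r.group == group]


def generate_cohort(
    config: CohortConfig,
    out_dir: str | Path | None = None,
    with_timeseries: bool = True,
) -> Cohort:
    """Generate atlas, subjects, time series and morphometry for the whole cohort.

    Reproducible from ``config.seed``; optionally writes the fixture bundle
    (atlas + per-subject time-series TSVs + morphometry tables + manifest).
    """
    atlas = build_phantom_atlas(
        config.grid_dims, config.n_parcels, config.seed, voxel_size_mm=config.voxel_size_mm
    )
    plan = build_plan(atlas, config)
    rng_master = np.random.default_rng([config.seed, 0])
    records = make_records(config, rng_master)
    subjects = []
    for i, rec in enumerate(records):
        ts = None
        if with_timeseries:
            rng_subj = np.random.default_rng([config.seed, 1, i])
            ts = simulate_timeseries(atlas, config, rec.group, rng_subj, plan)
        subjects.append(SyntheticSubject(rec, ts))

    cortical = atlas.region_names("cortical_parcel")
    subcortical = atlas.region_names("subcortical_parcel") + ["caudate_left", "caudate_right"]
    mcr, lcr = plan.mcr_parcels, plan.lcr_parcels
    sets_ctx = RegionSets(mcr, lcr, [r for r in cortical if r not in mcr + lcr])
    sets_sub = RegionSets([], [], subcortical)

    rng_morpho = np.random.default_rng([config.seed, 2])
    thickness_parts, volume_parts = [], []
    for group in ("young", "middle", "elderly"):
        recs = [r for r in records if r.group == group]
        if not recs:
            continue
        thickness_parts.append(simulate_morphometry(config, group, sets_ctx, rng_morpho, recs, "thickness_mm"))
        volume_parts.append(
            simulate_morphometry(config, group, sets_sub, rng_morpho, recs, "normalized_volume_mm3")
        )

    def _concat(parts: list[RegionalTable]) -> RegionalTable:
        subs = [s for p in parts for s in p.subjects]
        vals = pd.concat([p.values for p in parts], axis=0)
        return RegionalTable(subs, vals, parts[0].measure_kind)

    thickness = _concat(thickness_parts)
    volumes = _concat(volume_parts)
    planted = RegionSets(mcr, lcr, [r for r in cortical + subcortical if r not in mcr + lcr])
    manifest = {
        "config": config.to_jsonable(),
        "config_hash": config.content_hash(),
        "n_subjects": len(records),
        "n_nodes": plan.node_table.n_nodes,
        "mcr_parcels": mcr,
        "lcr_parcels": lcr,
        "package_version": _pkg_version,
    }
    cohort = Cohort(atlas, plan, subjects, thickness, volumes, planted, manifest)
    if out_dir is not None:
        _write_bundle(cohort, Path(out_dir))
    return cohort


def _write_bundle(cohort: Cohort, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_volume(cohort.atlas, out_dir / "atlas.nii.gz")
    write_regional_table(cohort.thickness, out_dir / "thickness.tsv")
    write_regional_table(cohort.volumes, out_dir / "volumes.tsv")
    ts_dir = out_dir / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    for s in cohort.subjects:
        if s.timeseries is not None:
            np.savetxt(ts_dir / f"{s.record.id}.tsv", s.timeseries, delimiter="\t", fmt="%.6g")
    (out_dir / "manifest.json").write_text(json.dumps(cohort.manifest, indent=1, sort_keys=True))
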