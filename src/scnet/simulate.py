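"""Synthetic two-group cortical-thickness cohorts with known ground truth.

The generator emulates the study design that motivates this package: two
groups (default 40 subjects each) of regional mean cortical thickness over
the 68 Desikan-Killiany regions.  Each group's regional vector is drawn
from a multivariate normal whose correlation structure is planted on a
small-world topology (ring lattice with probabilistic rewiring), optionally
with

* group-specific mean shifts in chosen regions (cortical thinning),
* group-specific correlation values on chosen region pairs, and
* a group-specific topology (``case_rewiring``) so the case group's
  covariance can be shifted toward a lattice-like organisation,

plus linear age and IQ effects shared by both groups.  Every draw is
reproducible from the spec's seed.

Defaults are chosen to sit in the physical range of pediatric cortical
thickness data: baseline mean 2.8 mm, between-subject SD 0.15 mm, ages
uniform on 9-15 years, IQ uniform on 85-135.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ThicknessDataset
from .graph import regular_reference, watts_strogatz_like
from .regions import default_region_names

__all__ = [
    "TopologySpec",
    "CohortSpec",
    "CovarianceBuild",
    "CovarianceRepairError",
    "build_ground_truth_covariance",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

CASE = "case"
CONTROL = "control"


class CovarianceRepairError(ValueError):
    """Eigenvalue clipping distorted target correlations beyond tolerance."""


@dataclass(frozen=True)
class TopologySpec:
    """Generative graph for the planted correlation structure.

    ``neighbors`` is the ring-lattice neighbor count per side (so the
    lattice has N * neighbors edges); ``rewiring`` is the per-edge
    rewiring probability (0 = pure lattice, 1 = essentially random).
    """

    neighbors: int = 3
    rewiring: float = 0.15

    def n_edges(self, n_regions: int) -> int:
        return min(n_regions * self.neighbors, n_regions * (n_regions - 1) // 2)


@dataclass
class CohortSpec:
    """Complete recipe for one synthetic two-group cohort.

    Parameters
    ----------
    n_per_group : subjects per group (>= 4).
    n_regions : network size (>= 4; 68 gives the Desikan-Killiany atlas).
    region_names : node labels; defaults to DK-68 when n_regions == 68.
    base_topology : generative small-world graph for both groups.
    within_edge_correlation : target Pearson r on topology edges.
    mean_shift_regions : list of (region_name, delta_mm) applied to the
        case group's mean vector.
    altered_edges : list of (region_i, region_j, r_case, r_control);
        overrides the topology correlation for those pairs per group.
    case_rewiring : optional rewiring probability for the case group's
        topology (same lattice backbone); lower than the base rewiring
        shifts the case covariance toward a regular network.
    covariate_effects : linear slopes of thickness on centered age
        (mm/year) and centered IQ (mm/point), shared by both groups.
    noise_sd : between-subject SD of regional thickness, mm.
    baseline_mean : grand mean thickness, mm.
    age_range, iq_range : uniform covariate marginals, identical in both
        groups by default so covariates are not confounded with group.
    adhd_index_means : mean symptom score per group (case, control).
    seed : master seed; two generations with equal seeds are identical.
    """

    n_per_group: int = 40
    n_regions: int = 68
    region_names: list[str] | None = None
    base_topology: TopologySpec = field(default_factory=TopologySpec)
    within_edge_correlation: float = 0.35
    mean_shift_regions: list[tuple[str, float]] = field(default_factory=list)
    altered_edges: list[tuple[str, str, float, float]] = field(default_factory=list)
    case_rewiring: float | None = None
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": -0.02, "iq": 0.0005}
    )
    noise_sd: float = 0.15
    baseline_mean: float = 2.8
    age_range: tuple[float, float] = (9.0, 15.0)
    iq_range: tuple[float, float] = (85.0, 135.0)
    adhd_index_means: tuple[float, float] = (62.0, 45.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_names is None:
            self.region_names = default_region_names(self.n_regions)
        self.validate()

    def validate(self) -> None:
        if self.n_per_group < 4:
            raise ValueError("n_per_group must be >= 4")
        if self.n_regions < 4:
            raise ValueError("n_regions must be >= 4")
        if len(self.region_names) != self.n_regions:
            raise ValueError("region_names length must equal n_regions")
        if not -1 < self.within_edge_correlation < 1:
            raise ValueError("within_edge_correlation must be in (-1, 1)")
        for ri, rj, rc, rn in self.altered_edges:
            if not (-1 < rc < 1 and -1 < rn < 1):
                raise ValueError(f"altered edge ({ri}, {rj}): r must be in (-1, 1)")
            self.region_index(ri), self.region_index(rj)
        for region, _ in self.mean_shift_regions:
            self.region_index(region)
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def region_index(self, region: str) -> int:
        try:
            return self.region_names.index(region)
        except ValueError:
            raise ValueError(f"unknown region {region!r}") from None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["altered_edges"] = [list(e) for e in self.altered_edges]
        d["mean_shift_regions"] = [list(e) for e in self.mean_shift_regions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if isinstance(d.get("base_topology"), dict):
            d["base_topology"] = TopologySpec(**d["base_topology"])
        d["altered_edges"] = [tuple(e) for e in d.get("altered_edges", [])]
        d["mean_shift_regions"] = [tuple(e) for e in d.get("mean_shift_regions", [])]
        for key in ("age_range", "iq_range", "adhd_index_means"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class CovarianceBuild:
    """Ground-truth covariance with a record of the PSD repair."""

    matrix: np.ndarray
    repaired: bool
    max_target_deviation: float


def _topology_adjacency(spec: CohortSpec, group: str) -> np.ndarray:
    """Planted graph for one group; both groups share the master seed so
    the lattice backbone and rewiring draws coincide except where
    ``case_rewiring`` differs."""
    topo = spec.base_topology
    k_edges = topo.n_edges(spec.n_regions)
    rewiring = topo.rewiring
    if group == CASE and spec.case_rewiring is not None:
        rewiring = spec.case_rewiring
    if k_edges == 0:
        return np.zeros((spec.n_regions, spec.n_regions), dtype=np.uint8)
    if rewiring == 0:
        return regular_reference(spec.n_regions, k_edges).adjacency
    # topology seed derived from the master seed, shared by both groups
    g = watts_strogatz_like(spec.n_regions, k_edges, rewiring, seed=spec.seed + 101)
    return g.adjacency


def build_ground_truth_covariance(spec: CohortSpec, group: str) -> CovarianceBuild:
    """Assemble the regions x regions covariance for one group.

    The target correlation matrix is identity + ``within_edge_correlation``
    on the planted topology edges, with ``altered_edges`` entries replaced
    by the group-specific r.  Eigenvalues are clipped at 1e-6 to force
    positive definiteness, the matrix is rescaled to unit diagonal, and
    the covariance is noise_sd**2 times the result.  If the repair moves
    any target entry by more than 0.1 a :class:`CovarianceRepairError`
    names the offending edges.
    """
    if group not in (CASE, CONTROL):
        raise ValueError(f"group must be {CASE!r} or {CONTROL!r}")
    spec.validate()
    p = spec.n_regions
    adj = _topology_adjacency(spec, group)
    target = np.eye(p) + spec.within_edge_correlation * adj.astype(float)
    for ri, rj, r_case, r_control in spec.altered_edges:
        i, j = spec.region_index(ri), spec.region_index(rj)
        r = r_case if group == CASE else r_control
        target[i, j] = target[j, i] = r

    vals, vecs = np.linalg.eigh(target)
    repaired = bool(vals.min() < 1e-6)
    corr = target
    if repaired:
        clipped = np.clip(vals, 1e-6, None)
        corr = (vecs * clipped) @ vecs.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        corr = (corr + corr.T) / 2.0

    # deviation on entries with a stated target (topology + altered edges)
    mask = adj.astype(bool).copy()
    for ri, rj, *_ in spec.altered_edges:
        i, j = spec.region_index(ri), spec.region_index(rj)
        mask[i, j] = mask[j, i] = True
    dev = np.abs(corr - target)[mask]
    max_dev = float(dev.max()) if dev.size else 0.0
    if max_dev > 0.1:
        bad = np.argwhere(np.triu(np.abs(corr - target) > 0.1, 1) & np.triu(mask, 1))
        names = [(spec.region_names[i], spec.region_names[j]) for i, j in bad]
        raise CovarianceRepairError(
            "positive-definiteness repair moved target correlations by more "
            f"than 0.1 on edges {names}; lower within_edge_correlation or the "
            "topology density"
        )
    return CovarianceBuild(
        matrix=spec.noise_sd**2 * corr, repaired=repaired, max_target_deviation=max_dev
    )


def _group_mean(spec: CohortSpec, group: str) -> np.ndarray:
    mean = np.full(spec.n_regions, spec.baseline_mean)
    if group == CASE:
        for region, delta in spec.mean_shift_regions:
            mean[spec.region_index(region)] += delta
    return mean


def generate_cohort(spec: CohortSpec) -> ThicknessDataset:
    """Draw one cohort: 2 * n_per_group subjects of regional thickness.

    thickness = group mean vector + age/IQ linear terms (covariates
    centered at their range midpoints) + multivariate-normal noise from
    the group's ground-truth covariance.  Bit-reproducible from
    ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_per_group, spec.n_regions

    rows, groups, ages, iqs, adhd = [], [], [], [], []
    for group, adhd_mean in zip((CASE, CONTROL), spec.adhd_index_means):
        cov = build_ground_truth_covariance(spec, group).matrix
        age = rng.uniform(*spec.age_range, size=n)
        iq = rng.uniform(*spec.iq_range, size=n)
        noise = rng.multivariate_normal(np.zeros(p), cov, size=n, method="eigh")
        mean = _group_mean(spec, group)
        cov_term = (
            spec.covariate_effects.get("age", 0.0)
            * (age - np.mean(spec.age_range))[:, None]
            + spec.covariate_effects.get("iq", 0.0)
            * (iq - np.mean(spec.iq_range))[:, None]
        )
        rows.append(mean[None, :] + cov_term + noise)
        groups.extend([group] * n)
        ages.append(age)
        iqs.append(iq)
        adhd.append(np.round(rng.normal(adhd_mean, 8.0, size=n), 1))

    thickness = np.vstack(rows)
    subject_ids = [f"sub-{i:03d}" for i in range(2 * n)]
    return ThicknessDataset(
        subject_ids=subject_ids,
        group=np.array(groups, dtype=object),
        thickness=thickness,
        age=np.concatenate(ages),
        iq=np.concatenate(iqs),
        region_names=list(spec.region_names),
        adhd_index=np.concatenate(adhd),
        case_label=CASE,
    )


# ----------------------------------------------------------------------
# cohort IO with a generating-spec sidecar
# ----------------------------------------------------------------------
def write_cohort(data: ThicknessDataset, path, spec: CohortSpec | None = None) -> None:
    """Write the tidy cohort CSV; when a spec is given, a JSON sidecar
    (<path>.spec.json) records the full generating recipe including seed."""
    path = Path(path)
    data.to_csv(path)
    if spec is not None:
        sidecar = path.with_suffix(path.suffix + ".spec.json")
        sidecar.write_text(json.dumps(spec.to_dict(), indent=2))


def read_cohort(path, case_label: str | None = CASE):
    """Read a cohort CSV (and its spec sidecar if present).

    Returns (ThicknessDataset, CohortSpec or None).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if case_label is not None and case_label not in set(df["group"]):
        case_label = None
    data = ThicknessDataset.from_dataframe(df, case_label=case_label)
    sidecar = path.with_suffix(path.suffix + ".spec.json")
    spec = None
    if sidecar.exists():
        spec = CohortSpec.from_dict(json.loads(sidecar.read_text()))
    return data, spec
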