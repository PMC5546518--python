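"""Permutation-based group inference on covariance networks.

Because each group contributes exactly one correlation matrix (and hence
one graph per cost), group differences in network metrics have no
subject-level sampling distribution; inference is by permutation of the
group labels.  Each permutation reassigns subjects to two pseudo-groups
of the original sizes, rebuilds both correlation matrices from the
(fixed, pooled) residuals, thresholds at the same cost, and recomputes
the metric difference.  The observed difference is referred to the null
distribution one-tailed, with the 95th-percentile decision threshold and
the +1 Monte-Carlo correction, so p >= 1/(n_perm+1).

Interregional correlations are screened pairwise with the Fisher
r-to-z difference statistic

    Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)),

given a permutation p per pair and Benjamini-Hochberg FDR across all
pairs.  Symptom associations use Spearman rank correlation of each
region's thickness with the ADHD index.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import ThicknessDataset
from .graph import (
    EfficiencyProfile,
    _global_eff,
    _local_eff,
    _nodal_eff,
    edges_for_cost,
    efficiency_profile,
)
from .preprocess import ResidualDataset

__all__ = [
    "PermutationResult",
    "EfficiencyCurves",
    "fisher_z_difference",
    "permute_network_metric",
    "nodal_screen",
    "efficiency_curves",
    "edge_screen",
    "symptom_correlation",
]

DEFAULT_TAILS = {"e_glob": "less", "e_loc": "greater", "e_nodal": "auto"}


# ----------------------------------------------------------------------
# Fisher r-to-z
# ----------------------------------------------------------------------
def fisher_z_difference(r1, r2, n1: int, n2: int):
    """Z statistic for the difference of two independent correlations.

    Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)).  Accepts
    scalars or arrays; raises on |r| = 1 (transform undefined) and on
    sample sizes <= 3.
    """
    r1, r2 = np.asarray(r1, float), np.asarray(r2, float)
    if n1 <= 3 or n2 <= 3:
        raise ValueError("Fisher z comparison needs n > 3 in both groups")
    if np.any(np.abs(r1) >= 1) or np.any(np.abs(r2) >= 1):
        raise ValueError("Fisher transform undefined for |r| >= 1")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    return z if z.ndim else float(z)


# ----------------------------------------------------------------------
# fast internals shared by the permutation engines
# ----------------------------------------------------------------------
def _corr(x: np.ndarray) -> np.ndarray:
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 0.0)
    return r


def _adjacency_top_k(r: np.ndarray, iu, ju, k: int) -> np.ndarray:
    """0/1 adjacency keeping the k largest-|r| pairs (ties: lexicographic)."""
    absr = np.abs(r[iu, ju])
    if k < absr.size:
        idx = np.argpartition(-absr, k - 1)[:k]
        cut = absr[idx].min()
        n_above = int((absr > cut).sum())
        if n_above < k:  # resolve ties at the cutoff lexicographically
            at_cut = np.nonzero(absr == cut)[0]
            idx = np.concatenate([np.nonzero(absr > cut)[0], at_cut[: k - n_above]])
    else:
        idx = np.arange(absr.size)
    adj = np.zeros(r.shape, dtype=np.uint8)
    adj[iu[idx], ju[idx]] = 1
    return adj | adj.T


_METRIC_FNS = {"e_glob": _global_eff, "e_loc": _local_eff}


def _metric_value(adj: np.ndarray, metric: str, node: int | None):
    if metric == "e_nodal":
        if node is None:
            raise ValueError("metric 'e_nodal' requires a node index")
        return float(_nodal_eff(adj)[node])
    try:
        return _METRIC_FNS[metric](adj)
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}") from None


def _one_tailed_p(observed: float, null: np.ndarray, tail: str) -> tuple[float, str]:
    if tail == "auto":
        tail = "greater" if observed >= 0 else "less"
    n = null.size
    if tail == "greater":
        p = (int((null >= observed).sum()) + 1) / (n + 1)
    elif tail == "less":
        p = (int((null <= observed).sum()) + 1) / (n + 1)
    else:
        raise ValueError(f"tail must be 'greater', 'less' or 'auto', got {tail!r}")
    return p, tail


# ----------------------------------------------------------------------
# permutation test for one network metric at one cost
# ----------------------------------------------------------------------
@dataclass
class PermutationResult:
    """Observed case-control metric difference against its permutation null."""

    metric: str
    cost: float
    observed_diff: float
    null_diffs: np.ndarray
    n_permutations: int
    seed: int | None
    tail: str
    p: float
    node: int | None = None
    node_name: str | None = None
    exact: bool = False
    null_mean: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        self.null_diffs = np.asarray(self.null_diffs, float)
        self.null_mean = float(self.null_diffs.mean())
        self.ci_low, self.ci_high = (
            float(v) for v in np.percentile(self.null_diffs, [2.5, 97.5])
        )


def permute_network_metric(
    resid: ResidualDataset,
    metric: str,
    cost: float,
    n_perm: int = 5000,
    seed: int = 0,
    tail: str | None = None,
    node: int | None = None,
    exact: bool = False,
) -> PermutationResult:
    """Permutation test of a case-control efficiency difference at one cost.

    Parameters
    ----------
    metric : 'e_glob', 'e_loc' or 'e_nodal' (with ``node``).
    tail : 'greater', 'less' or 'auto' (sign of the observed difference).
        Defaults follow the study hypotheses: global efficiency lower in
        cases ('less'), local efficiency higher ('greater'), nodal 'auto'.
    exact : enumerate every balanced relabeling instead of sampling;
        p is then the exact fraction of relabelings (including the
        identity) at least as extreme as the observed difference.
    """
    if tail is None:
        tail = DEFAULT_TAILS[metric]
    labels = resid.group
    case_mask = labels == resid.case_label
    n1 = int(case_mask.sum())
    n2 = labels.size - n1
    if min(n1, n2) < 4:
        raise ValueError("permutation test requires at least 4 subjects per group")
    if not exact and n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small for permutation inference")

    x = resid.residuals
    p_regions = x.shape[1]
    k = edges_for_cost(p_regions, cost)
    if k < 1:
        raise ValueError(f"cost {cost} yields an empty graph")
    iu, ju = np.triu_indices(p_regions, 1)

    def diff(case_idx: np.ndarray, control_idx: np.ndarray) -> float:
        vals = []
        for idx in (case_idx, control_idx):
            adj = _adjacency_top_k(_corr(x[idx]), iu, ju, k)
            vals.append(_metric_value(adj, metric, node))
        return vals[0] - vals[1]

    all_idx = np.arange(labels.size)
    observed = diff(all_idx[case_mask], all_idx[~case_mask])

    if exact:
        null = np.array(
            [
                diff(np.array(c), np.setdiff1d(all_idx, c, assume_unique=True))
                for c in itertools.combinations(all_idx, n1)
            ]
        )
        direction = tail if tail != "auto" else ("greater" if observed >= 0 else "less")
        if direction == "greater":
            p_val = float((null >= observed).mean())
        else:
            p_val = float((null <= observed).mean())
        return PermutationResult(
            metric=metric,
            cost=cost,
            observed_diff=observed,
            null_diffs=null,
            n_permutations=null.size,
            seed=None,
            tail=direction,
            p=p_val,
            node=node,
            node_name=resid.region_names[node] if node is not None else None,
            exact=True,
        )

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(all_idx)
        null[b] = diff(perm[:n1], perm[n1:])
    p_val, direction = _one_tailed_p(observed, null, tail)
    return PermutationResult(
        metric=metric,
        cost=cost,
        observed_diff=observed,
        null_diffs=null,
        n_permutations=n_perm,
        seed=seed,
        tail=direction,
        p=p_val,
        node=node,
        node_name=resid.region_names[node] if node is not None else None,
    )


# ----------------------------------------------------------------------
# nodal screen at the comparison cost
# ----------------------------------------------------------------------
def nodal_screen(
    resid: ResidualDataset,
    cost: float = 0.095,
    n_perm: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation test of E_nodal for every region at one cost.

    All regions share the same permutation stream (one relabeling tests
    all nodes at once).  The tail per node follows the sign of its
    observed difference; p values are not corrected across nodes.
    Returns a table: region, e_nodal_case, e_nodal_control,
    observed_diff, null_mean, ci_low, ci_high, tail, p.
    """
    labels = resid.group
    case_mask = labels == resid.case_label
    n1 = int(case_mask.sum())
    if min(n1, labels.size - n1) < 4:
        raise ValueError("permutation test requires at least 4 subjects per group")
    x = resid.residuals
    p_regions = x.shape[1]
    k = edges_for_cost(p_regions, cost)
    iu, ju = np.triu_indices(p_regions, 1)

    def nodal_vec(idx: np.ndarray) -> np.ndarray:
        return _nodal_eff(_adjacency_top_k(_corr(x[idx]), iu, ju, k))

    all_idx = np.arange(labels.size)
    obs_case = nodal_vec(all_idx[case_mask])
    obs_control = nodal_vec(all_idx[~case_mask])
    observed = obs_case - obs_control

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, p_regions))
    for b in range(n_perm):
        perm = rng.permutation(all_idx)
        null[b] = nodal_vec(perm[:n1]) - nodal_vec(perm[n1:])

    rows = []
    for i, name in enumerate(resid.region_names):
        p_val, direction = _one_tailed_p(observed[i], null[:, i], "auto")
        lo, hi = np.percentile(null[:, i], [2.5, 97.5])
        rows.append(
            {
                "region": name,
                "e_nodal_case": obs_case[i],
                "e_nodal_control": obs_control[i],
                "observed_diff": observed[i],
                "null_mean": null[:, i].mean(),
                "ci_low": lo,
                "ci_high": hi,
                "tail": direction,
                "p": p_val,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["cost"] = cost
    out.attrs["n_permutations"] = n_perm
    out.attrs["seed"] = seed
    return out


# ----------------------------------------------------------------------
# efficiency-versus-cost curves with permutation bands
# ----------------------------------------------------------------------
@dataclass
class EfficiencyCurves:
    """Group efficiency curves, matched references, and permutation bands.

    ``table`` is tidy: one row per (cost, metric) with both groups'
    values, regular/random references, the observed difference, the null
    mean, the 95% null band and the one-tailed p.  ``profiles`` maps each
    group label to its :class:`~scnet.graph.EfficiencyProfile`.
    """

    table: pd.DataFrame
    profiles: dict[str, EfficiencyProfile]
    n_permutations: int
    seed: int


def efficiency_curves(
    resid: ResidualDataset,
    cost_grid,
    n_perm: int = 5000,
    seed: int = 0,
    n_random: int = 20,
) -> EfficiencyCurves:
    """E_glob and E_loc of both groups across the cost grid, with matched
    regular/random reference curves and per-cost permutation inference.

    One permutation stream covers the whole grid: each relabeling's two
    correlation matrices are computed once and thresholded at every cost.
    """
    from .graph import GroupCorrelationMatrix  # local to avoid cycle at import

    cost_grid = np.asarray(cost_grid, dtype=float)
    if cost_grid.size == 0:
        raise ValueError("cost grid is empty")
    labels = resid.group
    case_mask = labels == resid.case_label
    n1 = int(case_mask.sum())
    if min(n1, labels.size - n1) < 4:
        raise ValueError("permutation test requires at least 4 subjects per group")
    x = resid.residuals
    p_regions = x.shape[1]
    iu, ju = np.triu_indices(p_regions, 1)
    ks = [edges_for_cost(p_regions, c) for c in cost_grid]
    if min(ks) < 1:
        raise ValueError("smallest cost yields an empty graph")

    def curve_pair(idx: np.ndarray) -> np.ndarray:
        """(n_costs, 2) array of [e_glob, e_loc] for one subject set."""
        r = _corr(x[idx])
        out = np.empty((cost_grid.size, 2))
        for ci, k in enumerate(ks):
            adj = _adjacency_top_k(r, iu, ju, k)
            out[ci, 0] = _global_eff(adj)
            out[ci, 1] = _local_eff(adj)
        return out

    all_idx = np.arange(labels.size)
    obs_case = curve_pair(all_idx[case_mask])
    obs_control = curve_pair(all_idx[~case_mask])
    observed = obs_case - obs_control

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, cost_grid.size, 2))
    for b in range(n_perm):
        perm = rng.permutation(all_idx)
        null[b] = curve_pair(perm[:n1]) - curve_pair(perm[n1:])

    # observed profiles (with nodal curves and references) via the
    # first-class graph API
    profiles = {}
    for label, mask in (
        (resid.case_label, case_mask),
        (resid.control_label, ~case_mask),
    ):
        corr = GroupCorrelationMatrix(
            r=np.clip(_corr(x[mask]), -1, 1),
            n_subjects=int(mask.sum()),
            group=label,
            region_names=list(resid.region_names),
        )
        profiles[label] = efficiency_profile(
            corr, cost_grid, seed=seed, n_random=n_random
        )

    ref = profiles[resid.control_label]
    rows = []
    for mi, metric in enumerate(("e_glob", "e_loc")):
        tail = DEFAULT_TAILS[metric]
        for ci, cost in enumerate(cost_grid):
            nd = null[:, ci, mi]
            p_val, direction = _one_tailed_p(observed[ci, mi], nd, tail)
            lo, hi = np.percentile(nd, [2.5, 97.5])
            rows.append(
                {
                    "cost": cost,
                    "metric": metric,
                    "value_case": obs_case[ci, mi],
                    "value_control": obs_control[ci, mi],
                    "value_regular": (ref.e_glob_reg if mi == 0 else ref.e_loc_reg)[ci],
                    "value_random": (ref.e_glob_rand if mi == 0 else ref.e_loc_rand)[
                        ci
                    ],
                    "observed_diff": observed[ci, mi],
                    "null_mean": nd.mean(),
                    "ci_low": lo,
                    "ci_high": hi,
                    "tail": direction,
                    "p": p_val,
                }
            )
    table = pd.DataFrame(rows)
    return EfficiencyCurves(
        table=table, profiles=profiles, n_permutations=n_perm, seed=seed
    )


# ----------------------------------------------------------------------
# pairwise correlation screen (Fisher z + permutation + FDR)
# ----------------------------------------------------------------------
def edge_screen(
    resid: ResidualDataset,
    n_perm: int = 5000,
    q_level: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Screen every region pair for a group difference in correlation.

    For each of the N(N-1)/2 pairs: both groups' correlations, the Fisher
    Z difference statistic, a permutation p (null of |Z| under label
    relabeling), and the Benjamini-Hochberg q across all pairs.
    ``direction`` is 'increased' where r_case > r_control and 'decreased'
    otherwise, mirroring the increased/decreased-correlation partition of
    published tables; ``significant`` marks q < q_level.
    """
    labels = resid.group
    case_mask = labels == resid.case_label
    n1 = int(case_mask.sum())
    n2 = labels.size - n1
    if min(n1, n2) < 4:
        raise ValueError("edge screen requires at least 4 subjects per group")
    x = resid.residuals
    p_regions = x.shape[1]
    iu, ju = np.triu_indices(p_regions, 1)

    def pair_z(case_idx, control_idx):
        r1 = _corr(x[case_idx])[iu, ju]
        r2 = _corr(x[control_idx])[iu, ju]
        return r1, r2, fisher_z_difference(
            np.clip(r1, -1 + 1e-15, 1 - 1e-15),
            np.clip(r2, -1 + 1e-15, 1 - 1e-15),
            n1,
            n2,
        )

    all_idx = np.arange(labels.size)
    r_case, r_control, z_obs = pair_z(all_idx[case_mask], all_idx[~case_mask])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(iu.size, dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(all_idx)
        _, _, z_null = pair_z(perm[:n1], perm[n1:])
        exceed += np.abs(z_null) >= np.abs(z_obs)
    p_perm = (exceed + 1) / (n_perm + 1)
    _, q, _, _ = multipletests(p_perm, alpha=q_level, method="fdr_bh")

    table = pd.DataFrame(
        {
            "region_i": [resid.region_names[i] for i in iu],
            "region_j": [resid.region_names[j] for j in ju],
            "r_case": r_case,
            "r_control": r_control,
            "z_case": np.arctanh(np.clip(r_case, -1 + 1e-15, 1 - 1e-15)),
            "z_control": np.arctanh(np.clip(r_control, -1 + 1e-15, 1 - 1e-15)),
            "Z": z_obs,
            "p_perm": p_perm,
            "q": q,
            "significant": q < q_level,
            "direction": np.where(r_case > r_control, "increased", "decreased"),
        }
    )
    table.attrs["n_permutations"] = n_perm
    table.attrs["q_level"] = q_level
    table.attrs["seed"] = seed
    return table.sort_values("p_perm", kind="stable").reset_index(drop=True)


# ----------------------------------------------------------------------
# symptom correlation screen
# ----------------------------------------------------------------------
def symptom_correlation(data: ThicknessDataset) -> pd.DataFrame:
    """Spearman correlation of each region's thickness with the ADHD index.

    Returns a table (region, rho, p) over all subjects with a non-missing
    index; raises if the index is absent or constant.
    """
    if data.adhd_index is None:
        raise ValueError("dataset has no adhd_index column")
    idx = data.adhd_index
    ok = np.isfinite(idx)
    if np.ptp(idx[ok]) == 0:
        raise ValueError("adhd_index is constant; rank correlation undefined")
    rows = []
    for j, region in enumerate(data.region_names):
        rho, p = stats.spearmanr(data.thickness[ok, j], idx[ok])
        rows.append({"region": region, "rho": rho, "p": p})
    return pd.DataFrame(rows)
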