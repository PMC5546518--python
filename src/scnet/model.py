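"""Model/Results interface over the full covariance-network analysis.

:class:`StructuralCovarianceModel` is constructed from a
:class:`~scnet.datasets.ThicknessDataset` (or a tidy DataFrame / CSV);
``fit()`` runs the whole chain — residualization, per-region ANOVA, group
correlation matrices, efficiency-versus-cost curves with matched
references, the small-world check, permutation tests of global/local
efficiency and the nodal screen at the comparison cost, the pairwise
correlation screen, and the symptom screen — and returns a
:class:`StructuralCovarianceResults` carrying every table plus
``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import inference, preprocess
from .datasets import ThicknessDataset
from .graph import SmallWorldVerdict, correlation_matrix

__all__ = ["StructuralCovarianceModel", "StructuralCovarianceResults"]

DEFAULT_COST_GRID = np.round(np.arange(0.05, 0.4 + 1e-9, 0.005), 3)


class StructuralCovarianceModel:
    """Two-group structural covariance network analysis.

    Parameters
    ----------
    data : ThicknessDataset
    cost_grid : array-like of network costs, default 0.05-0.4 step 0.005.
    comparison_cost : single cost for the global/local/nodal permutation
        tests, default 0.095.
    n_random_realizations : random reference networks averaged per cost.
    pooled_residualization : fit the nuisance regression across all
        subjects jointly (default) rather than within group.
    """

    def __init__(
        self,
        data: ThicknessDataset,
        cost_grid=None,
        comparison_cost: float = 0.095,
        n_random_realizations: int = 20,
        pooled_residualization: bool = True,
    ):
        self.data = data
        self.cost_grid = (
            DEFAULT_COST_GRID.copy() if cost_grid is None else np.asarray(cost_grid, float)
        )
        if self.cost_grid.size == 0:
            raise ValueError("cost grid must be non-empty")
        if np.any(np.diff(self.cost_grid) <= 0) or not (
            0 < self.cost_grid[0] and self.cost_grid[-1] <= 1
        ):
            raise ValueError("cost grid must be strictly increasing within (0, 1]")
        self.comparison_cost = float(comparison_cost)
        self.n_random_realizations = int(n_random_realizations)
        self.pooled_residualization = bool(pooled_residualization)

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, case_label: str | None = None, **kwargs):
        return cls(ThicknessDataset.from_dataframe(df, case_label=case_label), **kwargs)

    @classmethod
    def from_csv(cls, path, case_label: str | None = None, **kwargs):
        return cls(ThicknessDataset.read_csv(path, case_label=case_label), **kwargs)

    # ------------------------------------------------------------------
    def fit(
        self,
        n_permutations: int = 5000,
        seed: int = 0,
        run_curves: bool = True,
        run_nodal: bool = True,
        run_edge_screen: bool = True,
        run_symptoms: bool = True,
    ) -> "StructuralCovarianceResults":
        """Run the analysis; each stage draws its own seed from ``seed``."""
        data = self.data
        resid = preprocess.residualize(data, pooled=self.pooled_residualization)
        anova = preprocess.region_group_anova(resid)
        corr_case = correlation_matrix(resid, resid.case_label)
        corr_control = correlation_matrix(resid, resid.control_label)

        ss = np.random.SeedSequence(seed)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]

        curves = None
        if run_curves:
            curves = inference.efficiency_curves(
                resid,
                self.cost_grid,
                n_perm=n_permutations,
                seed=seeds[0],
                n_random=self.n_random_realizations,
            )

        glob_test = inference.permute_network_metric(
            resid, "e_glob", self.comparison_cost, n_perm=n_permutations, seed=seeds[1]
        )
        loc_test = inference.permute_network_metric(
            resid, "e_loc", self.comparison_cost, n_perm=n_permutations, seed=seeds[2]
        )

        nodal = None
        if run_nodal:
            nodal = inference.nodal_screen(
                resid, cost=self.comparison_cost, n_perm=n_permutations, seed=seeds[3]
            )

        edges = None
        if run_edge_screen:
            edges = inference.edge_screen(
                resid, n_perm=n_permutations, seed=seeds[4]
            )

        symptoms = None
        if run_symptoms and data.adhd_index is not None:
            symptoms = inference.symptom_correlation(data)

        small_world = {}
        if curves is not None:
            for label, profile in curves.profiles.items():
                try:
                    small_world[label] = profile.small_world_at(self.comparison_cost)
                except ValueError:
                    pass

        return StructuralCovarianceResults(
            model=self,
            residuals=resid,
            anova_table=anova,
            corr_case=corr_case,
            corr_control=corr_control,
            curves=curves,
            glob_test=glob_test,
            loc_test=loc_test,
            nodal_table=nodal,
            edge_table=edges,
            symptom_table=symptoms,
            small_world=small_world,
            n_permutations=n_permutations,
            seed=seed,
            stage_seeds=seeds,
        )


@dataclass
class StructuralCovarianceResults:
    """Fitted results of :class:`StructuralCovarianceModel`."""

    model: StructuralCovarianceModel
    residuals: preprocess.ResidualDataset
    anova_table: pd.DataFrame
    corr_case: object
    corr_control: object
    curves: inference.EfficiencyCurves | None
    glob_test: inference.PermutationResult
    loc_test: inference.PermutationResult
    nodal_table: pd.DataFrame | None
    edge_table: pd.DataFrame | None
    symptom_table: pd.DataFrame | None
    small_world: dict[str, SmallWorldVerdict]
    n_permutations: int
    seed: int
    stage_seeds: list[int] = field(default_factory=list)

    # ------------------------------------------------------------------
    def summary(self, top: int = 5) -> str:
        """Human-readable overview in the style of a fit report."""
        d = self.model.data
        lines = []
        add = lines.append
        add("Structural Covariance Network Analysis")
        add("=" * 54)
        add(
            f"Subjects: {d.n_subjects} "
            f"({d.case_label}: {int(d.group_mask(d.case_label).sum())}, "
            f"{d.control_label}: {int(d.group_mask(d.control_label).sum())}); "
            f"regions: {d.n_regions}"
        )
        add(
            f"Cost grid: {self.model.cost_grid[0]:.3f}-{self.model.cost_grid[-1]:.3f} "
            f"({self.model.cost_grid.size} points); comparison cost "
            f"{self.model.comparison_cost}; permutations: {self.n_permutations}; "
            f"seed: {self.seed}"
        )
        add("")
        sig = self.anova_table[self.anova_table["p"] < 0.05]
        add(
            f"Regional thickness ANOVA (residualized, df=({self.anova_table['df1'].iat[0]},"
            f"{self.anova_table['df2'].iat[0]})): {len(sig)}/{len(self.anova_table)} "
            "regions with p < 0.05"
        )
        for _, row in sig.nsmallest(top, "p").iterrows():
            add(
                f"  {row['region']:<28s} F={row['F']:7.3f}  p={row['p']:.4f}  "
                f"{row['mean_case']:.4f} vs {row['mean_control']:.4f}"
            )
        add("")
        cc = self.model.comparison_cost
        add(f"Efficiency at cost {cc} ({self.glob_test.n_permutations} permutations):")
        for name, res in (("E_glob", self.glob_test), ("E_loc", self.loc_test)):
            add(
                f"  {name}: diff({d.case_label}-{d.control_label}) = "
                f"{res.observed_diff:+.4f}, 95% null band "
                f"[{res.ci_low:+.4f}, {res.ci_high:+.4f}], one-tailed "
                f"({res.tail}) p = {res.p:.4f}"
            )
        for label, verdict in self.small_world.items():
            add(
                f"  small-world ({label}): "
                f"{'yes' if verdict.is_small_world else 'no'} "
                + " ".join(f"{k}={v:+.3f}" for k, v in verdict.margins.items())
            )
        if self.nodal_table is not None:
            nsig = self.nodal_table[self.nodal_table["p"] < 0.05]
            add("")
            add(f"Nodal screen at cost {cc}: {len(nsig)} regions with p < 0.05")
            for _, row in nsig.nsmallest(top, "p").iterrows():
                add(
                    f"  {row['region']:<28s} diff={row['observed_diff']:+.4f} "
                    f"({row['tail']}) p={row['p']:.4f}"
                )
        if self.edge_table is not None:
            esig = self.edge_table[self.edge_table["significant"]]
            add("")
            add(
                f"Edge screen ({len(self.edge_table)} pairs, BH q < "
                f"{self.edge_table.attrs.get('q_level', 0.05)}): "
                f"{len(esig)} significant"
            )
            for _, row in self.edge_table.head(min(top, 3)).iterrows():
                add(
                    f"  {row['region_i']} -- {row['region_j']}: "
                    f"r={row['r_case']:+.2f} vs {row['r_control']:+.2f}, "
                    f"Z={row['Z']:+.2f}, p_perm={row['p_perm']:.4f}, q={row['q']:.3f}"
                )
        if self.symptom_table is not None:
            ssig = self.symptom_table[self.symptom_table["p"] < 0.05]
            add("")
            add(f"Symptom screen (Spearman vs ADHD index): {len(ssig)} regions p < 0.05")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def summary_dict(self) -> dict:
        """Machine-readable summary (stable schema; JSON-serializable)."""
        d = self.model.data
        out = {
            "n_subjects": d.n_subjects,
            "n_regions": d.n_regions,
            "case_label": d.case_label,
            "control_label": d.control_label,
            "comparison_cost": self.model.comparison_cost,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "stage_seeds": self.stage_seeds,
            "anova_significant_regions": self.anova_table.loc[
                self.anova_table["p"] < 0.05, "region"
            ].tolist(),
            "e_glob": {
                "observed_diff": self.glob_test.observed_diff,
                "ci_low": self.glob_test.ci_low,
                "ci_high": self.glob_test.ci_high,
                "tail": self.glob_test.tail,
                "p": self.glob_test.p,
            },
            "e_loc": {
                "observed_diff": self.loc_test.observed_diff,
                "ci_low": self.loc_test.ci_low,
                "ci_high": self.loc_test.ci_high,
                "tail": self.loc_test.tail,
                "p": self.loc_test.p,
            },
            "small_world": {
                label: {"is_small_world": v.is_small_world, "margins": v.margins}
                for label, v in self.small_world.items()
            },
        }
        if self.nodal_table is not None:
            out["nodal_significant_regions"] = self.nodal_table.loc[
                self.nodal_table["p"] < 0.05, "region"
            ].tolist()
        if self.edge_table is not None:
            out["edge_screen_significant"] = int(self.edge_table["significant"].sum())
        if self.symptom_table is not None:
            out["symptom_significant_regions"] = self.symptom_table.loc[
                self.symptom_table["p"] < 0.05, "region"
            ].tolist()
        return out

    def summary_json(self, **kwargs) -> str:
        return json.dumps(self.summary_dict(), indent=2, sort_keys=True, **kwargs)
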