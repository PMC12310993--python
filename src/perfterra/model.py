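"""Model/Results facade for end-to-end perfusion runs.

:class:`PerfusionModel` bundles a vascular network, a labeled tissue mesh
and the physiologic constants; :meth:`PerfusionModel.fit` executes
source selection -> tessellation -> demand -> boundary lumping -> steady
1D solve -> flow distribution and returns a :class:`PerfusionResults`
carrying territories, flows, pressures and reporting helpers.  The
``boundary_model`` switch selects the supply-and-demand tessellation
boundary conditions or the Murray's-law comparator on the same network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import flow as flow_mod
from . import murray as murray_mod
from . import tessellation as tess_mod
from .network import VascularNetwork, resample_centerline
from .tissue import TissueClassTable, TissueMesh, total_demand

__all__ = ["PerfusionModel", "PerfusionResults"]


class PerfusionModel:
    """Supply-and-demand perfusion model of a vascular network and tissue mesh.

    Parameters
    ----------
    network, mesh:
        Geometry in a common coordinate frame (mm).
    cbf_table:
        Per-tissue-class CBF and density; defaults to gray 0.8 / white 0.2 /
        other 0.5 mL/min/g at 1.04 g/mL.
    boundary_model:
        "tessellation" (default) or "murray".
    d_max:
        Perforator source distance threshold, mm.
    inlet_pressure_mmhg:
        Pressure pinned at every inlet node.
    resample_spacing:
        If set, the network is resampled to this point spacing (mm) before
        anything else.
    """

    def __init__(
        self,
        network: VascularNetwork,
        mesh: TissueMesh,
        cbf_table: TissueClassTable | None = None,
        constants: flow_mod.FluidConstants | None = None,
        boundary_model: str = "tessellation",
        d_max: float = tess_mod.DEFAULT_D_MAX,
        inlet_pressure_mmhg: float = flow_mod.DEFAULT_INLET_PRESSURE_MMHG,
        artery_labels: dict[str, str] | None = None,
        inlet_labels: dict[str, str] | None = None,
        resample_spacing: float | None = None,
        source_speed: float = 1.0,
    ):
        if boundary_model not in ("tessellation", "murray"):
            raise ValueError(f"unknown boundary model {boundary_model!r}")
        self.network = (resample_centerline(network, resample_spacing)
                        if resample_spacing else network.copy())
        self.network.orient_from_inlets()
        self.mesh = mesh
        self.cbf_table = cbf_table or TissueClassTable()
        self.constants = constants or flow_mod.FluidConstants()
        self.boundary_model = boundary_model
        self.d_max = d_max
        self.inlet_pressure_mmhg = inlet_pressure_mmhg
        self.artery_labels = artery_labels
        self.inlet_labels = inlet_labels
        self.source_speed = source_speed

    @classmethod
    def from_files(cls, network_path, mesh_path, **kwargs) -> "PerfusionModel":
        from .network import load_network
        from .tissue import load_mesh

        return cls(load_network(network_path), load_mesh(mesh_path), **kwargs)

    # ------------------------------------------------------------------ fit
    def fit(self, solve: bool = True) -> "PerfusionResults":
        """Run the pipeline; with ``solve=False`` stop after the demand step
        (useful for disconnected diseased networks whose territories are
        still meaningful)."""
        assignment = None
        if self.boundary_model == "tessellation":
            sources = tess_mod.select_sources(
                self.network, self.mesh, self.d_max, self.source_speed)
            assignment = tess_mod.tessellate(self.mesh, sources)
            tess_mod.territory_demand(assignment, self.mesh, self.cbf_table)
            outlet_flows, midpoint_sinks = tess_mod.aggregate_segment_sinks(
                assignment, self.network)
        else:
            alloc = murray_mod.murray_boundary(self.network, self.mesh, self.cbf_table)
            outlet_flows, midpoint_sinks = alloc.outlet_flow_ml_min, {}

        bcs = flow_mod.BoundaryConditions(
            inlet_pressure_mmhg={n: self.inlet_pressure_mmhg for n in self.network.inlets},
            outlet_flow_ml_min=outlet_flows,
            midpoint_sink_ml_min=midpoint_sinks,
        )
        solution = distribution = None
        if solve:
            system = flow_mod.build_system(self.network, bcs, self.constants)
            solution = flow_mod.solve_steady_flow(system)
            distribution = flow_mod.compute_distribution(
                solution, self.artery_labels, self.inlet_labels)
        return PerfusionResults(self, assignment, bcs, solution, distribution)


@dataclass
class PerfusionResults:
    """Fitted territories, flows, pressures and reports."""

    model: PerfusionModel
    assignment: tess_mod.TerritoryAssignment | None
    boundary_conditions: flow_mod.BoundaryConditions
    solution: flow_mod.FlowSolution | None
    distribution: flow_mod.FlowDistribution | None
    _contrib: dict | None = field(default=None, repr=False)

    # -------------------------------------------------------------- queries
    @property
    def total_demand_ml_min(self) -> float:
        bcs = self.boundary_conditions
        return (sum(bcs.outlet_flow_ml_min.values())
                + sum(bcs.midpoint_sink_ml_min.values()))

    def territory_summary(self):
        if self.assignment is None:
            raise ValueError("no territories under the Murray boundary model")
        return self.assignment.summary()

    def inlet_contributions(self) -> dict:
        """Per-source inlet supply fractions (collateral mixing through loops)."""
        if self.solution is None:
            raise ValueError("model was fitted with solve=False")
        if self._contrib is None:
            self._contrib = flow_mod.inlet_contribution_map(
                self.solution, self.assignment)
        return self._contrib

    # ------------------------------------------------------------- reporting
    def summary(self) -> str:
        m = self.model
        lines = [
            "Perfusion model results",
            "=======================",
            f"boundary model:      {m.boundary_model}",
            f"segments / points:   {len(m.network.segments)} / {len(m.network.points)}",
            f"tissue elements:     {m.mesh.n_elements}"
            f" ({m.mesh.total_volume_ml:.1f} mL)",
            f"total demand:        {self.total_demand_ml_min:.3f} mL/min",
        ]
        if self.assignment is not None:
            n_src = len(self.assignment.sources)
            n_out = sum(1 for s in self.assignment.sources if s.kind == "outlet")
            lines.append(f"sources:             {n_src} ({n_out} outlets, "
                         f"{n_src - n_out} perforators)")
            n_un = len(self.assignment.unassigned_elements)
            if n_un:
                lines.append(f"unassigned elements: {n_un}")
        if self.solution is not None:
            lines.append(f"total inflow:        "
                         f"{self.solution.total_inflow_ml_min:.3f} mL/min")
            lines.append(f"conservation resid.: "
                         f"{self.solution.conservation_residual:.3e}")
        if self.distribution is not None:
            lines.append("")
            lines.append("flow distribution (% of measured arteries / inlets)")
            for k, v in self.distribution.artery_ratio_pct.items():
                lines.append(f"  {k:6s} {v:6.2f} %"
                             f"   ({self.distribution.artery_flow_ml_min[k]:8.3f} mL/min)")
            for k, v in self.distribution.inlet_ratio_pct.items():
                lines.append(f"  {k:6s} {v:6.2f} %"
                             f"   ({self.distribution.inlet_flow_ml_min[k]:8.3f} mL/min)")
            if self.distribution.missing_arteries:
                lines.append(f"  absent arteries: "
                             f"{', '.join(self.distribution.missing_arteries)}")
        return "\n".join(lines)

    def plot_distribution(self, ax=None):
        """Bar chart of the artery flow ratios (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if self.distribution is None:
            raise ValueError("no flow solution to plot")
        if ax is None:
            _, ax = plt.subplots()
        items = list(self.distribution.artery_ratio_pct.items())
        ax.bar([k for k, _ in items], [v for _, v in items])
        ax.set_ylabel("relative flow ratio [%]")
        ax.set_title(f"{self.model.boundary_model} boundary model")
        return ax

    def to_csv(self, path) -> None:
        """Per-segment flow/pressure table."""
        if self.solution is None:
            raise ValueError("no flow solution")
        self.solution.edge_table().to_csv(path, index=False)
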