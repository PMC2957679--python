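"""Model/Results interface for the topology significance analysis.

:class:`SrnaTargetTopology` binds a network and an sRNA-target map;
``fit`` runs the size-matched random-node-set simulation and returns a
:class:`TopologyResults` carrying one observed-vs-null record per metric
plus a formatted summary table, in the spirit of the fitted-model /
results-object split used by statistical modelling packages.

Example
-------
>>> from srnanet.synthetic import StudyConfig, generate_study
>>> from srnanet.model import SrnaTargetTopology
>>> bundle = generate_study(StudyConfig(seed=7))
>>> res = SrnaTargetTopology(bundle.ppin, bundle.target_map).fit(
...     n_sims=1000, seed=7)
>>> print(res.summary())        # doctest: +SKIP
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .network import Network, load_network
from .permutation import (
    DEFAULT_TAILS,
    StatResult,
    results_to_frame,
    run_significance_suite,
)
from .targets import TargetMap, load_target_table, map_to_network

__all__ = ["SrnaTargetTopology", "TopologyResults"]


class SrnaTargetTopology:
    """Topological enrichment of sRNA target sets in a cellular network.

    Parameters
    ----------
    network : Network
        Undirected (PPI) or directed (transcription-regulatory) network.
    target_map : TargetMap
        sRNA -> target pairs; mapped onto the network at construction, the
        per-evidence coverage is kept on ``self.coverage``.
    universe_mode : str
        ``"network-nodes"`` (default) samples nulls from the network's node
        set; ``"supplied-gene-list"`` samples from ``universe`` (off-network
        draws contribute undefined material).
    harmonic : bool
        Use harmonic instead of reciprocal-mean closeness.
    """

    def __init__(
        self,
        network: Network,
        target_map: TargetMap,
        universe_mode: str = "network-nodes",
        universe: Optional[Sequence[str]] = None,
        harmonic: bool = False,
    ) -> None:
        self.network = network
        self.target_map = target_map
        self.universe_mode = universe_mode
        self.universe = universe
        self.harmonic = harmonic
        self.mapped, self.coverage = map_to_network(target_map, network)
        self.n_targets_in_network = len(self.mapped.unique_targets())
        self.eligible_srnas = sorted(
            s for s in self.mapped.srnas
            if len(self.mapped.targets_of(s)) >= 2
        )

    @classmethod
    def from_files(
        cls,
        network_path: str,
        targets_path: str,
        directed: bool = False,
        dialect: str = "tsv",
        node_list: Optional[str] = None,
        **kwargs,
    ) -> "SrnaTargetTopology":
        net = load_network(network_path, directed=directed, dialect=dialect,
                           node_list=node_list)
        tmap = load_target_table(targets_path)
        return cls(net, tmap, **kwargs)

    def fit(
        self,
        n_sims: int = 1000,
        seed: Optional[int] = None,
        metrics: Optional[Sequence[str]] = None,
        tails: Optional[Dict[str, str]] = None,
    ) -> "TopologyResults":
        """Run the Monte-Carlo null and return the results object."""
        results = run_significance_suite(
            self.network, self.target_map, n_sims=n_sims, seed=seed,
            universe_mode=self.universe_mode, universe=self.universe,
            metrics=metrics, tails=tails, harmonic=self.harmonic,
        )
        return TopologyResults(self, results, n_sims=n_sims, seed=seed)


class TopologyResults:
    """Observed statistics, null summaries, Z-scores and empirical p-values."""

    def __init__(
        self,
        model: SrnaTargetTopology,
        results: List[StatResult],
        n_sims: int,
        seed: Optional[int],
    ) -> None:
        self.model = model
        self.results = results
        self.n_sims = n_sims
        self.seed = seed

    def to_frame(self) -> pd.DataFrame:
        return results_to_frame(self.results)

    def __getitem__(self, statistic: str) -> StatResult:
        for r in self.results:
            if r.statistic == statistic:
                return r
        raise KeyError(statistic)

    def significant(self, alpha: float = 0.05) -> List[str]:
        return [r.statistic for r in self.results
                if math.isfinite(r.p) and r.p <= alpha]

    def summary(self, alpha: float = 0.05) -> str:
        m = self.model
        kind = "directed" if m.network.directed else "undirected"
        lines = [
            "sRNA target topology — random node-set significance",
            "=" * 70,
            f"network: {kind}, {m.network.n_nodes} nodes, {m.network.n_edges} edges",
            f"targets in network: {m.n_targets_in_network}"
            f" ({len(m.eligible_srnas)} eligible sRNAs)",
            f"simulations: {self.n_sims}   seed: {self.seed}"
            f"   universe: {m.universe_mode}",
            "-" * 70,
            f"{'statistic':<22}{'observed':>10}{'sim.mean':>10}"
            f"{'sim.sd':>10}{'z':>8}{'p':>10}",
            "-" * 70,
        ]
        for r in self.results:
            star = " *" if math.isfinite(r.p) and r.p <= alpha else ""
            lines.append(
                f"{r.statistic:<22}{_fmt(r.observed):>10}{_fmt(r.null_mean):>10}"
                f"{_fmt(r.null_sd):>10}{_fmt(r.z, 2):>8}{_fmt(r.p, 3):>10}{star}"
            )
        lines.append("-" * 70)
        lines.append(f"* p <= {alpha} (one-tailed; tail per statistic)")
        return "\n".join(lines)


def _fmt(x: float, sig: int = 3) -> str:
    if x is None or not math.isfinite(x):
        return "N/A"
    if x == 0:
        return "0"
    if abs(x) >= 0.01:
        return f"{x:.{sig}g}"
    return f"{x:.{max(sig - 1, 1)}e}"
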