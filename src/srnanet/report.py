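"""Pipeline orchestration and table rendering.

Runs tier selection -> operon extension -> network mapping -> metric and
significance computation (and optionally the robustness analysis) for each
supplied network, and renders a per-network report whose rows are the
metrics and whose column groups are the analysis tiers with mean /
simulated mean / p-value, in the layout customary for this analysis.
Everything is deterministic given the configured seed, and the metadata
block records the conventions in force (normalisation, tie handling,
universe) so every cell is traceable.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .model import SrnaTargetTopology, _fmt
from .network import Network, load_network
from .permutation import StatResult
from .robustness import PerturbationSpec, sensitivity_suite
from .targets import (
    OperonTable,
    TargetMap,
    extend_by_operon,
    load_operons,
    load_target_table,
    select_evidence,
)

__all__ = ["TIERS", "PipelineConfig", "ReportTable", "build_tier_map",
           "run_pipeline", "render"]

#: the four standard analysis tiers: evidence labels kept, then whether
#: operon extension is applied (extension after selection, so the extended
#: experimental tier never inherits predicted-derived operon genes).
TIERS: Dict[str, Tuple[Tuple[str, ...], bool]] = {
    "experimental": (("experimental",), False),
    "experimental+predicted": (("experimental", "predicted"), False),
    "experimental+extended": (("experimental",), True),
    "all": (("experimental", "predicted"), True),
}

_METRIC_ORDER_UNDIRECTED = ("degree", "betweenness", "closeness",
                            "clustering_coefficient", "cpl", "density",
                            "in_degree_ratio")
_METRIC_ORDER_DIRECTED = ("in_degree", "out_degree", "betweenness",
                          "closeness", "density", "in_degree_ratio")


@dataclass
class PipelineConfig:
    """Everything one ``analyze`` run needs; at least one network path."""

    targets_path: str
    ppin_path: Optional[str] = None
    trn_path: Optional[str] = None
    operons_path: Optional[str] = None
    tiers: Sequence[str] = tuple(TIERS)
    n_sims: int = 1000
    seed: int = 0
    universe_mode: str = "network-nodes"
    universe_path: Optional[str] = None
    harmonic: bool = False
    robustness: Optional[Sequence[PerturbationSpec]] = None
    out_dir: str = "srnanet-report"
    alpha: float = 0.05

    def __post_init__(self):
        if self.ppin_path is None and self.trn_path is None:
            raise ValueError("at least one network must be supplied")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        unknown = set(self.tiers) - set(TIERS)
        if unknown:
            raise ValueError(f"unknown tiers: {sorted(unknown)}")


@dataclass
class ReportTable:
    """Per-network, per-tier significance blocks plus provenance."""

    blocks: Dict[str, Dict[str, List[StatResult]]]
    coverage: Dict[str, Dict[str, dict]]
    metadata: dict
    robustness: Optional[pd.DataFrame] = None

    def to_json_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "coverage": self.coverage,
            "results": {
                net: {tier: [r.to_dict() for r in res]
                      for tier, res in tiers.items()}
                for net, tiers in self.blocks.items()
            },
        }


def build_tier_map(
    tmap: TargetMap,
    tier: str,
    operons: Optional[OperonTable],
) -> TargetMap:
    """Apply one named tier: evidence selection, then optional extension."""
    labels, extend = TIERS[tier]
    selected = select_evidence(tmap, labels)
    if extend:
        if operons is None:
            raise ValueError(f"tier {tier!r} needs an operon table")
        selected = extend_by_operon(selected, operons)
    return selected


def _tier_seed(base: int, net_i: int, tier_i: int) -> int:
    ss = np.random.SeedSequence(entropy=base, spawn_key=(net_i, tier_i))
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(cfg: PipelineConfig) -> ReportTable:
    """Run every (network, tier) block and write the report files.

    Writes ``report.tsv``, ``report.json`` and ``report.md`` (plus
    ``robustness.tsv`` when configured) under ``cfg.out_dir``.  Partial
    failures isolate to their cell as N/A.  Byte-identical output for
    identical configuration and seed.
    """
    full_map = load_target_table(cfg.targets_path)
    operons = load_operons(cfg.operons_path) if cfg.operons_path else None
    universe = None
    if cfg.universe_path:
        with open(cfg.universe_path, "r", encoding="utf-8") as fh:
            universe = [ln.strip() for ln in fh if ln.strip()
                        and not ln.startswith("#")]

    networks: List[Tuple[str, Network]] = []
    if cfg.ppin_path:
        networks.append(("ppin", load_network(cfg.ppin_path, directed=False)))
    if cfg.trn_path:
        networks.append(("trn", load_network(cfg.trn_path, directed=True)))

    blocks: Dict[str, Dict[str, List[StatResult]]] = {}
    coverage: Dict[str, Dict[str, dict]] = {}
    rob_frames = []
    for ni, (name, net) in enumerate(networks):
        blocks[name] = {}
        coverage[name] = {}
        for ti, tier in enumerate(cfg.tiers):
            tier_map = build_tier_map(full_map, tier, operons)
            model = SrnaTargetTopology(
                net, tier_map, universe_mode=cfg.universe_mode,
                universe=universe, harmonic=cfg.harmonic,
            )
            res = model.fit(n_sims=cfg.n_sims,
                            seed=_tier_seed(cfg.seed, ni, ti))
            blocks[name][tier] = res.results
            coverage[name][tier] = {
                "pairs": tier_map.n_pairs,
                "targets_in_network": model.n_targets_in_network,
                "eligible_srnas": len(model.eligible_srnas),
            }
        if cfg.robustness:
            tier_map = build_tier_map(full_map, cfg.tiers[0], operons)
            frame = sensitivity_suite(
                net, tier_map, cfg.robustness, n_sims=cfg.n_sims,
                seed=_tier_seed(cfg.seed, ni, 999), alpha=cfg.alpha,
                universe_mode=cfg.universe_mode, universe=universe,
                harmonic=cfg.harmonic,
            )
            frame.insert(0, "network", name)
            rob_frames.append(frame)

    metadata = {
        "srnanet_version": __version__,
        "seed": cfg.seed,
        "n_sims": cfg.n_sims,
        "universe_mode": cfg.universe_mode,
        "alpha": cfg.alpha,
        "tiers": list(cfg.tiers),
        "conventions": {
            "closeness": "harmonic" if cfg.harmonic else
                         "reciprocal mean distance over reachable nodes",
            "betweenness": "fractional multiplicity, normalized to [0,1]",
            "in_degree_ratio": "raw within/boundary edge-count ratio",
            "cpl": "mean over connected target pairs",
            "p_value": "(1+r)/(N+1), ties extreme, one-tailed",
            "subnet_null": "per-sRNA size multiset preserved",
            "rounding": "perturbation counts round half away from zero",
        },
    }
    report = ReportTable(
        blocks, coverage, metadata,
        robustness=pd.concat(rob_frames, ignore_index=True) if rob_frames else None,
    )
    os.makedirs(cfg.out_dir, exist_ok=True)
    for fmt in ("tsv", "json", "markdown"):
        ext = {"tsv": "tsv", "json": "json", "markdown": "md"}[fmt]
        render(report, fmt, os.path.join(cfg.out_dir, f"report.{ext}"),
               alpha=cfg.alpha)
    if report.robustness is not None:
        report.robustness.to_csv(
            os.path.join(cfg.out_dir, "robustness.tsv"), sep="\t", index=False
        )
    return report


def render(report: ReportTable, fmt: str, path: str, alpha: float = 0.05) -> None:
    """Render a report as lossless ``tsv``/``json`` or ``markdown``.

    Markdown mirrors the customary table layout — metric rows, tier column
    groups — with significant cells (p <= alpha) in boldface and undefined
    cells as N/A.
    """
    if fmt == "tsv":
        rows = []
        for net, tiers in report.blocks.items():
            for tier, results in tiers.items():
                for r in results:
                    rows.append({"network": net, "tier": tier, **r.to_dict()})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True,
                      allow_nan=True, default=str)
            fh.write("\n")
    elif fmt == "markdown":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# sRNA target topology report\n")
            for net, tiers in report.blocks.items():
                order = (_METRIC_ORDER_DIRECTED if net == "trn"
                         else _METRIC_ORDER_UNDIRECTED)
                tier_names = list(tiers)
                fh.write(f"\n## {net}\n\n")
                header = ["metric"]
                for t in tier_names:
                    header += [f"{t} mean", f"{t} sim.mean", f"{t} p"]
                fh.write("| " + " | ".join(header) + " |\n")
                fh.write("|" + "---|" * len(header) + "\n")
                for metric in order:
                    cells = [metric]
                    for t in tier_names:
                        r = next((x for x in tiers[t] if x.statistic == metric),
                                 None)
                        if r is None:
                            cells += ["N/A"] * 3
                            continue
                        sig = math.isfinite(r.p) and r.p <= alpha
                        wrap = (lambda s: f"**{s}**") if sig else (lambda s: s)
                        cells += [wrap(_fmt(r.observed)),
                                  wrap(_fmt(r.null_mean)),
                                  wrap(_fmt(r.p, 3))]
                    fh.write("| " + " | ".join(cells) + " |\n")
                cov = report.coverage.get(net, {})
                if cov:
                    fh.write("\ncoverage: " + "; ".join(
                        f"{t}: {c['targets_in_network']} targets in network, "
                        f"{c['eligible_srnas']} eligible sRNAs"
                        for t, c in cov.items()) + "\n")
            fh.write(f"\nseed: {report.metadata['seed']}, "
                     f"n_sims: {report.metadata['n_sims']}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
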