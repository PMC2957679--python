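"""Synthetic study generator: planted sRNA-target modules on random graphs.

A :class:`StudyBundle` emulates the statistical structure the analysis
assumes: a sparse undirected background interaction graph (the PPI
stand-in), a sparse directed regulatory graph (the TRN stand-in), per-sRNA
target sets whose *within-set* connectivity can be raised above background
(the planted module), and operons of consecutive genes for extension tests.

Planting resamples each within-set node pair: any background edge on the
pair is removed and the pair is reconnected with probability
``within_edge_prob``.  Consequently ``within_edge_prob`` *is* the final
within-set edge probability, and setting it equal to the background edge
probability yields an exact calibration null — planted and background
within-set edge counts are identically distributed.

Defaults (500 genes, 15 sRNAs with 2-8 targets, background edge
probability 0.01, within-set probability 0.3) are large enough for stable
null distributions yet small enough for seconds-scale simulation.  All
randomness flows from ``StudyConfig.seed``.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field, replace
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import yaml

from .network import Network, export_network, load_network
from .targets import OperonTable, TargetMap, load_operons, load_target_table

__all__ = ["StudyConfig", "StudyBundle", "generate_background",
           "plant_modules", "generate_operons", "generate_study", "load_study"]


@dataclass(frozen=True)
class StudyConfig:
    """Ground-truth parameters of one synthetic study."""

    n_genes: int = 500
    ppi_model: Tuple[str, float] = ("erdos-renyi", 0.01)
    trn_model: Tuple[str, float] = ("erdos-renyi", 0.004)
    n_srnas: int = 15
    targets_per_srna: Tuple[int, int] = (2, 8)
    within_edge_prob: float = 0.3
    trn_within_edge_prob: Optional[float] = None  # per ordered pair; None -> trn background p
    boundary_attachment: float = 0.0  # expected extra target->background edges
    operon_count: int = 30
    operon_size_range: Tuple[int, int] = (1, 5)
    fraction_predicted: float = 0.5
    plant_in_ppi: bool = True
    plant_in_trn: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_srnas < 0 or self.operon_count < 0:
            raise ValueError("counts must be positive")
        lo, hi = self.targets_per_srna
        if not (1 <= lo <= hi <= self.n_genes):
            raise ValueError("invalid targets_per_srna range")
        if not (0.0 <= self.within_edge_prob <= 1.0):
            raise ValueError("within_edge_prob must be in [0, 1]")
        if self.ppi_model[0] not in ("erdos-renyi", "preferential-attachment"):
            raise ValueError(f"unknown ppi model {self.ppi_model[0]!r}")
        if self.trn_model[0] != "erdos-renyi":
            raise ValueError("trn model must be erdos-renyi")
        olo, ohi = self.operon_size_range
        if self.operon_count * max(ohi, 1) > self.n_genes:
            raise ValueError("operons would exceed the gene universe")

    @classmethod
    def null(cls, **kwargs) -> "StudyConfig":
        """A calibration-null config: within-set probability == background."""
        cfg = cls(**kwargs)
        return replace(
            cfg,
            within_edge_prob=cfg.ppi_model[1],
            trn_within_edge_prob=cfg.trn_model[1],
            boundary_attachment=0.0,
        )

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        for key in ("ppi_model", "trn_model", "targets_per_srna", "operon_size_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class StudyBundle:
    ppin: Network
    trn: Network
    target_map: TargetMap
    operons: OperonTable
    truth: StudyConfig


def _gene_names(n: int) -> List[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(n)]


def generate_background(
    cfg: StudyConfig, rng: np.random.Generator
) -> Tuple[Network, Network]:
    """Background PPI (undirected) and TRN (directed) over one gene universe."""
    genes = _gene_names(cfg.n_genes)
    model, param = cfg.ppi_model
    ppi_seed = int(rng.integers(2**31))
    trn_seed = int(rng.integers(2**31))
    if model == "erdos-renyi":
        g = nx.fast_gnp_random_graph(cfg.n_genes, param, seed=ppi_seed)
    else:  # preferential-attachment
        g = nx.barabasi_albert_graph(cfg.n_genes, int(param), seed=ppi_seed)
    d = nx.fast_gnp_random_graph(cfg.n_genes, cfg.trn_model[1], seed=trn_seed,
                                 directed=True)
    relabel = dict(enumerate(genes))
    ppin = Network(nx.relabel_nodes(g, relabel))
    trn = Network(nx.relabel_nodes(d, relabel))
    return ppin, trn


def plant_modules(
    ppin: Network,
    trn: Network,
    cfg: StudyConfig,
    rng: np.random.Generator,
) -> TargetMap:
    """Draw per-sRNA target sets and resample their within-set edges in place.

    Target sets are sampled without replacement per sRNA but may overlap
    across sRNAs.  Each unordered within-set pair (union over sets) gets a
    PPI edge with probability ``within_edge_prob``; each ordered pair gets
    a TRN arc with probability ``trn_within_edge_prob`` (default: the TRN
    background probability, i.e. no directed planting signal).  Expected
    ``boundary_attachment`` extra edges per target attach it to random
    background genes.
    """
    genes = sorted(ppin.nodes)
    lo, hi = cfg.targets_per_srna
    tmap = TargetMap()
    sets: List[List[str]] = []
    for i in range(cfg.n_srnas):
        k = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(genes), size=k, replace=False)
        targets = [genes[j] for j in idx]
        sets.append(targets)
        srna = f"srna{i:02d}"
        for t in targets:
            ev = "predicted" if rng.random() < cfg.fraction_predicted else "experimental"
            tmap.add(srna, t, ev)

    pairs = sorted({tuple(sorted(p)) for s in sets for p in combinations(s, 2)})
    w_trn = (cfg.trn_within_edge_prob
             if cfg.trn_within_edge_prob is not None else cfg.trn_model[1])
    for u, v in pairs:
        if cfg.plant_in_ppi:
            if ppin.g.has_edge(u, v):
                ppin.g.remove_edge(u, v)
            if rng.random() < cfg.within_edge_prob:
                ppin.g.add_edge(u, v)
        if cfg.plant_in_trn:
            for a, b in ((u, v), (v, u)):
                if trn.g.has_edge(a, b):
                    trn.g.remove_edge(a, b)
                if rng.random() < w_trn:
                    trn.g.add_edge(a, b)
    if cfg.boundary_attachment > 0:
        target_set = {t for s in sets for t in s}
        outside = [g for g in genes if g not in target_set]
        for t in sorted(target_set):
            for _ in range(rng.poisson(cfg.boundary_attachment)):
                other = outside[int(rng.integers(len(outside)))]
                ppin.g.add_edge(t, other)
    return tmap


def generate_operons(
    cfg: StudyConfig,
    rng: np.random.Generator,
    target_map: Optional[TargetMap] = None,
) -> OperonTable:
    """Disjoint ordered gene runs, sizes uniform in ``operon_size_range``.

    When a target map is supplied, roughly half the operons are seeded to
    start with a planted target (a non-terminal position for sizes >= 2),
    so operon extension is actually exercised.
    """
    genes = _gene_names(cfg.n_genes)
    lo, hi = cfg.operon_size_range
    used: set = set()
    operons: List[List[str]] = []
    seeds: List[str] = []
    if target_map is not None:
        all_targets = sorted(target_map.unique_targets())
        n_seeded = min(len(all_targets), cfg.operon_count // 2)
        if n_seeded:
            idx = rng.choice(len(all_targets), size=n_seeded, replace=False)
            seeds = [all_targets[i] for i in sorted(idx)]
    free = [g for g in genes if g not in seeds]
    rng.shuffle(free)
    cursor = 0
    for i in range(cfg.operon_count):
        size = int(rng.integers(lo, hi + 1))
        op: List[str] = []
        if i < len(seeds):
            op.append(seeds[i])
        while len(op) < size and cursor < len(free):
            g = free[cursor]
            cursor += 1
            if g not in used and g not in seeds:
                op.append(g)
        used.update(op)
        if op:
            operons.append(op)
    return OperonTable(operons)


def generate_study(cfg: StudyConfig, out_dir: Optional[str] = None) -> StudyBundle:
    """Generate a complete reproducible study; optionally write its files.

    Files written: ``ppin.tsv``, ``trn.tsv`` (edge lists), ``targets.tsv``
    (srna, target, evidence), ``operons.tsv``, ``config.yaml`` — exactly
    the dialects the loaders consume, so a round trip reproduces the
    in-memory bundle.
    """
    rng = np.random.default_rng(cfg.seed)
    ppin, trn = generate_background(cfg, rng)
    tmap = plant_modules(ppin, trn, cfg, rng)
    operons = generate_operons(cfg, rng, tmap)
    bundle = StudyBundle(ppin, trn, tmap, operons, cfg)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        _write_edges(ppin, os.path.join(out_dir, "ppin.tsv"))
        _write_edges(trn, os.path.join(out_dir, "trn.tsv"))
        with open(os.path.join(out_dir, "targets.tsv"), "w", encoding="utf-8") as fh:
            for srna, gene, ev in tmap.pairs():
                fh.write(f"{srna}\t{gene}\t{ev}\n")
        with open(os.path.join(out_dir, "operons.tsv"), "w", encoding="utf-8") as fh:
            for i, op in enumerate(operons.operons):
                fh.write(f"op{i:03d}\t{','.join(op)}\n")
        cfg.to_yaml(os.path.join(out_dir, "config.yaml"))
    return bundle


def _write_edges(net: Network, path: str) -> None:
    # isolated nodes go to a side-car file so the 2-column dialect stays clean
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(net.edge_set()):
            fh.write(f"{u}\t{v}\n")
    isolated = sorted(net.nodes - {n for e in net.edge_set() for n in e})
    if isolated:
        with open(path + ".nodes", "w", encoding="utf-8") as fh:
            for v in isolated:
                fh.write(v + "\n")


def load_study(in_dir: str) -> StudyBundle:
    """Load a study written by :func:`generate_study`."""
    cfg = StudyConfig.from_yaml(os.path.join(in_dir, "config.yaml"))
    ppin_path = os.path.join(in_dir, "ppin.tsv")
    trn_path = os.path.join(in_dir, "trn.tsv")
    ppin = load_network(ppin_path, directed=False,
                        node_list=_sidecar(ppin_path))
    trn = load_network(trn_path, directed=True, node_list=_sidecar(trn_path))
    tmap = load_target_table(os.path.join(in_dir, "targets.tsv"))
    operons = load_operons(os.path.join(in_dir, "operons.tsv"))
    return StudyBundle(ppin, trn, tmap, operons, cfg)


def _sidecar(path: str) -> Optional[str]:
    side = path + ".nodes"
    return side if os.path.exists(side) else None
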