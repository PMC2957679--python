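"""sRNA target-set assembly: loading, operon extension, network mapping.

A :class:`TargetMap` holds (sRNA, target gene) pairs with an evidence label
per pair — ``experimental`` (validated interactions), ``predicted``
(ingested from external target-prediction output), or the ``extended-*``
labels that operon extension attaches to downstream genes.  Because an
sRNA acts on an mRNA, silencing one gene of an operon can propagate to the
genes transcribed after it; ``extend_by_operon`` therefore adds every gene
strictly downstream of a target within its operon (gadB -> gadC, lexA ->
dinF are the canonical examples), never upstream genes.

The four standard analysis tiers (experimental; experimental+predicted;
each with operon extension) are defined in :mod:`srnanet.report`.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Set, Tuple

from .network import Network

__all__ = [
    "EVIDENCE_LABELS",
    "TargetMap",
    "OperonTable",
    "TargetParseError",
    "load_target_pairs",
    "load_target_table",
    "load_operons",
    "extend_by_operon",
    "map_to_network",
    "select_evidence",
]

EVIDENCE_LABELS = (
    "experimental",
    "predicted",
    "extended-experimental",
    "extended-predicted",
)

# when the same pair arrives under two labels, the stronger evidence wins
_EVIDENCE_RANK = {label: i for i, label in enumerate(EVIDENCE_LABELS)}


class TargetParseError(ValueError):
    pass


class TargetMap:
    """Mapping sRNA id -> {target gene id: evidence label}, pairs unique."""

    def __init__(self, entries: Optional[Dict[str, Dict[str, str]]] = None) -> None:
        self._entries: Dict[str, Dict[str, str]] = {}
        if entries:
            for srna, targets in entries.items():
                for gene, ev in targets.items():
                    self.add(srna, gene, ev)

    def add(self, srna: str, gene: str, evidence: str) -> None:
        if evidence not in EVIDENCE_LABELS:
            raise ValueError(f"unknown evidence label {evidence!r}")
        bucket = self._entries.setdefault(srna, {})
        old = bucket.get(gene)
        if old is None or _EVIDENCE_RANK[evidence] < _EVIDENCE_RANK[old]:
            bucket[gene] = evidence

    # -- queries ----------------------------------------------------------

    @property
    def srnas(self) -> FrozenSet[str]:
        return frozenset(self._entries)

    def targets_of(self, srna: str) -> FrozenSet[str]:
        return frozenset(self._entries.get(srna, ()))

    def evidence_of(self, srna: str, gene: str) -> str:
        return self._entries[srna][gene]

    def pairs(self) -> Iterator[Tuple[str, str, str]]:
        """Yield (srna, gene, evidence) in deterministic order."""
        for srna in sorted(self._entries):
            for gene in sorted(self._entries[srna]):
                yield srna, gene, self._entries[srna][gene]

    @property
    def n_pairs(self) -> int:
        return sum(len(v) for v in self._entries.values())

    def unique_targets(self) -> FrozenSet[str]:
        out: Set[str] = set()
        for targets in self._entries.values():
            out.update(targets)
        return frozenset(out)

    def merged(self, other: "TargetMap") -> "TargetMap":
        out = TargetMap()
        for m in (self, other):
            for srna, gene, ev in m.pairs():
                out.add(srna, gene, ev)
        return out

    def __len__(self) -> int:
        return self.n_pairs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TargetMap):
            return NotImplemented
        return self._entries == other._entries

    def __repr__(self) -> str:
        return f"<TargetMap: {len(self.srnas)} sRNAs, {self.n_pairs} pairs>"


class OperonTable:
    """Ordered gene lists in transcription order (upstream -> downstream).

    Genes are unique within an operon and appear in at most one operon.
    """

    def __init__(self, operons: Iterable[Iterable[str]]) -> None:
        self.operons: List[Tuple[str, ...]] = [tuple(op) for op in operons]
        self._position: Dict[str, Tuple[int, int]] = {}
        for i, op in enumerate(self.operons):
            if len(set(op)) != len(op):
                raise ValueError(f"operon {i} contains a duplicated gene: {op}")
            for j, gene in enumerate(op):
                if gene in self._position:
                    raise ValueError(f"gene {gene!r} appears in more than one operon")
                self._position[gene] = (i, j)

    def downstream_of(self, gene: str) -> Tuple[str, ...]:
        """Genes strictly after ``gene`` in its operon (empty if not in one)."""
        pos = self._position.get(gene)
        if pos is None:
            return ()
        i, j = pos
        return self.operons[i][j + 1:]

    def __len__(self) -> int:
        return len(self.operons)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OperonTable):
            return NotImplemented
        return self.operons == other.operons


# ---------------------------------------------------------------------------
# loading


def _data_rows(path: str) -> Iterator[Tuple[int, List[str]]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def load_target_pairs(path: str, evidence_label: str = "experimental") -> TargetMap:
    """Load 2-column (sRNA, target) TSV rows under one evidence label.

    Extra columns (e.g. prediction scores) are ignored; duplicates are
    collapsed.
    """
    tmap = TargetMap()
    for lineno, fields in _data_rows(path):
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise TargetParseError(f"{path}:{lineno}: expected srna<TAB>target")
        tmap.add(fields[0], fields[1], evidence_label)
    return tmap


def load_target_table(path: str) -> TargetMap:
    """Load a 3-column (sRNA, target, evidence) TSV."""
    tmap = TargetMap()
    for lineno, fields in _data_rows(path):
        if len(fields) < 3:
            raise TargetParseError(
                f"{path}:{lineno}: expected srna<TAB>target<TAB>evidence"
            )
        try:
            tmap.add(fields[0], fields[1], fields[2])
        except ValueError as exc:
            raise TargetParseError(f"{path}:{lineno}: {exc}") from exc
    return tmap


def load_operons(path: str) -> OperonTable:
    """Load operons from ``operon_id<TAB>gene1,gene2,...`` TSV rows."""
    ops = []
    for lineno, fields in _data_rows(path):
        if len(fields) < 2:
            raise TargetParseError(
                f"{path}:{lineno}: expected operon_id<TAB>comma-separated genes"
            )
        genes = [g for g in fields[1].split(",") if g]
        if not genes:
            raise TargetParseError(f"{path}:{lineno}: empty gene list")
        ops.append(genes)
    return OperonTable(ops)


# ---------------------------------------------------------------------------
# transforms


def extend_by_operon(tmap: TargetMap, operons: OperonTable) -> TargetMap:
    """Add operon genes strictly downstream of each target.

    Added pairs carry ``extended-experimental`` / ``extended-predicted``
    according to the evidence of the source pair; existing pairs are
    retained unchanged.  Idempotent for a fixed operon table.
    """
    out = TargetMap()
    for srna, gene, ev in tmap.pairs():
        out.add(srna, gene, ev)
        base = ev.removeprefix("extended-")
        for down in operons.downstream_of(gene):
            out.add(srna, down, f"extended-{base}")
    return out


def map_to_network(tmap: TargetMap, net: Network) -> Tuple[TargetMap, Dict[str, Dict[str, int]]]:
    """Drop targets absent from the network; report per-evidence coverage.

    Returns ``(filtered map, coverage)`` where coverage maps evidence label
    to ``{"pairs": total pairs, "in_network": retained pairs}``.  sRNAs left
    with no in-network target disappear from the filtered map.
    """
    out = TargetMap()
    coverage: Dict[str, Dict[str, int]] = {
        ev: {"pairs": 0, "in_network": 0} for ev in EVIDENCE_LABELS
    }
    for srna, gene, ev in tmap.pairs():
        coverage[ev]["pairs"] += 1
        if gene in net:
            coverage[ev]["in_network"] += 1
            out.add(srna, gene, ev)
    return out, coverage


def select_evidence(tmap: TargetMap, tiers: Iterable[str]) -> TargetMap:
    """Keep only pairs whose evidence label is in ``tiers``."""
    tiers = set(tiers)
    unknown = tiers - set(EVIDENCE_LABELS)
    if unknown:
        raise ValueError(f"unknown evidence labels: {sorted(unknown)}")
    if not tiers:
        raise ValueError("tiers must be non-empty")
    out = TargetMap()
    for srna, gene, ev in tmap.pairs():
        if ev in tiers:
            out.add(srna, gene, ev)
    return out
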