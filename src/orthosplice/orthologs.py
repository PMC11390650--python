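"""Matching lifted source-species splice events to target-species events.

Two events are candidate orthologs when they lie on the same chromosome and
strand, are of the same event type, belong to a 1:1 orthologous gene pair
(when a gene map is supplied), and all four boundary coordinates agree to
within a tolerance (10 bp by default, inclusive).  Among candidates a 1:1
assignment is chosen greedily by ascending total absolute boundary offset,
with deterministic tie-breaking on source coordinates; on realistic inputs
(events further apart than the tolerance) this equals the minimum-weight
assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .events import SpliceEvent

__all__ = [
    "OrthologPair",
    "OrthologyRates",
    "read_ortholog_map",
    "match_events",
    "orthology_rates",
]


@dataclass(frozen=True)
class OrthologPair:
    source_event_id: str
    target_event_id: str
    source_gene_id: str
    target_gene_id: str
    offsets: tuple[int, int, int, int]  # per boundary, signed (target - source)

    @property
    def total_offset(self) -> int:
        return sum(abs(o) for o in self.offsets)


@dataclass(frozen=True)
class OrthologyRates:
    n_matched: int
    source_total: int
    target_total: int
    source_rate: float | None
    target_rate: float | None


def read_ortholog_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV source_gene_id → target_gene_id, strictly 1:1."""
    mapping: dict[str, str] = {}
    seen_targets: set[str] = set()
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            src, tgt = parts
            if src in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate source gene {src}")
            if tgt in seen_targets:
                raise ValueError(f"{path}:{lineno}: duplicate target gene {tgt}")
            mapping[src] = tgt
            seen_targets.add(tgt)
    return mapping


def _check_unique_ids(events: Sequence[SpliceEvent], label: str) -> None:
    seen: set[str] = set()
    for ev in events:
        if ev.event_id in seen:
            raise ValueError(f"duplicate {label} event id {ev.event_id}")
        seen.add(ev.event_id)


def match_events(
    lifted_source: Sequence[SpliceEvent],
    target: Sequence[SpliceEvent],
    tolerance: int = 10,
    ortholog_map: Mapping[str, str] | None = None,
) -> list[OrthologPair]:
    """1:1 match lifted source events to target events within ``tolerance``.

    Output is sorted by target-event coordinates and is invariant to the
    order of the input lists.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    _check_unique_ids(lifted_source, "source")
    _check_unique_ids(target, "target")

    if ortholog_map is not None:
        lifted_source = [e for e in lifted_source if e.gene_id in ortholog_map]
        valid_target_genes = set(ortholog_map.values())
        target = [e for e in target if e.gene_id in valid_target_genes]

    # bucket targets for candidate generation
    buckets: dict[tuple, list[SpliceEvent]] = {}
    for ev in target:
        buckets.setdefault((ev.chrom, ev.strand, ev.event_type), []).append(ev)

    candidates: list[tuple[int, tuple, str, str, OrthologPair]] = []
    for src in lifted_source:
        expect_gene = ortholog_map.get(src.gene_id) if ortholog_map is not None else None
        for tgt in buckets.get((src.chrom, src.strand, src.event_type), []):
            if expect_gene is not None and tgt.gene_id != expect_gene:
                continue
            offsets = tuple(t - s for s, t in zip(src.boundaries, tgt.boundaries))
            if any(abs(o) > tolerance for o in offsets):
                continue
            pair = OrthologPair(
                source_event_id=src.event_id, target_event_id=tgt.event_id,
                source_gene_id=src.gene_id, target_gene_id=tgt.gene_id,
                offsets=offsets,
            )
            sort_key = (pair.total_offset, src.chrom, src.boundaries,
                        src.event_id, tgt.event_id)
            candidates.append((pair.total_offset, sort_key, src.event_id,
                               tgt.event_id, pair))

    candidates.sort(key=lambda c: c[1])
    used_source: set[str] = set()
    used_target: set[str] = set()
    matched: list[OrthologPair] = []
    for _, _, sid, tid, pair in candidates:
        if sid in used_source or tid in used_target:
            continue
        used_source.add(sid)
        used_target.add(tid)
        matched.append(pair)

    target_coords = {ev.event_id: (ev.chrom, ev.boundaries) for ev in target}
    matched.sort(key=lambda p: target_coords[p.target_event_id])
    return matched


def orthology_rates(
    matched: Sequence[OrthologPair], source_total: int, target_total: int
) -> OrthologyRates:
    """Fraction of each species' events that found an orthologous partner."""
    n = len(matched)
    if n > min(source_total, target_total):
        raise ValueError("matched count exceeds a species total")
    return OrthologyRates(
        n_matched=n,
        source_total=source_total,
        target_total=target_total,
        source_rate=(n / source_total) if source_total > 0 else None,
        target_rate=(n / target_total) if target_total > 0 else None,
    )
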