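"""UCSC chain-file parsing and coordinate lifting between genome assemblies.

A chain describes a gapped pairwise alignment between a *target* genome (the
coordinate system being lifted FROM, ``t``) and a *query* genome (lifted TO,
``q``).  Block lines carry an aligned block size followed, except on the last
line, by ``dt`` and ``dq`` — unaligned gaps on the target and query side
before the next block.  When ``q_strand`` is ``-`` the query coordinates in
the file are expressed on the reversed query sequence; lifted positions are
always reported here on the forward strand of the query genome.

Only single positions and four-boundary event tuples are lifted; the 10-bp
matching tolerance applied downstream makes whole-interval (minMatch-style)
remapping unnecessary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .events import SpliceEvent

__all__ = [
    "ChainBlock",
    "Chain",
    "ChainSet",
    "ChainFormatError",
    "LiftedPosition",
    "LiftFailure",
    "parse_chain",
    "parse_chain_text",
    "lift_position",
    "lift_event",
]


class ChainFormatError(ValueError):
    pass


@dataclass(frozen=True)
class ChainBlock:
    size: int
    dt: int = 0  # gap on target side before next block (0 on last block)
    dq: int = 0  # gap on query side before next block


@dataclass(frozen=True)
class Chain:
    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: str
    blocks: tuple[ChainBlock, ...]

    def validate(self) -> None:
        if self.t_strand != "+":
            raise ChainFormatError(f"chain {self.chain_id}: target strand must be '+'")
        if self.q_strand not in ("+", "-"):
            raise ChainFormatError(f"chain {self.chain_id}: bad query strand {self.q_strand!r}")
        for b in self.blocks[:-1]:
            if b.size <= 0 or b.dt < 0 or b.dq < 0:
                raise ChainFormatError(f"chain {self.chain_id}: bad block {b}")
        if self.blocks[-1].size <= 0 or self.blocks[-1].dt or self.blocks[-1].dq:
            raise ChainFormatError(f"chain {self.chain_id}: last block must carry no gaps")
        t_span = sum(b.size + b.dt for b in self.blocks)
        q_span = sum(b.size + b.dq for b in self.blocks)
        if t_span != self.t_end - self.t_start:
            raise ChainFormatError(
                f"chain {self.chain_id}: blocks span {t_span} on target but header "
                f"declares {self.t_end - self.t_start}"
            )
        if q_span != self.q_end - self.q_start:
            raise ChainFormatError(
                f"chain {self.chain_id}: blocks span {q_span} on query but header "
                f"declares {self.q_end - self.q_start}"
            )
        if not (0 <= self.t_start < self.t_end <= self.t_size):
            raise ChainFormatError(f"chain {self.chain_id}: target span outside sequence")
        if not (0 <= self.q_start < self.q_end <= self.q_size):
            raise ChainFormatError(f"chain {self.chain_id}: query span outside sequence")

    def lift(self, pos: int) -> tuple[str, int | str, bool]:
        """Map a target position through this chain.

        Returns (q_name, forward-strand query position or "gap", strand_flip).
        ``pos`` must lie within [t_start, t_end).
        """
        flip = self.q_strand == "-"
        t_cursor = self.t_start
        q_cursor = self.q_start  # in file (possibly reversed) coordinates
        for block in self.blocks:
            if pos < t_cursor + block.size:
                q_pos = q_cursor + (pos - t_cursor)
                if flip:
                    q_pos = self.q_size - 1 - q_pos
                return self.q_name, q_pos, flip
            t_cursor += block.size + block.dt
            q_cursor += block.size + block.dq
            if pos < t_cursor:  # inside the dt gap just skipped
                return self.q_name, "gap", flip
        raise ValueError(f"position {pos} outside chain {self.chain_id} span")


class ChainSet:
    """Parsed chains with an interval index on target-genome coordinates."""

    def __init__(self, chains: Sequence[Chain]):
        self.chains = tuple(chains)
        self._trees: dict[str, IntervalTree] = {}
        for chain in self.chains:
            self._trees.setdefault(chain.t_name, IntervalTree()).addi(
                chain.t_start, chain.t_end, chain
            )

    def __len__(self) -> int:
        return len(self.chains)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Chain]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        found = [iv.data for iv in tree.overlap(start, end)]
        found.sort(key=lambda c: (-c.score, c.t_start, c.q_name))
        return found

    def covering(self, chrom: str, pos: int) -> list[Chain]:
        """Chains whose target span contains pos, best (highest score) first."""
        return self.overlapping(chrom, pos, pos + 1)


@dataclass(frozen=True)
class LiftedPosition:
    status: str  # mapped | unmapped | gap
    chrom: str | None = None
    pos: int | None = None
    strand_flip: bool = False
    chain_score_used: float | None = None

    def __post_init__(self) -> None:
        if (self.status == "mapped") != (self.pos is not None):
            raise ValueError("pos must be defined exactly when status == 'mapped'")


@dataclass(frozen=True)
class LiftFailure:
    event_id: str
    reason: str
    boundary_statuses: tuple[str, str, str, str]


def parse_chain_lines(lines: Iterable[str], source: str = "<chain>") -> ChainSet:
    chains: list[Chain] = []
    header: list[str] | None = None
    blocks: list[ChainBlock] = []

    def _finish() -> None:
        nonlocal header, blocks
        if header is None:
            return
        if not blocks:
            raise ChainFormatError(f"{source}: chain {header[-1]} has no blocks")
        (_, score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, chain_id) = header
        chain = Chain(
            score=float(score), t_name=t_name, t_size=int(t_size),
            t_strand=t_strand, t_start=int(t_start), t_end=int(t_end),
            q_name=q_name, q_size=int(q_size), q_strand=q_strand,
            q_start=int(q_start), q_end=int(q_end),
            chain_id=chain_id, blocks=tuple(blocks),
        )
        chain.validate()
        chains.append(chain)
        header, blocks = None, []

    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("chain"):
            _finish()
            fields = line.split()
            if len(fields) == 12:  # id column is optional in the wild
                fields.append(f"anon{len(chains)}")
            if len(fields) != 13:
                raise ChainFormatError(f"{source}: malformed chain header: {line!r}")
            header = fields
        else:
            parts = line.split()
            if header is None:
                raise ChainFormatError(f"{source}: block line before any chain header")
            if len(parts) == 3:
                blocks.append(ChainBlock(int(parts[0]), int(parts[1]), int(parts[2])))
            elif len(parts) == 1:
                blocks.append(ChainBlock(int(parts[0])))
            else:
                raise ChainFormatError(f"{source}: malformed block line: {line!r}")
    _finish()
    return ChainSet(chains)


def parse_chain(path: str | Path) -> ChainSet:
    path = Path(path)
    with path.open() as fh:
        return parse_chain_lines(fh, source=str(path))


def parse_chain_text(text: str) -> ChainSet:
    return parse_chain_lines(text.splitlines())


def lift_position(chains: ChainSet, chrom: str, pos: int) -> LiftedPosition:
    """Lift one 0-based target-genome position to the query genome.

    Among chains covering the position the highest-scoring one is used (ties
    broken by (t_start, q_name) for determinism).  A position falling in a
    target-side gap of the best chain reports status ``gap``.
    """
    covering = chains.covering(chrom, pos)
    if not covering:
        return LiftedPosition(status="unmapped")
    best = covering[0]
    q_name, q_pos, flip = best.lift(pos)
    if q_pos == "gap":
        return LiftedPosition(status="gap", chrom=q_name, strand_flip=flip,
                              chain_score_used=best.score)
    return LiftedPosition(status="mapped", chrom=q_name, pos=q_pos,
                          strand_flip=flip, chain_score_used=best.score)


def _lift_base_through(chain: Chain, pos: int) -> tuple[str, int | str, bool]:
    return chain.lift(pos)


def lift_event(chains: ChainSet, event: SpliceEvent,
               species: str | None = None) -> SpliceEvent | LiftFailure:
    """Lift all four event boundaries through a single best chain.

    End-type coordinates (half-open exclusive ends) are lifted as the last
    contained base then re-opened, so block edges do not produce off-by-one
    shifts.  Success requires all four boundaries mapped through the same
    chain onto one query chromosome with consistent (possibly uniformly
    flipped) order; on a flip the upstream/downstream roles are swapped so
    the lifted event again satisfies the boundary-order invariant.
    """
    b1, b2, b3, b4 = event.boundaries  # upstream_end, target_start, target_end, downstream_start
    # inner-edge base of each boundary: ends as end-1, starts as-is
    bases = (b1 - 1, b2, b3 - 1, b4)
    covering = chains.covering(event.chrom, bases[0])
    chain = None
    for cand in covering:
        if all(cand.t_start <= b < cand.t_end for b in bases):
            chain = cand
            break
    if chain is None:
        return LiftFailure(event.event_id, "no single chain covers all boundaries",
                           ("unmapped",) * 4)
    lifted = [chain.lift(b) for b in bases]
    statuses = tuple("gap" if q == "gap" else "mapped" for _, q, _ in lifted)
    if any(s != "mapped" for s in statuses):
        return LiftFailure(event.event_id, "boundary in alignment gap", statuses)
    q_names = {name for name, _, _ in lifted}
    if len(q_names) != 1:
        return LiftFailure(event.event_id, "boundaries map to different chromosomes", statuses)
    flip = lifted[0][2]
    q1, q2, q3, q4 = (q for _, q, _ in lifted)
    if not flip:
        coords = (q1 + 1, q2, q3 + 1, q4)  # upstream_end, target_start, target_end, downstream_start
        strand = event.strand
    else:
        # order reverses: old downstream flank becomes upstream
        coords = (q4 + 1, q3, q2 + 1, q1)
        strand = "-" if event.strand == "+" else "+"
    up_end, t_start, t_end, down_start = coords
    if not (up_end <= t_start < t_end <= down_start):
        return LiftFailure(event.event_id, "lifted boundaries violate event order", statuses)
    return SpliceEvent(
        event_id=event.event_id,
        species=species if species is not None else event.species,
        gene_id=event.gene_id, gene_symbol=event.gene_symbol,
        event_type=event.event_type, chrom=lifted[0][0], strand=strand,
        target_start=t_start, target_end=t_end,
        upstream_end=up_end, downstream_start=down_start,
    )
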