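"""Splice events, replicate junction counts and percent-spliced-in (PSI).

A cassette ("skipped") exon event is anchored by four genomic boundary
coordinates on one chromosome: the 3' end of the upstream flanking exon, the
start and end of the alternative exon, and the 5' start of the downstream
flanking exon.  Retained-intron events reuse the same boundary tuple with the
retained intron in place of the alternative exon.  All coordinates are
0-based, half-open on the genomic (forward) axis regardless of gene strand.

PSI is the length-normalised inclusion ratio computed from junction counts:

    psi = 100 * (I / lI) / (I / lI + S / lS)

where ``I`` and ``S`` are inclusion- and skipping-junction read counts and
``lI``, ``lS`` the corresponding effective junction lengths.  For
junction-count (JC) quantification of a cassette exon the inclusion isoform
spans two junctions and the skipping isoform one, hence the default effective
lengths ``lI=2``, ``lS=1``.  Replicates are aggregated as the arithmetic mean
of per-replicate PSI values, not from pooled counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "EventType",
    "Condition",
    "InclusionClass",
    "SpliceEvent",
    "ReplicateCounts",
    "PsiEstimate",
    "DialectError",
    "EventTableParseError",
    "read_event_table",
    "write_event_table",
    "compute_psi",
    "classify_psi",
    "filter_expressed",
    "DEFAULT_INCLUSION_EFF_LEN",
    "DEFAULT_SKIPPING_EFF_LEN",
]

DEFAULT_INCLUSION_EFF_LEN = 2.0
DEFAULT_SKIPPING_EFF_LEN = 1.0


class EventType(str, Enum):
    SE = "SE"  # skipped (cassette) exon
    RI = "RI"  # retained intron


class Condition(str, Enum):
    basal = "basal"
    stimulated = "stimulated"


class InclusionClass(str, Enum):
    PI = "PI"  # primarily included, PSI > 80
    PS = "PS"  # primarily skipped, PSI < 20
    AS = "AS"  # alternatively spliced, 20 < PSI < 80


class DialectError(ValueError):
    """Raised when a table header does not match the declared dialect."""


class EventTableParseError(ValueError):
    """Raised for malformed rows; carries the offending 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


@dataclass(frozen=True)
class SpliceEvent:
    event_id: str
    species: str
    gene_id: str
    gene_symbol: str
    event_type: EventType
    chrom: str
    strand: str
    target_start: int
    target_end: int
    upstream_end: int
    downstream_start: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"{self.event_id}: empty chromosome name")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.event_id}: strand must be '+' or '-'")
        coords = (self.upstream_end, self.target_start, self.target_end, self.downstream_start)
        if any(c < 0 for c in coords):
            raise ValueError(f"{self.event_id}: negative coordinate in {coords}")
        if not (self.upstream_end <= self.target_start < self.target_end <= self.downstream_start):
            raise ValueError(
                f"{self.event_id}: boundary order violated "
                f"(upstream_end={self.upstream_end}, target={self.target_start}-{self.target_end}, "
                f"downstream_start={self.downstream_start})"
            )

    @property
    def boundaries(self) -> tuple[int, int, int, int]:
        """(upstream_end, target_start, target_end, downstream_start)."""
        return (self.upstream_end, self.target_start, self.target_end, self.downstream_start)


@dataclass(frozen=True)
class ReplicateCounts:
    event_id: str
    condition: Condition
    inclusion_counts: tuple[int, ...]
    skipping_counts: tuple[int, ...]
    inclusion_eff_len: float = DEFAULT_INCLUSION_EFF_LEN
    skipping_eff_len: float = DEFAULT_SKIPPING_EFF_LEN

    def __post_init__(self) -> None:
        object.__setattr__(self, "inclusion_counts", tuple(int(c) for c in self.inclusion_counts))
        object.__setattr__(self, "skipping_counts", tuple(int(c) for c in self.skipping_counts))
        if len(self.inclusion_counts) != len(self.skipping_counts):
            raise ValueError(f"{self.event_id}: unequal replicate vectors")
        if len(self.inclusion_counts) < 1:
            raise ValueError(f"{self.event_id}: at least one replicate required")
        if any(c < 0 for c in self.inclusion_counts + self.skipping_counts):
            raise ValueError(f"{self.event_id}: negative count")
        if self.inclusion_eff_len <= 0 or self.skipping_eff_len <= 0:
            raise ValueError(f"{self.event_id}: effective lengths must be positive")

    @property
    def n_replicates(self) -> int:
        return len(self.inclusion_counts)


@dataclass(frozen=True)
class PsiEstimate:
    event_id: str
    condition: Condition
    psi_per_replicate: tuple[float | None, ...]
    mean_psi: float | None
    n_replicates: int

    @property
    def quantifiable(self) -> bool:
        return self.mean_psi is not None


def compute_psi(counts: ReplicateCounts) -> PsiEstimate:
    """Length-normalised PSI per replicate and their arithmetic mean.

    A replicate with zero inclusion and zero skipping counts is undefined and
    excluded from the mean; if every replicate is undefined the event is
    unquantifiable (``mean_psi is None``).
    """
    li, ls = counts.inclusion_eff_len, counts.skipping_eff_len
    psis: list[float | None] = []
    for i, s in zip(counts.inclusion_counts, counts.skipping_counts):
        if i == 0 and s == 0:
            psis.append(None)
        else:
            ni, ns = i / li, s / ls
            psis.append(100.0 * ni / (ni + ns))
    defined = [p for p in psis if p is not None]
    mean = sum(defined) / len(defined) if defined else None
    return PsiEstimate(
        event_id=counts.event_id,
        condition=counts.condition,
        psi_per_replicate=tuple(psis),
        mean_psi=mean,
        n_replicates=counts.n_replicates,
    )


def classify_psi(mean_psi: float) -> InclusionClass:
    """Classify a mean PSI as PI (>= 80), PS (<= 20) or AS (in between).

    The outer bins are closed so the three classes partition [0, 100].
    """
    if mean_psi is None or isinstance(mean_psi, float) and math.isnan(mean_psi):
        raise ValueError("cannot classify an undefined PSI")
    if not 0.0 <= mean_psi <= 100.0:
        raise ValueError(f"PSI {mean_psi} outside [0, 100]")
    if mean_psi >= 80.0:
        return InclusionClass.PI
    if mean_psi <= 20.0:
        return InclusionClass.PS
    return InclusionClass.AS


def filter_expressed(
    counts: Iterable[ReplicateCounts],
    min_count: int = 5,
    rule: str = "all_samples",
) -> set[str]:
    """Event ids whose junction support clears ``min_count``.

    ``all_samples``: max(inclusion, skipping) strictly exceeds ``min_count``
    in every replicate of every supplied condition.  ``mean_over_samples``:
    the mean over all supplied samples of max(inclusion, skipping) strictly
    exceeds ``min_count``.  Both variants exist because differential calls
    use the per-sample rule while enrichment backgrounds use the averaged
    rule.
    """
    if rule not in ("all_samples", "mean_over_samples"):
        raise ValueError(f"unknown rule {rule!r}")
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    per_event: dict[str, list[int]] = {}
    for rc in counts:
        maxima = [max(i, s) for i, s in zip(rc.inclusion_counts, rc.skipping_counts)]
        per_event.setdefault(rc.event_id, []).extend(maxima)
    kept: set[str] = set()
    for event_id, maxima in per_event.items():
        if rule == "all_samples":
            if all(m > min_count for m in maxima):
                kept.add(event_id)
        else:
            if sum(maxima) / len(maxima) > min_count:
                kept.add(event_id)
    return kept


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------

RMATS_JC_COLUMNS = [
    "ID", "GeneID", "geneSymbol", "chr", "strand",
    "exonStart_0base", "exonEnd", "upstreamES", "upstreamEE",
    "downstreamES", "downstreamEE",
    "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2",
    "IncFormLen", "SkipFormLen", "PValue", "FDR",
    "IncLevel1", "IncLevel2", "IncLevelDifference",
]

INTERNAL_COLUMNS = [
    "event_id", "species", "gene_id", "gene_symbol", "event_type", "chrom",
    "strand", "target_start", "target_end", "upstream_end", "downstream_start",
    "basal_inclusion", "basal_skipping", "stim_inclusion", "stim_skipping",
    "inclusion_eff_len", "skipping_eff_len",
    "basal_mean_psi", "stim_mean_psi",
]


def _parse_count_vector(text: str, line: int, column: str) -> tuple[int, ...]:
    out = []
    for tok in text.strip().split(","):
        tok = tok.strip()
        if tok in ("", "NA"):
            continue
        try:
            out.append(int(tok))
        except ValueError:
            raise EventTableParseError(f"non-integer count {tok!r} in {column}", line)
    if not out:
        raise EventTableParseError(f"empty count vector in {column}", line)
    return tuple(out)


def read_event_table(
    path: str | Path,
    dialect: str = "rmats_jc",
    species: str = "unknown",
    event_type: EventType = EventType.SE,
) -> tuple[list[SpliceEvent], list[ReplicateCounts]]:
    """Read an event table in ``rmats_jc`` or ``internal_tsv`` dialect.

    In the rmats_jc dialect SAMPLE_1 is the basal condition and SAMPLE_2 the
    stimulated one.  Rows violating event invariants raise a parse error with
    their line number.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if dialect == "rmats_jc":
            if header != RMATS_JC_COLUMNS:
                raise DialectError(
                    f"{path}: header does not match rmats_jc dialect "
                    f"(got {header[:5]}...)"
                )
            return _read_rmats(fh, species, event_type)
        elif dialect == "internal_tsv":
            if header != INTERNAL_COLUMNS:
                raise DialectError(f"{path}: header does not match internal_tsv dialect")
            return _read_internal(fh)
        raise ValueError(f"unknown dialect {dialect!r}")


def _read_rmats(fh, species: str, event_type: EventType):
    events: list[SpliceEvent] = []
    counts: list[ReplicateCounts] = []
    for lineno, raw in enumerate(fh, start=2):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) != len(RMATS_JC_COLUMNS):
            raise EventTableParseError(
                f"expected {len(RMATS_JC_COLUMNS)} columns, got {len(fields)}", lineno
            )
        row = dict(zip(RMATS_JC_COLUMNS, fields))
        try:
            event = SpliceEvent(
                event_id=row["ID"],
                species=species,
                gene_id=row["GeneID"],
                gene_symbol=row["geneSymbol"],
                event_type=event_type,
                chrom=row["chr"],
                strand=row["strand"],
                target_start=int(row["exonStart_0base"]),
                target_end=int(row["exonEnd"]),
                upstream_end=int(row["upstreamEE"]),
                downstream_start=int(row["downstreamES"]),
            )
        except ValueError as exc:
            raise EventTableParseError(str(exc), lineno) from exc
        li = float(row["IncFormLen"])
        ls = float(row["SkipFormLen"])
        counts.append(ReplicateCounts(
            event_id=event.event_id, condition=Condition.basal,
            inclusion_counts=_parse_count_vector(row["IJC_SAMPLE_1"], lineno, "IJC_SAMPLE_1"),
            skipping_counts=_parse_count_vector(row["SJC_SAMPLE_1"], lineno, "SJC_SAMPLE_1"),
            inclusion_eff_len=li, skipping_eff_len=ls,
        ))
        counts.append(ReplicateCounts(
            event_id=event.event_id, condition=Condition.stimulated,
            inclusion_counts=_parse_count_vector(row["IJC_SAMPLE_2"], lineno, "IJC_SAMPLE_2"),
            skipping_counts=_parse_count_vector(row["SJC_SAMPLE_2"], lineno, "SJC_SAMPLE_2"),
            inclusion_eff_len=li, skipping_eff_len=ls,
        ))
        events.append(event)
    return events, counts


def _read_internal(fh):
    events: list[SpliceEvent] = []
    counts: list[ReplicateCounts] = []
    for lineno, raw in enumerate(fh, start=2):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) != len(INTERNAL_COLUMNS):
            raise EventTableParseError(
                f"expected {len(INTERNAL_COLUMNS)} columns, got {len(fields)}", lineno
            )
        row = dict(zip(INTERNAL_COLUMNS, fields))
        try:
            event = SpliceEvent(
                event_id=row["event_id"], species=row["species"],
                gene_id=row["gene_id"], gene_symbol=row["gene_symbol"],
                event_type=EventType(row["event_type"]), chrom=row["chrom"],
                strand=row["strand"],
                target_start=int(row["target_start"]),
                target_end=int(row["target_end"]),
                upstream_end=int(row["upstream_end"]),
                downstream_start=int(row["downstream_start"]),
            )
        except ValueError as exc:
            raise EventTableParseError(str(exc), lineno) from exc
        events.append(event)
        li = float(row["inclusion_eff_len"])
        ls = float(row["skipping_eff_len"])
        for cond, icol, scol in (
            (Condition.basal, "basal_inclusion", "basal_skipping"),
            (Condition.stimulated, "stim_inclusion", "stim_skipping"),
        ):
            if row[icol] == "NA":
                continue
            counts.append(ReplicateCounts(
                event_id=event.event_id, condition=cond,
                inclusion_counts=_parse_count_vector(row[icol], lineno, icol),
                skipping_counts=_parse_count_vector(row[scol], lineno, scol),
                inclusion_eff_len=li, skipping_eff_len=ls,
            ))
    return events, counts


def _fmt_psi(value: float | None) -> str:
    return "NA" if value is None else f"{value:.6g}"


def write_event_table(
    events: Sequence[SpliceEvent],
    counts: Sequence[ReplicateCounts],
    psis: Sequence[PsiEstimate] | None,
    path: str | Path,
) -> None:
    """Write the internal_tsv dialect; round-trips losslessly with the reader."""
    by_event: dict[str, dict[Condition, ReplicateCounts]] = {}
    for rc in counts:
        by_event.setdefault(rc.event_id, {})[rc.condition] = rc
    psi_by_event: dict[tuple[str, Condition], PsiEstimate] = {}
    for p in psis or ():
        psi_by_event[(p.event_id, p.condition)] = p
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(INTERNAL_COLUMNS) + "\n")
        for ev in events:
            conds = by_event.get(ev.event_id, {})
            some = next(iter(conds.values()), None)
            li = some.inclusion_eff_len if some else DEFAULT_INCLUSION_EFF_LEN
            ls = some.skipping_eff_len if some else DEFAULT_SKIPPING_EFF_LEN
            cells: dict[str, str] = {
                "event_id": ev.event_id, "species": ev.species,
                "gene_id": ev.gene_id, "gene_symbol": ev.gene_symbol,
                "event_type": ev.event_type.value, "chrom": ev.chrom,
                "strand": ev.strand,
                "target_start": str(ev.target_start),
                "target_end": str(ev.target_end),
                "upstream_end": str(ev.upstream_end),
                "downstream_start": str(ev.downstream_start),
                "inclusion_eff_len": f"{li:g}", "skipping_eff_len": f"{ls:g}",
            }
            for cond, icol, scol, pcol in (
                (Condition.basal, "basal_inclusion", "basal_skipping", "basal_mean_psi"),
                (Condition.stimulated, "stim_inclusion", "stim_skipping", "stim_mean_psi"),
            ):
                rc = conds.get(cond)
                if rc is None:
                    cells[icol] = cells[scol] = cells[pcol] = "NA"
                else:
                    cells[icol] = ",".join(str(c) for c in rc.inclusion_counts)
                    cells[scol] = ",".join(str(c) for c in rc.skipping_counts)
                    est = psi_by_event.get((ev.event_id, cond))
                    cells[pcol] = _fmt_psi(est.mean_psi if est else None)
            fh.write("\t".join(cells[c] for c in INTERNAL_COLUMNS) + "\n")


def write_rmats_table(
    events: Sequence[SpliceEvent],
    basal: Sequence[ReplicateCounts],
    stimulated: Sequence[ReplicateCounts],
    path: str | Path,
) -> None:
    """Write events + counts in the rmats_jc dialect (SAMPLE_1 = basal)."""
    b = {rc.event_id: rc for rc in basal}
    s = {rc.event_id: rc for rc in stimulated}
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(RMATS_JC_COLUMNS) + "\n")
        for ev in events:
            rb, rs = b[ev.event_id], s[ev.event_id]
            pb = compute_psi(rb)
            ps = compute_psi(rs)

            def _lvl(est: PsiEstimate) -> str:
                return ",".join(
                    "NA" if p is None else f"{p / 100.0:.3f}" for p in est.psi_per_replicate
                )

            diff = (
                "NA" if pb.mean_psi is None or ps.mean_psi is None
                else f"{(ps.mean_psi - pb.mean_psi) / 100.0:.3f}"
            )
            row = [
                ev.event_id, ev.gene_id, ev.gene_symbol, ev.chrom, ev.strand,
                str(ev.target_start), str(ev.target_end),
                str(max(ev.upstream_end - 100, 0)), str(ev.upstream_end),
                str(ev.downstream_start), str(ev.downstream_start + 100),
                ",".join(map(str, rb.inclusion_counts)),
                ",".join(map(str, rb.skipping_counts)),
                ",".join(map(str, rs.inclusion_counts)),
                ",".join(map(str, rs.skipping_counts)),
                f"{rb.inclusion_eff_len:g}", f"{rb.skipping_eff_len:g}",
                "NA", "NA", _lvl(pb), _lvl(ps), diff,
            ]
            fh.write("\t".join(row) + "\n")
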