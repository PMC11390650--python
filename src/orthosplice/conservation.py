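"""Conserved vs species-specific activity-regulated gene sets and enrichments.

Working on matched ortholog pairs, genes are labelled by where their
activity-dependent splicing is observed.  A gene is *conserved-regulated*
when it has at least one orthologous event called significant in species A
(e.g. human) and its 1:1 orthologous gene has a significant event in at
least one species-B dataset (e.g. the mouse preparations).  A gene is
*species-specific* to A when it is regulated in A, its ortholog is testable
(in the expression background) in at least one B dataset, but never
significant there.  Genes whose ortholog is untestable in every B dataset
are excluded from the species-specific set rather than counted as divergent:
absence of evidence is not treated as evidence of divergence (a permissive
flag restores the inclusive reading).

Splicing-factor target enrichment and flat per-term annotation enrichment
reuse the shared 2x2 machinery.  Term enrichment is a plain per-term Fisher
test; it deliberately does not reproduce graph-weighted GO algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .compstats import EnrichmentResult, class_enrichment
from .differential import DifferentialCall, apply_significance_filters
from .events import ReplicateCounts, filter_expressed
from .orthologs import OrthologPair

__all__ = [
    "RegulationLabel",
    "build_background",
    "conserved_regulated_genes",
    "species_specific_regulated_genes",
    "label_genes",
    "factor_target_enrichment",
    "term_enrichment",
]

LABELS = ("conserved", "species_specific_A", "species_specific_B",
          "unregulated", "untestable")


@dataclass(frozen=True)
class RegulationLabel:
    gene_id: str  # species-A gene id of the 1:1 pair
    label: str
    supporting_events: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def _gene_of_pair(pair: OrthologPair, side: str) -> str:
    return pair.target_gene_id if side == "A" else pair.source_gene_id


def build_background(
    pairs: Sequence[OrthologPair],
    counts_a: Iterable[ReplicateCounts],
    counts_b_datasets: Mapping[str, Iterable[ReplicateCounts]],
    min_count: int = 5,
) -> set[str]:
    """Genes with >= 1 orthologous event expressed in A and in >= 1 B dataset.

    Expression uses the averaged rule (mean over samples of
    max(inclusion, skipping) > min_count), the background criterion for
    enrichment analyses.  Returns species-A gene ids.
    """
    if not pairs:
        raise ValueError("no ortholog pairs supplied")
    expressed_a = filter_expressed(counts_a, min_count=min_count, rule="mean_over_samples")
    expressed_b = [
        filter_expressed(c, min_count=min_count, rule="mean_over_samples")
        for c in counts_b_datasets.values()
    ]
    background: set[str] = set()
    for pair in pairs:
        if pair.target_event_id not in expressed_a:
            continue
        if any(pair.source_event_id in ex for ex in expressed_b):
            background.add(pair.target_gene_id)
    if not background:
        raise ValueError("background gene set is empty")
    return background


def _significant_events(calls: Mapping[str, DifferentialCall],
                        alpha: float, min_delta: float) -> set[str]:
    return {
        eid for eid, call in calls.items()
        if apply_significance_filters(call, alpha=alpha, min_delta=min_delta)
    }


def conserved_regulated_genes(
    pairs: Sequence[OrthologPair],
    calls_a: Mapping[str, DifferentialCall],
    calls_b_datasets: Mapping[str, Mapping[str, DifferentialCall]],
    alpha: float = 0.05,
    min_delta: float = 10.0,
    event_level: bool = False,
) -> set[str]:
    """Genes regulated in A whose ortholog is regulated in >= 1 B dataset.

    ``calls_a`` is keyed by A (target-species) event id, each B dataset by
    source event id.  With ``event_level`` the *same* orthologous event must
    be significant in both species (the stricter variant used for
    event-level enrichment); default is gene-level conservation.
    """
    sig_a = _significant_events(calls_a, alpha, min_delta)
    sig_b_sets = [
        _significant_events(calls, alpha, min_delta)
        for calls in calls_b_datasets.values()
    ]
    genes_sig_a = {p.target_gene_id for p in pairs if p.target_event_id in sig_a}
    if event_level:
        return {
            p.target_gene_id for p in pairs
            if p.target_event_id in sig_a
            and any(p.source_event_id in sb for sb in sig_b_sets)
        }
    genes_sig_b = {
        p.target_gene_id for p in pairs
        if any(p.source_event_id in sb for sb in sig_b_sets)
    }
    return genes_sig_a & genes_sig_b


def conserved_regulated_events(
    pairs: Sequence[OrthologPair],
    calls_a: Mapping[str, DifferentialCall],
    calls_b_datasets: Mapping[str, Mapping[str, DifferentialCall]],
    alpha: float = 0.05,
    min_delta: float = 10.0,
) -> set[str]:
    """Orthologous events (by A event id) significant in A and >= 1 B dataset."""
    sig_a = _significant_events(calls_a, alpha, min_delta)
    sig_b_sets = [
        _significant_events(calls, alpha, min_delta)
        for calls in calls_b_datasets.values()
    ]
    return {
        p.target_event_id for p in pairs
        if p.target_event_id in sig_a
        and any(p.source_event_id in sb for sb in sig_b_sets)
    }


def species_specific_regulated_genes(
    pairs: Sequence[OrthologPair],
    calls_a: Mapping[str, DifferentialCall],
    calls_b_datasets: Mapping[str, Mapping[str, DifferentialCall]],
    background: set[str],
    alpha: float = 0.05,
    min_delta: float = 10.0,
    include_untested: bool = False,
) -> set[str]:
    """Genes regulated in A but never in any B dataset.

    By default the ortholog must be testable in B (gene in ``background``),
    so divergence is only claimed where B had the chance to show regulation;
    ``include_untested`` restores the permissive reading.
    """
    conserved = conserved_regulated_genes(
        pairs, calls_a, calls_b_datasets, alpha=alpha, min_delta=min_delta
    )
    sig_a = _significant_events(calls_a, alpha, min_delta)
    regulated_a = {p.target_gene_id for p in pairs if p.target_event_id in sig_a}
    out = regulated_a - conserved
    if not include_untested:
        out &= background
    return out


def label_genes(
    pairs: Sequence[OrthologPair],
    calls_a: Mapping[str, DifferentialCall],
    calls_b_datasets: Mapping[str, Mapping[str, DifferentialCall]],
    background: set[str],
    alpha: float = 0.05,
    min_delta: float = 10.0,
) -> dict[str, RegulationLabel]:
    """Partition all genes carrying ortholog pairs into regulation labels."""
    sig_a = _significant_events(calls_a, alpha, min_delta)
    sig_b_sets = [
        _significant_events(calls, alpha, min_delta)
        for calls in calls_b_datasets.values()
    ]
    by_gene: dict[str, list[OrthologPair]] = {}
    for p in pairs:
        by_gene.setdefault(p.target_gene_id, []).append(p)
    labels: dict[str, RegulationLabel] = {}
    for gene, gpairs in by_gene.items():
        a_events = {p.target_event_id for p in gpairs if p.target_event_id in sig_a}
        b_events = {
            p.source_event_id for p in gpairs
            if any(p.source_event_id in sb for sb in sig_b_sets)
        }
        if gene not in background:
            label = "untestable"
        elif a_events and b_events:
            label = "conserved"
        elif a_events:
            label = "species_specific_A"
        elif b_events:
            label = "species_specific_B"
        else:
            label = "unregulated"
        labels[gene] = RegulationLabel(gene, label,
                                       tuple(sorted(a_events | b_events)))
    return labels


def factor_target_enrichment(
    target_sets: Mapping[str, set[str]],
    foreground: set[str],
    background: set[str],
) -> dict[str, EnrichmentResult]:
    """Per splicing factor, enrichment of its target events in the foreground.

    ``foreground`` must be a subset of ``background`` (event ids); target
    sets are intersected with the background.  Shares the 2x2 code path with
    class enrichment.
    """
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    results: dict[str, EnrichmentResult] = {}
    for name, targets in target_sets.items():
        results[name] = class_enrichment(
            reference_ids=targets & background,
            query_ids=foreground,
            universe=background,
        )
    return results


def term_enrichment(
    gene_set: set[str],
    background_genes: set[str],
    gene2term: Mapping[str, set[str]] | pd.DataFrame,
    min_genes: int = 5,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Flat per-term Fisher enrichment of ``gene_set`` within the background.

    ``gene2term`` maps gene id -> set of term ids (or a two-column DataFrame
    gene_id/term_id).  Terms annotating fewer than ``min_genes`` background
    genes are skipped.  Returns a DataFrame sorted by p with the 2x2 counts;
    optional Benjamini–Hochberg q-values.
    """
    if not gene_set <= background_genes:
        raise ValueError("gene_set must be a subset of background_genes")
    if isinstance(gene2term, pd.DataFrame):
        mapping: dict[str, set[str]] = {}
        for gene, term in zip(gene2term.iloc[:, 0], gene2term.iloc[:, 1]):
            mapping.setdefault(str(gene), set()).add(str(term))
        gene2term = mapping
    term_genes: dict[str, set[str]] = {}
    for gene, terms in gene2term.items():
        if gene not in background_genes:
            continue
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)
    rows = []
    for term, genes in sorted(term_genes.items()):
        if len(genes) < min_genes:
            continue
        enr = class_enrichment(reference_ids=genes, query_ids=gene_set,
                               universe=background_genes)
        rows.append({
            "term": term, "n_annotated": len(genes),
            "a": enr.a, "b": enr.b, "c": enr.c, "d": enr.d,
            "fold_enrichment": enr.fold_enrichment,
            "fisher_p": enr.fisher_p,
        })
    frame = pd.DataFrame(rows, columns=[
        "term", "n_annotated", "a", "b", "c", "d", "fold_enrichment", "fisher_p",
    ])
    if frame.empty:
        return frame
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        frame["q_value"] = multipletests(frame["fisher_p"], method="fdr_bh")[1]
    return frame.sort_values("fisher_p", kind="mergesort").reset_index(drop=True)
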