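"""Correlations, 2x2 enrichment statistics and pairwise dataset matrices.

Pearson correlations carry 95% confidence limits from the Fisher
z-transform (SE = 1/sqrt(n-3)) and a two-sided p-value from the z statistic.
Enrichment of one event class in another is summarised by a 2x2 table with
the fold enrichment reported as a ratio of proportions (Katz log CI) and the
odds ratio with its Woolf standard error; two enrichments are compared by a
normal approximation to the difference in log odds ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "EnrichmentResult",
    "pearson_with_ci",
    "fisher_exact_p",
    "class_enrichment",
    "enrichment_from_table",
    "compare_enrichments",
    "pairwise_matrix",
    "expression_matched_subset",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float | None
    n: int
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    degenerate: bool = False  # zero variance or |r| == 1


def pearson_with_ci(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with Fisher-z 95% CI and two-sided p from the z statistic.

    Pairs with an undefined member (None/NaN) are dropped.  Requires at
    least 3 complete pairs; zero-variance input yields an undefined r.
    """
    xa = np.asarray([np.nan if v is None else v for v in x], dtype=float)
    ya = np.asarray([np.nan if v is None else v for v in y], dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    n = int(xa.size)
    if n < 3:
        return CorrelationResult(None, n, None, None, None, degenerate=True)
    if np.std(xa) == 0.0 or np.std(ya) == 0.0:
        return CorrelationResult(None, n, None, None, None, degenerate=True)
    r = float(np.corrcoef(xa, ya)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) >= 1.0 - 1e-12:
        r = math.copysign(1.0, r)
        return CorrelationResult(r, n, r, r, 0.0, degenerate=True)
    if n == 3:  # Fisher-z SE 1/sqrt(n-3) undefined
        return CorrelationResult(r, n, None, None, None, degenerate=True)
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.975)
    ci_low = math.tanh(z - zcrit * se)
    ci_high = math.tanh(z + zcrit * se)
    p = 2.0 * stats.norm.sf(abs(z) / se)
    return CorrelationResult(r, n, ci_low, ci_high, float(p))


@dataclass(frozen=True)
class EnrichmentResult:
    a: int  # in reference class AND in query class
    b: int  # in query, not reference
    c: int  # in reference, not query
    d: int  # in neither
    fold_enrichment: float
    fold_ci_low: float
    fold_ci_high: float
    odds_ratio: float
    log_or_se: float
    fisher_p: float
    continuity_corrected: bool = False

    @property
    def table(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def enrichment_from_table(a: int, b: int, c: int, d: int,
                          conditioning: str = "complement") -> EnrichmentResult:
    """Enrichment statistics from 2x2 counts.

    ``conditioning='complement'`` reports P(ref | query) / P(ref | not query)
    as the fold enrichment; ``'universe'`` uses P(ref | universe) as the
    denominator.  Zero cells trigger a Haldane–Anscombe 0.5 correction for
    the ratio statistics (flagged); the Fisher p always uses the raw table.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    p = fisher_exact_p(a, b, c, d)
    corrected = min(a, b, c, d) == 0
    aa, bb, cc, dd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if corrected else (a, b, c, d)
    )
    if conditioning == "complement":
        if c + d == 0:
            fold = 1.0  # query is the whole universe: nothing to condition on
        elif a > 0 and c > 0:
            fold = (a / (a + b)) / (c / (c + d))
        else:
            fold = (aa / (aa + bb)) / (cc / (cc + dd))
        # Katz log CI for a ratio of proportions (corrected counts)
        se_log = math.sqrt(1 / aa - 1 / (aa + bb) + 1 / cc - 1 / (cc + dd))
    elif conditioning == "universe":
        if a > 0:
            fold = (a / (a + b)) / ((a + c) / (a + b + c + d))
        else:
            fold = (aa / (aa + bb)) / ((aa + cc) / (aa + bb + cc + dd))
        se_log = math.sqrt(1 / aa - 1 / (aa + bb) + 1 / (aa + cc) - 1 / (aa + bb + cc + dd))
    else:
        raise ValueError(f"unknown conditioning {conditioning!r}")
    zcrit = stats.norm.ppf(0.975)
    odds = (aa * dd) / (bb * cc)
    woolf = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    return EnrichmentResult(
        a=a, b=b, c=c, d=d,
        fold_enrichment=fold,
        fold_ci_low=fold * math.exp(-zcrit * se_log),
        fold_ci_high=fold * math.exp(zcrit * se_log),
        odds_ratio=odds, log_or_se=woolf, fisher_p=p,
        continuity_corrected=corrected,
    )


def class_enrichment(reference_ids: set, query_ids: set, universe: set,
                     conditioning: str = "complement") -> EnrichmentResult:
    """Enrichment of membership in ``reference_ids`` among ``query_ids``.

    Both sets must be subsets of the (matched-pair) universe.  The table is
    a = |ref ∩ query|, b = |query \\ ref|, c = |ref \\ query|, d = rest.
    """
    if not universe:
        raise ValueError("empty universe")
    if not reference_ids <= universe or not query_ids <= universe:
        raise ValueError("reference and query must be subsets of the universe")
    a = len(reference_ids & query_ids)
    b = len(query_ids - reference_ids)
    c = len(reference_ids - query_ids)
    d = len(universe) - a - b - c
    return enrichment_from_table(a, b, c, d, conditioning=conditioning)


def compare_enrichments(e1: EnrichmentResult, e2: EnrichmentResult) -> tuple[float, float]:
    """Normal approximation to the difference in log odds ratios.

    Returns (z, two-sided p).  Antisymmetric in its arguments.
    """
    z = (math.log(e1.odds_ratio) - math.log(e2.odds_ratio)) / math.sqrt(
        e1.log_or_se ** 2 + e2.log_or_se ** 2
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def pairwise_matrix(
    datasets: Mapping[str, Mapping[str, float]]
) -> pd.DataFrame:
    """Symmetric matrix of CorrelationResult over all dataset pairs.

    Each dataset maps shared event ids to a value (basal PSI, delta PSI or
    pct-of-max); each cell correlates the pair's intersection of event ids.
    Cells with fewer than 3 shared events are undefined (flagged results).
    """
    names = list(datasets)
    if len(names) < 2:
        raise ValueError("need at least two datasets")
    mat = pd.DataFrame(index=names, columns=names, dtype=object)
    for i, na in enumerate(names):
        for nb in names[i:]:
            if na == nb:
                n = len(datasets[na])
                cell = CorrelationResult(1.0, n, 1.0, 1.0, 0.0, degenerate=True)
            else:
                shared = sorted(set(datasets[na]) & set(datasets[nb]))
                cell = pearson_with_ci(
                    [datasets[na][k] for k in shared],
                    [datasets[nb][k] for k in shared],
                )
            mat.loc[na, nb] = cell
            mat.loc[nb, na] = cell
    return mat


def matrix_r_frame(mat: pd.DataFrame) -> pd.DataFrame:
    """Extract the r values of a pairwise_matrix result as floats (NaN if undefined)."""
    return mat.map(lambda c: np.nan if c.r is None else c.r).astype(float)


def expression_matched_subset(
    pairs: Sequence,
    expr_a: Mapping[str, float],
    expr_b: Mapping[str, float],
    band: float = 0.2,
    symmetric: bool = True,
) -> list:
    """Keep ortholog pairs whose genes are expressed at similar levels.

    The expression ratio expr_b/expr_a must fall within the band: with
    ``symmetric`` (default) the log-symmetric interval [1/(1+band), 1+band],
    otherwise the arithmetic interval [1-band, 1+band].  Pairs with a gene
    missing from either table are dropped.  Idempotent.
    """
    if band < 0:
        raise ValueError("band must be >= 0")
    lo = 1.0 / (1.0 + band) if symmetric else 1.0 - band
    hi = 1.0 + band
    kept = []
    for pair in pairs:
        ea = expr_a.get(pair.source_gene_id)
        eb = expr_b.get(pair.target_gene_id)
        if ea is None or eb is None or ea <= 0 or eb <= 0:
            continue
        ratio = eb / ea
        if lo <= ratio <= hi:
            kept.append(pair)
    return kept
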