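"""Activity-dependent inclusion calls and effect-size normalisation.

Per event, the basal-vs-stimulated contrast is summarised by the change in
mean PSI (``delta_psi = stimulated - basal``) and a p-value from a
likelihood-ratio test comparing binomial models for the raw
inclusion/skipping junction counts: a shared read-level inclusion fraction
across conditions against per-condition fractions, referred to chi-square
with one degree of freedom.  Because both conditions of an event share the
same effective junction lengths, equality of read-level inclusion fractions
is equivalent to equality of PSI.  A beta-binomial variant is available for overdispersed
replicates.  An event is called significant when p < alpha, the expression
filter passes (max(inclusion, skipping) > min_count in every sample, both
conditions) and |delta_psi| > min_delta — all strict inequalities.

``pct_max_change`` expresses a PSI change as a percentage of the maximum
change possible from the basal level: an increase is divided by
(100 - basal), a decrease by basal.  Downstream comparisons gate this
statistic to events with 20 < basal PSI < 80, because near-constitutive
exons turn trivial absolute changes into extreme percentages (e.g. 95 → 98
is 60% of the possible change).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .events import ReplicateCounts, compute_psi, filter_expressed

__all__ = [
    "DifferentialCall",
    "test_differential_inclusion",
    "apply_significance_filters",
    "pct_max_change",
    "binomial_lrt",
]


@dataclass(frozen=True)
class DifferentialCall:
    event_id: str
    basal_mean_psi: float | None
    stim_mean_psi: float | None
    delta_psi: float | None
    p_value: float | None
    passes_expression: bool
    significant: bool = False
    pct_of_max: float | None = None
    gate_open: bool | None = None  # 20 < basal < 80


def _xlogy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return special.xlogy(x, y)


def binomial_lrt(i1, s1, i2, s2) -> np.ndarray:
    """Vectorised binomial LRT p-value for pooled normalised counts.

    ``i1, s1`` are inclusion/skipping totals in condition 1, ``i2, s2`` in
    condition 2.  Shared- vs per-condition inclusion probability; the LRT
    statistic is referred to chi-square(1).  With a common probability per
    condition the per-replicate likelihood factorises through the totals, so
    only summed counts enter.
    """
    i1 = np.asarray(i1, dtype=float)
    s1 = np.asarray(s1, dtype=float)
    i2 = np.asarray(i2, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    n1, n2 = i1 + s1, i2 + s2
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n1 > 0, i1 / np.maximum(n1, 1), 0.0)
        p2 = np.where(n2 > 0, i2 / np.maximum(n2, 1), 0.0)
        p0 = np.where(n1 + n2 > 0, (i1 + i2) / np.maximum(n1 + n2, 1), 0.0)
    ll_alt = (_xlogy(i1, p1) + _xlogy(s1, 1 - p1)
              + _xlogy(i2, p2) + _xlogy(s2, 1 - p2))
    ll_null = (_xlogy(i1 + i2, p0) + _xlogy(s1 + s2, 1 - p0))
    stat = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    return stats.chi2.sf(stat, df=1)


def _raw_totals(counts: ReplicateCounts) -> tuple[int, int]:
    """Raw inclusion/skipping read totals pooled over replicates.

    The LRT is run on raw counts: with both conditions sharing the same
    effective lengths, equal read-level inclusion fractions are equivalent
    to equal PSI, every read keeps its unit of information (dividing by
    effective lengths would misstate the binomial variance), and the
    p-value is automatically invariant to rescaling both lengths.
    """
    return sum(counts.inclusion_counts), sum(counts.skipping_counts)


def _betabinom_negll(params, ks, ns):
    # mean/overdispersion parametrisation: alpha = mu*nu, beta = (1-mu)*nu
    mu = 1.0 / (1.0 + math.exp(-params[0]))
    nu = math.exp(params[1])
    a, b = mu * nu, (1 - mu) * nu
    ll = 0.0
    for k, n in zip(ks, ns):
        ll += (special.betaln(k + a, n - k + b) - special.betaln(a, b))
    return -ll


def _betabinom_lrt(basal: ReplicateCounts, stim: ReplicateCounts) -> float:
    def norm(counts):
        ks, ns = [], []
        for i, s in zip(counts.inclusion_counts, counts.skipping_counts):
            ks.append(i)
            ns.append(i + s)
        return ks, ns

    kb, nb = norm(basal)
    ks_, ns_ = norm(stim)

    def fit(ks, ns):
        k_tot, n_tot = sum(ks), sum(ns)
        p = min(max(k_tot / n_tot, 1e-6), 1 - 1e-6) if n_tot else 0.5
        x0 = [math.log(p / (1 - p)), math.log(50.0)]
        res = optimize.minimize(_betabinom_negll, x0, args=(ks, ns),
                                method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
        return -res.fun

    ll_alt = fit(kb, nb) + fit(ks_, ns_)
    ll_null = fit(kb + ks_, nb + ns_)
    stat = max(2.0 * (ll_alt - ll_null), 0.0)
    # alternative has two extra parameters (its own mean and dispersion)
    return float(stats.chi2.sf(stat, df=2))


def test_differential_inclusion(
    basal: ReplicateCounts,
    stim: ReplicateCounts,
    method: str = "binomial",
    min_count: int = 5,
) -> DifferentialCall:
    """Differential inclusion call for one event between two conditions."""
    if basal.event_id != stim.event_id:
        raise ValueError("condition count tables refer to different events")
    psi_b = compute_psi(basal)
    psi_s = compute_psi(stim)
    passes = bool(filter_expressed([basal, stim], min_count=min_count,
                                   rule="all_samples"))
    if psi_b.mean_psi is None or psi_s.mean_psi is None:
        return DifferentialCall(basal.event_id, psi_b.mean_psi, psi_s.mean_psi,
                                None, None, passes_expression=False)
    delta = psi_s.mean_psi - psi_b.mean_psi
    if not passes:
        return DifferentialCall(basal.event_id, psi_b.mean_psi, psi_s.mean_psi,
                                delta, None, passes_expression=False)
    if method == "binomial":
        ib, sb = _raw_totals(basal)
        is_, ss = _raw_totals(stim)
        p = float(binomial_lrt(ib, sb, is_, ss))
    elif method == "betabinomial":
        p = _betabinom_lrt(basal, stim)
    else:
        raise ValueError(f"unknown method {method!r}")
    return DifferentialCall(basal.event_id, psi_b.mean_psi, psi_s.mean_psi,
                            delta, p, passes_expression=True)


def apply_significance_filters(
    call: DifferentialCall,
    alpha: float = 0.05,
    min_delta: float = 10.0,
) -> bool:
    """Strict thresholds: p < alpha, expression filter passed, |dPSI| > min_delta."""
    if call.p_value is None or call.delta_psi is None:
        return False
    return (call.p_value < alpha
            and call.passes_expression
            and abs(call.delta_psi) > min_delta)


def pct_max_change(basal_psi: float, stim_psi: float) -> float | None:
    """PSI change as a percentage of the maximum possible change.

    Increases are scaled by the available headroom (100 - basal), decreases
    by the available floor (basal).  Degenerate denominators (basal 100 with
    an increase, basal 0 with a decrease) give None.
    """
    for name, v in (("basal", basal_psi), ("stimulated", stim_psi)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} PSI {v} outside [0, 100]")
    delta = stim_psi - basal_psi
    if delta >= 0:
        denom = 100.0 - basal_psi
    else:
        denom = basal_psi
    if denom == 0.0:
        return None
    return 100.0 * delta / denom


def annotate_pct_max(call: DifferentialCall, gate: tuple[float, float] = (20.0, 80.0)
                     ) -> DifferentialCall:
    """Attach pct-of-max and its basal-PSI gate flag to a call."""
    from dataclasses import replace
    if call.basal_mean_psi is None or call.stim_mean_psi is None:
        return replace(call, pct_of_max=None, gate_open=None)
    pct = pct_max_change(call.basal_mean_psi, call.stim_mean_psi)
    lo, hi = gate
    return replace(call, pct_of_max=pct,
                   gate_open=bool(lo < call.basal_mean_psi < hi))
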