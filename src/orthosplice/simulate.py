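"""Synthetic two-species splicing fixtures with planted ground truth.

The generator lays out cassette-exon events for a *source* species (lifted,
mouse-like) and a *target* species (reference coordinates, human-like),
emits a UCSC chain file that exactly encodes the source→target coordinate
map (including indel gaps and occasional strand flips), a 1:1 gene ortholog
map, and replicate junction-count tables for basal and stimulated
conditions in both species.

True basal PSI is drawn from a PI/PS/AS mixture on the logit scale, with a
Gaussian-copula cross-species correlation for orthologous events (PSI is
bounded, so correlation is imposed on logits).  A configurable fraction of
events respond to stimulation; conserved responders change in both species
with a shared direction and correlated magnitudes, species-specific
responders change in one species only.  Counts are binomial junction reads
at Poisson replicate depth (optionally beta-binomial for overdispersion).

Every quantity downstream of the pipeline — match rate, basal-PSI
correlation, regulated gene sets — is therefore known in advance, so
recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .events import (
    Condition, EventType, ReplicateCounts, SpliceEvent, write_rmats_table,
)
from .liftover import ChainSet, lift_event, parse_chain_text
from .orthologs import OrthologPair

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimBundle",
    "simulate_bundle",
    "simulate_correlated_panel",
    "write_fixture_bundle",
    "bundle_from_manifest",
    "SMALL_PROFILE",
    "RECOVERY_PROFILE",
]

# geometry of one event template within a gene (relative offsets)
_UP_EXON = (0, 100)          # upstream flanking exon
_TARGET = (200, 280)         # alternative exon
_DOWN_EXON = (400, 500)      # downstream flanking exon
_EVENT_PITCH = 700           # spacing between consecutive event templates
_GENE_MARGIN = 100
_INTERGENIC = 500
_SAFE_GAP_ZONE = 540         # offset of inter-event gap insertion point
_DECOY_GAP = (190, 230)      # gap straddling target_start for decoy events
_NONORTH_SHIFT = 25          # coordinate shift of target-only decoy events


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic two-species comparison."""
    n_genes: int = 200
    events_per_gene: int = 3
    orthologous_fraction: float = 0.7
    class_mixture: tuple[float, float, float] = (0.40, 0.25, 0.35)  # PI, PS, AS
    basal_logit_psi_corr: float = 0.85
    responsive_fraction: float = 0.15
    conserved_response_fraction: float = 0.5
    delta_mean: float = 25.0       # mean |dPSI| of responsive events
    delta_sd: float = 8.0
    delta_min: float = 15.0
    delta_max: float = 60.0
    sign_negative_fraction: float = 0.6  # stimulation-induced exclusion bias
    delta_corr: float = 0.8
    depth: float = 200.0
    replicates: int = 3
    dispersion: float | None = None  # beta-binomial rho; None = binomial
    jitter: int = 10               # max per-boundary offset of planted orthologs
    decoy_gap_fraction: float = 0.3
    strand_flip_fraction: float = 0.1
    inclusion_eff_len: float = 2.0
    skipping_eff_len: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.orthologous_fraction, self.responsive_fraction,
                 self.conserved_response_fraction, self.sign_negative_fraction,
                 self.decoy_gap_fraction, self.strand_flip_fraction)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("all fractions must be in [0, 1]")
        if not -1.0 <= self.basal_logit_psi_corr <= 1.0:
            raise ValueError("basal_logit_psi_corr must be in [-1, 1]")
        if not -1.0 <= self.delta_corr <= 1.0:
            raise ValueError("delta_corr must be in [-1, 1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.replicates < 2:
            raise ValueError("at least two replicates required")
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise ValueError("class_mixture must sum to 1")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


SMALL_PROFILE = SimConfig(n_genes=200)
# ~2100 orthologous events at depth 200, 3 replicates
RECOVERY_PROFILE = SimConfig(n_genes=1000)


@dataclass
class SimTruth:
    events: pd.DataFrame  # one row per planted event (source or pair)
    genes: pd.DataFrame   # one row per 1:1 gene pair with regulation label
    realized_basal_psi_corr: float | None


@dataclass
class SimBundle:
    config: SimConfig
    events_source: list[SpliceEvent]
    events_target: list[SpliceEvent]
    chain_text: str
    chains: ChainSet
    ortholog_map: dict[str, str]
    counts: dict[tuple[str, str], list[ReplicateCounts]]  # (species, condition)
    truth: SimTruth


# ---------------------------------------------------------------------------
# genome pair + chain construction
# ---------------------------------------------------------------------------

def _build_genome_pair(config: SimConfig, rng: np.random.Generator):
    """Lay out source genes/events, emit the chain, lift and jitter targets."""
    n_events_total = config.n_genes * config.events_per_gene
    n_orth = int(round(config.orthologous_fraction * n_events_total))
    order = rng.permutation(n_events_total)
    orth_ids = set(order[:n_orth].tolist())
    non_orth = order[n_orth:]
    n_decoy = int(round(config.decoy_gap_fraction * len(non_orth)))
    decoy_ids = set(non_orth[:n_decoy].tolist())

    flip_genes = set(
        np.flatnonzero(rng.random(config.n_genes) < config.strand_flip_fraction).tolist()
    )

    events_source: list[SpliceEvent] = []
    chain_lines: list[str] = []
    gene_records = []  # (gene_idx, t_start, t_end, q_fwd_start, q_fwd_len, flipped)

    gene_span = 2 * _GENE_MARGIN + config.events_per_gene * _EVENT_PITCH
    t_cursor = 0
    q_cursor = 0
    chain_specs = []
    for g in range(config.n_genes):
        t0 = t_cursor
        gaps: list[tuple[int, int, int]] = []  # (t_gap_start, dt, dq)
        for k in range(config.events_per_gene):
            base = t0 + _GENE_MARGIN + k * _EVENT_PITCH
            ev_idx = g * config.events_per_gene + k
            ev = SpliceEvent(
                event_id=f"src_e{ev_idx:05d}",
                species="source", gene_id=f"srcG{g:04d}",
                gene_symbol=f"SrcGene{g}", event_type=EventType.SE,
                chrom="chrA", strand="+",
                target_start=base + _TARGET[0], target_end=base + _TARGET[1],
                upstream_end=base + _UP_EXON[1],
                downstream_start=base + _DOWN_EXON[0],
            )
            events_source.append(ev)
            if ev_idx in decoy_ids:
                gaps.append((base + _DECOY_GAP[0],
                             _DECOY_GAP[1] - _DECOY_GAP[0], 0))
            if k < config.events_per_gene - 1:
                dt = int(rng.integers(0, 31))
                dq = int(rng.integers(0, 31))
                if dt or dq:
                    gaps.append((base + _SAFE_GAP_ZONE, dt, dq))
        t1 = t0 + gene_span + sum(dt for _, dt, _ in gaps)
        q_len = (t1 - t0) - sum(dt for _, dt, _ in gaps) + sum(dq for _, _, dq in gaps)
        flipped = g in flip_genes
        chain_specs.append((g, t0, t1, q_cursor, q_len, flipped, sorted(gaps)))
        gene_records.append((g, t0, t1, q_cursor, q_len, flipped))
        t_cursor = t1 + _INTERGENIC
        q_cursor += q_len + _INTERGENIC

    t_size = t_cursor
    q_size = q_cursor
    for g, t0, t1, q0, q_len, flipped, gaps in chain_specs:
        blocks = []
        cursor = t0
        for gap_start, dt, dq in gaps:
            blocks.append((gap_start - cursor, dt, dq))
            cursor = gap_start + dt
        blocks.append((t1 - cursor, 0, 0))
        if flipped:
            q_strand = "-"
            q_start, q_end = q_size - (q0 + q_len), q_size - q0
        else:
            q_strand = "+"
            q_start, q_end = q0, q0 + q_len
        chain_lines.append(
            f"chain 1000 chrA {t_size} + {t0} {t1} "
            f"chrB {q_size} {q_strand} {q_start} {q_end} {g + 1}"
        )
        for size, dt, dq in blocks[:-1]:
            chain_lines.append(f"{size} {dt} {dq}")
        chain_lines.append(str(blocks[-1][0]))
        chain_lines.append("")

    chain_text = "\n".join(chain_lines) + "\n"
    chains = parse_chain_text(chain_text)

    # target-species annotation: jittered copies of lifted orthologs plus
    # shifted decoy events with no orthologous counterpart
    events_target: list[SpliceEvent] = []
    pair_of_source: dict[str, str] = {}
    for idx, src in enumerate(events_source):
        lifted = lift_event(chains, src)
        gene_idx = idx // config.events_per_gene
        tgt_gene = f"tgtG{gene_idx:04d}"
        if idx in orth_ids:
            if isinstance(lifted, SpliceEvent):
                jit = rng.integers(-config.jitter, config.jitter + 1, size=4)
                up, ts, te, ds = (b + int(j) for b, j in zip(lifted.boundaries, jit))
                tgt = SpliceEvent(
                    event_id=f"tgt_e{idx:05d}", species="target",
                    gene_id=tgt_gene, gene_symbol=f"TgtGene{gene_idx}",
                    event_type=EventType.SE, chrom=lifted.chrom,
                    strand=lifted.strand, target_start=ts, target_end=te,
                    upstream_end=up, downstream_start=ds,
                )
                events_target.append(tgt)
                pair_of_source[src.event_id] = tgt.event_id
            else:  # pragma: no cover - construction guarantees liftability
                raise RuntimeError(f"planted ortholog {src.event_id} failed to lift")
        elif idx not in decoy_ids and isinstance(lifted, SpliceEvent):
            # target-only event far (> tolerance) from any lifted source event
            tgt = SpliceEvent(
                event_id=f"tgt_e{idx:05d}", species="target",
                gene_id=tgt_gene, gene_symbol=f"TgtGene{gene_idx}",
                event_type=EventType.SE, chrom=lifted.chrom,
                strand=lifted.strand,
                target_start=lifted.target_start + _NONORTH_SHIFT,
                target_end=lifted.target_end + _NONORTH_SHIFT,
                upstream_end=lifted.upstream_end + _NONORTH_SHIFT,
                downstream_start=lifted.downstream_start + _NONORTH_SHIFT,
            )
            events_target.append(tgt)

    ortholog_map = {f"srcG{g:04d}": f"tgtG{g:04d}" for g in range(config.n_genes)}
    return events_source, events_target, chain_text, chains, ortholog_map, pair_of_source


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

_CLASS_PARAMS = {  # logit-scale mean and spread per inclusion class
    "PI": (2.6, 0.7),
    "PS": (-2.6, 0.7),
    "AS": (0.0, 1.2),
}


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size=None,
               z: np.ndarray | None = None) -> np.ndarray:
    raw = mean + sd * (rng.standard_normal(size) if z is None else z)
    return np.clip(raw, lo, hi)


def _feasible_sign(preferred: int, basals: list[float], mag: float) -> int:
    """Pick a response direction that leaves room for the planted change."""
    def ok(sign: int) -> bool:
        if sign > 0:
            return all(b + mag <= 97.0 for b in basals)
        return all(b - mag >= 3.0 for b in basals)

    if ok(preferred):
        return preferred
    if ok(-preferred):
        return -preferred
    return preferred  # will be clipped; rare with the class means used


def _mixture_quantile_fn(mixture: tuple[float, float, float]):
    """Quantile function of the logit-PSI mixture (PI/PS/AS components).

    Built on a dense grid so correlated uniforms can be pushed through the
    common marginal; the cross-species Pearson correlation of logit-PSI then
    tracks the copula parameter.
    """
    from scipy.stats import norm
    grid = np.linspace(-9.0, 9.0, 4001)
    cdf = np.zeros_like(grid)
    for w, cls in zip(mixture, ("PI", "PS", "AS")):
        mu, sd = _CLASS_PARAMS[cls]
        cdf += w * norm.cdf((grid - mu) / sd)

    def quantile(u):
        return np.interp(u, cdf, grid)

    return quantile


def _simulate_truth(config: SimConfig, rng: np.random.Generator,
                    events_source, events_target, pair_of_source) -> SimTruth:
    from scipy.stats import norm
    rho = config.basal_logit_psi_corr
    quantile = _mixture_quantile_fn(config.class_mixture)

    rows = []
    tgt_only = [e for e in events_target
                if e.event_id not in set(pair_of_source.values())]

    def _classify(psi: float) -> str:
        if psi >= 80.0:
            return "PI"
        if psi <= 20.0:
            return "PS"
        return "AS"

    def draw_pairwise_basal(paired: bool):
        z1 = rng.standard_normal()
        psi1 = float(100.0 * expit(quantile(norm.cdf(z1))))
        if not paired:
            return psi1, None
        z2 = rho * z1 + np.sqrt(max(1 - rho ** 2, 0.0)) * rng.standard_normal()
        psi2 = float(100.0 * expit(quantile(norm.cdf(z2))))
        return psi1, psi2

    for idx, src in enumerate(events_source):
        tgt_id = pair_of_source.get(src.event_id)
        psi_src, psi_tgt = draw_pairwise_basal(paired=tgt_id is not None)
        cls = _classify(psi_src)

        responsive = bool(rng.random() < config.responsive_fraction)
        conserved = False
        resp_src = resp_tgt = False
        d_src = d_tgt = 0.0
        if responsive:
            preferred = -1 if rng.random() < config.sign_negative_fraction else 1
            if tgt_id is not None and rng.random() < config.conserved_response_fraction:
                conserved = True
                resp_src = resp_tgt = True
                z1 = rng.standard_normal()
                z2 = (config.delta_corr * z1
                      + np.sqrt(max(1 - config.delta_corr ** 2, 0.0))
                      * rng.standard_normal())
                m1 = float(_truncnorm(rng, config.delta_mean, config.delta_sd,
                                      config.delta_min, config.delta_max, z=np.array(z1)))
                m2 = float(_truncnorm(rng, config.delta_mean, config.delta_sd,
                                      config.delta_min, config.delta_max, z=np.array(z2)))
                sign = _feasible_sign(preferred, [psi_src, psi_tgt], max(m1, m2))
                d_src, d_tgt = sign * m1, sign * m2
            else:
                if tgt_id is not None and rng.random() < 0.5:
                    resp_tgt = True
                else:
                    resp_src = True
                mag = float(_truncnorm(rng, config.delta_mean, config.delta_sd,
                                       config.delta_min, config.delta_max))
                if resp_src:
                    sign = _feasible_sign(preferred, [psi_src], mag)
                    d_src = sign * mag
                else:
                    sign = _feasible_sign(preferred, [psi_tgt], mag)
                    d_tgt = sign * mag

        rows.append({
            "source_event_id": src.event_id,
            "target_event_id": tgt_id,
            "source_gene_id": src.gene_id,
            "target_gene_id": ("tgtG" + src.gene_id[4:]),
            "inclusion_class": cls,
            "basal_psi_source": psi_src,
            "basal_psi_target": psi_tgt,
            "stim_psi_source": float(np.clip(psi_src + d_src, 1.0, 99.0)),
            "stim_psi_target": (
                None if psi_tgt is None
                else float(np.clip(psi_tgt + d_tgt, 1.0, 99.0))
            ),
            "responsive_source": resp_src,
            "responsive_target": resp_tgt,
            "conserved_response": conserved,
            "orthologous": tgt_id is not None,
        })

    for tgt in tgt_only:
        psi, _ = draw_pairwise_basal(paired=False)
        cls = _classify(psi)
        responsive = bool(rng.random() < config.responsive_fraction)
        d = 0.0
        if responsive:
            preferred = -1 if rng.random() < config.sign_negative_fraction else 1
            mag = float(_truncnorm(rng, config.delta_mean, config.delta_sd,
                                   config.delta_min, config.delta_max))
            d = _feasible_sign(preferred, [psi], mag) * mag
        rows.append({
            "source_event_id": None, "target_event_id": tgt.event_id,
            "source_gene_id": "srcG" + tgt.gene_id[4:],
            "target_gene_id": tgt.gene_id,
            "inclusion_class": cls,
            "basal_psi_source": None, "basal_psi_target": psi,
            "stim_psi_source": None,
            "stim_psi_target": float(np.clip(psi + d, 1.0, 99.0)),
            "responsive_source": False, "responsive_target": responsive,
            "conserved_response": False, "orthologous": False,
        })

    events = pd.DataFrame(rows)

    # gene-level regulation labels mirror the gene-level calling criteria,
    # which are defined over 1:1 orthologous events only: a gene is
    # conserved-regulated when some orthologous event responds in each species
    gene_rows = []
    for gene, sub in events.groupby("target_gene_id", sort=True):
        orth = sub[sub["orthologous"]]
        in_src = bool(orth["responsive_source"].any())
        in_tgt = bool(orth["responsive_target"].any())
        if in_src and in_tgt:
            label = "conserved"
        elif in_tgt:
            label = "target_only"
        elif in_src:
            label = "source_only"
        else:
            label = "unregulated"
        gene_rows.append({
            "source_gene_id": "srcG" + gene[4:], "target_gene_id": gene,
            "regulated_source": in_src, "regulated_target": in_tgt,
            "label": label,
            "has_orthologous_event": bool(sub["orthologous"].any()),
        })
    genes = pd.DataFrame(gene_rows)

    paired = events[events["orthologous"]]
    realized = None
    if len(paired) >= 3:
        realized = float(np.corrcoef(
            paired["basal_psi_source"].astype(float),
            paired["basal_psi_target"].astype(float))[0, 1])
    return SimTruth(events=events, genes=genes, realized_basal_psi_corr=realized)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _draw_counts(config: SimConfig, rng: np.random.Generator,
                 event_ids: list[str], psis: np.ndarray,
                 condition: Condition) -> list[ReplicateCounts]:
    li, ls = config.inclusion_eff_len, config.skipping_eff_len
    frac = psis / 100.0
    q = frac * li / (frac * li + (1.0 - frac) * ls)
    n_ev = len(event_ids)
    totals = rng.poisson(config.depth, size=(n_ev, config.replicates))
    if config.dispersion:
        nu = (1.0 - config.dispersion) / config.dispersion
        p_rep = rng.beta(np.maximum(q[:, None] * nu, 1e-9),
                         np.maximum((1.0 - q[:, None]) * nu, 1e-9),
                         size=(n_ev, config.replicates))
    else:
        p_rep = np.broadcast_to(q[:, None], (n_ev, config.replicates))
    inc = rng.binomial(totals, p_rep)
    skp = totals - inc
    out = []
    for i, eid in enumerate(event_ids):
        out.append(ReplicateCounts(
            event_id=eid, condition=condition,
            inclusion_counts=tuple(int(v) for v in inc[i]),
            skipping_counts=tuple(int(v) for v in skp[i]),
            inclusion_eff_len=li, skipping_eff_len=ls,
        ))
    return out


def _simulate_counts(config: SimConfig, rng: np.random.Generator,
                     truth: SimTruth) -> dict[tuple[str, str], list[ReplicateCounts]]:
    ev = truth.events
    counts: dict[tuple[str, str], list[ReplicateCounts]] = {}
    src = ev[ev["source_event_id"].notna()]
    tgt = ev[ev["target_event_id"].notna()]
    for species, frame, id_col, basal_col, stim_col in (
        ("source", src, "source_event_id", "basal_psi_source", "stim_psi_source"),
        ("target", tgt, "target_event_id", "basal_psi_target", "stim_psi_target"),
    ):
        ids = frame[id_col].tolist()
        counts[(species, "basal")] = _draw_counts(
            config, rng, ids, frame[basal_col].astype(float).to_numpy(),
            Condition.basal)
        counts[(species, "stimulated")] = _draw_counts(
            config, rng, ids, frame[stim_col].astype(float).to_numpy(),
            Condition.stimulated)
    return counts


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimConfig) -> SimBundle:
    """Generate the full two-species fixture; deterministic in config.seed."""
    rng = np.random.default_rng(config.seed)
    (events_source, events_target, chain_text, chains,
     ortholog_map, pair_of_source) = _build_genome_pair(config, rng)
    truth = _simulate_truth(config, rng, events_source, events_target,
                            pair_of_source)
    counts = _simulate_counts(config, rng, truth)
    return SimBundle(
        config=config, events_source=events_source,
        events_target=events_target, chain_text=chain_text, chains=chains,
        ortholog_map=ortholog_map, counts=counts, truth=truth,
    )


def simulate_correlated_panel(
    n_events: int,
    groups: dict[str, str],
    rho_within: float = 0.8,
    rho_between: float = 0.5,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Panel of datasets with block-structured cross-dataset correlation.

    ``groups`` maps dataset name to a group label (e.g. species); values for
    the shared events are correlated ``rho_within`` inside a group and
    ``rho_between`` across groups, imposed on the logit-PSI scale.
    """
    names = list(groups)
    k = len(names)
    cov = np.empty((k, k))
    for i, na in enumerate(names):
        for j, nb in enumerate(names):
            cov[i, j] = (1.0 if i == j
                         else rho_within if groups[na] == groups[nb]
                         else rho_between)
    # ensure positive definiteness before Cholesky
    w, v = np.linalg.eigh(cov)
    cov = (v * np.maximum(w, 1e-9)) @ v.T
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(np.zeros(k), cov, size=n_events,
                                method="cholesky")
    psi = 100.0 * expit(1.2 * z)
    return {
        name: {f"e{i:05d}": float(psi[i, j]) for i in range(n_events)}
        for j, name in enumerate(names)
    }


# ---------------------------------------------------------------------------
# bundle IO
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.json"
_FILES = {
    "source_table": "source_events.rmats.tsv",
    "target_table": "target_events.rmats.tsv",
    "chain": "source_to_target.chain",
    "ortholog_map": "ortholog_map.tsv",
    "truth_events": "truth_events.tsv",
    "truth_genes": "truth_genes.tsv",
}


def write_fixture_bundle(bundle: SimBundle, directory: str | Path) -> Path:
    """Write all fixture files plus a manifest sufficient for regeneration."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_rmats_table(bundle.events_source,
                      bundle.counts[("source", "basal")],
                      bundle.counts[("source", "stimulated")],
                      directory / _FILES["source_table"])
    write_rmats_table(bundle.events_target,
                      bundle.counts[("target", "basal")],
                      bundle.counts[("target", "stimulated")],
                      directory / _FILES["target_table"])
    (directory / _FILES["chain"]).write_text(bundle.chain_text)
    with (directory / _FILES["ortholog_map"]).open("w") as fh:
        for src, tgt in sorted(bundle.ortholog_map.items()):
            fh.write(f"{src}\t{tgt}\n")
    bundle.truth.events.to_csv(directory / _FILES["truth_events"],
                               sep="\t", index=False)
    bundle.truth.genes.to_csv(directory / _FILES["truth_genes"],
                              sep="\t", index=False)
    manifest = {
        "format_version": 1,
        "config": dataclasses.asdict(bundle.config),
        "files": dict(_FILES),
    }
    manifest_path = directory / MANIFEST_NAME
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path


def bundle_from_manifest(manifest_path: str | Path) -> SimBundle:
    """Regenerate a bundle byte-identically from its manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    cfg = manifest.get("config", {})
    if "seed" not in cfg:
        raise ValueError("manifest lacks a seed; cannot regenerate bundle")
    cfg = {**cfg}
    for key in ("class_mixture",):
        if key in cfg and isinstance(cfg[key], list):
            cfg[key] = tuple(cfg[key])
    return simulate_bundle(SimConfig(**cfg))


def planted_pairs(bundle: SimBundle) -> list[OrthologPair]:
    """The planted source↔target event pairing (ground truth for matching)."""
    ev = bundle.truth.events
    paired = ev[ev["orthologous"]]
    return [
        OrthologPair(
            source_event_id=row.source_event_id,
            target_event_id=row.target_event_id,
            source_gene_id=row.source_gene_id,
            target_gene_id=row.target_gene_id,
            offsets=(0, 0, 0, 0),
        )
        for row in paired.itertuples()
    ]
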