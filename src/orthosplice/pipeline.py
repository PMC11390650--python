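"""End-to-end orchestration: read → PSI → lift → match → call → compare → sets.

A run is described by a declarative config (YAML/JSON mapping) naming the
two species' event tables (the *source* species is lifted onto the *target*
species' coordinates), the chain file, the 1:1 gene-ortholog map and the
analysis parameters, whose defaults are the study thresholds: matching
tolerance 10 bp, alpha 0.05, junction-count filter > 5, |dPSI| > 10, the
20 < basal PSI < 80 gate for percent-of-maximum change, and a 20%
expression-matching band.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import compstats, conservation, differential, events as ev, liftover, orthologs

__all__ = ["RunConfig", "DatasetSpec", "run_full_comparison", "load_config"]


@dataclass(frozen=True)
class DatasetSpec:
    name: str
    species: str  # "source" or "target"
    table: str
    dialect: str = "rmats_jc"


@dataclass(frozen=True)
class RunConfig:
    datasets: tuple[DatasetSpec, ...]
    chain: str
    ortholog_map: str
    output_dir: str
    tolerance: int = 10
    alpha: float = 0.05
    min_count: int = 5
    min_delta: float = 10.0
    psi_gate: tuple[float, float] = (20.0, 80.0)
    expression_band: float = 0.2
    test_method: str = "binomial"
    seed: int = 0

    def validate(self) -> None:
        species = {d.species for d in self.datasets}
        if not {"source", "target"} <= species:
            raise ValueError("config needs at least one source and one target dataset")
        names = [d.name for d in self.datasets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate dataset names")
        for fieldname, path in (("chain", self.chain),
                                ("ortholog_map", self.ortholog_map)):
            if not Path(path).exists():
                raise FileNotFoundError(f"config field {fieldname!r}: {path} not found")
        for d in self.datasets:
            if not Path(d.table).exists():
                raise FileNotFoundError(f"dataset {d.name!r}: {d.table} not found")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    datasets = tuple(DatasetSpec(**d) for d in raw.pop("datasets"))
    if "psi_gate" in raw:
        raw["psi_gate"] = tuple(raw["psi_gate"])
    return RunConfig(datasets=datasets, **raw)


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _calls_frame(calls: Mapping[str, differential.DifferentialCall]) -> pd.DataFrame:
    rows = []
    for eid, c in sorted(calls.items()):
        rows.append({
            "event_id": eid, "basal_psi": c.basal_mean_psi,
            "stim_psi": c.stim_mean_psi, "delta_psi": c.delta_psi,
            "p_value": c.p_value, "passes_expression": c.passes_expression,
            "significant": c.significant, "pct_of_max": c.pct_of_max,
            "gate_open": c.gate_open,
        })
    return pd.DataFrame(rows)


def run_full_comparison(config: RunConfig) -> dict:
    """Execute every stage and write per-stage tables plus a JSON summary."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"parameters": {
        k: v for k, v in dataclasses.asdict(config).items() if k != "datasets"
    }}
    log["inputs"] = {d.name: {"table": d.table, "sha256": _checksum(d.table)}
                     for d in config.datasets}
    log["inputs"]["chain"] = {"table": config.chain, "sha256": _checksum(config.chain)}

    # --- read + PSI ---------------------------------------------------------
    tables: dict[str, dict] = {}
    for spec in config.datasets:
        evts, counts = ev.read_event_table(spec.table, dialect=spec.dialect,
                                           species=spec.species)
        by_cond: dict[ev.Condition, dict[str, ev.ReplicateCounts]] = {}
        for rc in counts:
            by_cond.setdefault(rc.condition, {})[rc.event_id] = rc
        psis = {
            (rc.event_id, rc.condition): ev.compute_psi(rc) for rc in counts
        }
        tables[spec.name] = {
            "spec": spec, "events": evts, "counts": counts,
            "by_cond": by_cond, "psis": psis,
        }
    log["stage_counts"] = {
        name: {"events_read": len(t["events"])} for name, t in tables.items()
    }

    # --- lift + match (shared annotations per species) ----------------------
    chains = liftover.parse_chain(config.chain)
    gene_map = orthologs.read_ortholog_map(config.ortholog_map)
    source_name = next(d.name for d in config.datasets if d.species == "source")
    target_name = next(d.name for d in config.datasets if d.species == "target")
    source_events = tables[source_name]["events"]
    target_events = tables[target_name]["events"]

    lifted, failures = [], []
    for event in source_events:
        result = liftover.lift_event(chains, event)
        if isinstance(result, ev.SpliceEvent):
            lifted.append(result)
        else:
            failures.append(result)
    pairs = orthologs.match_events(lifted, target_events,
                                   tolerance=config.tolerance,
                                   ortholog_map=gene_map)
    rates = orthologs.orthology_rates(pairs, len(source_events), len(target_events))
    pd.DataFrame([{
        "source_event_id": p.source_event_id,
        "target_event_id": p.target_event_id,
        "source_gene_id": p.source_gene_id,
        "target_gene_id": p.target_gene_id,
        "offset_upstream_end": p.offsets[0],
        "offset_target_start": p.offsets[1],
        "offset_target_end": p.offsets[2],
        "offset_downstream_start": p.offsets[3],
        "total_offset": p.total_offset,
    } for p in pairs]).to_csv(out / "ortholog_pairs.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "event_id": f.event_id, "reason": f.reason,
        "boundary_statuses": ",".join(f.boundary_statuses),
    } for f in failures]).to_csv(out / "lift_failures.tsv", sep="\t", index=False)
    log["stage_counts"]["liftover"] = {
        "lifted": len(lifted), "failed": len(failures),
    }
    log["stage_counts"]["matching"] = {
        "matched": rates.n_matched,
        "source_rate": rates.source_rate, "target_rate": rates.target_rate,
    }

    # --- differential calls per dataset -------------------------------------
    calls: dict[str, dict[str, differential.DifferentialCall]] = {}
    for name, t in tables.items():
        basal = t["by_cond"].get(ev.Condition.basal, {})
        stim = t["by_cond"].get(ev.Condition.stimulated, {})
        dataset_calls: dict[str, differential.DifferentialCall] = {}
        for eid in basal.keys() & stim.keys():
            call = differential.test_differential_inclusion(
                basal[eid], stim[eid], method=config.test_method,
                min_count=config.min_count)
            call = replace(call, significant=differential.apply_significance_filters(
                call, alpha=config.alpha, min_delta=config.min_delta))
            call = differential.annotate_pct_max(call, gate=config.psi_gate)
            dataset_calls[eid] = call
        calls[name] = dataset_calls
        _calls_frame(dataset_calls).to_csv(out / f"differential_{name}.tsv",
                                           sep="\t", index=False)
        log["stage_counts"][name]["significant"] = sum(
            c.significant for c in dataset_calls.values())

    # --- cross-species comparisons on matched pairs --------------------------
    def _mode_values(name: str, mode: str) -> dict[str, float]:
        side = tables[name]["spec"].species
        values: dict[str, float] = {}
        for p in pairs:
            eid = p.source_event_id if side == "source" else p.target_event_id
            call = calls[name].get(eid)
            if call is None:
                continue
            if mode == "basal_psi":
                v = call.basal_mean_psi
            elif mode == "delta_psi":
                v = call.delta_psi
            else:  # pct_max, gated on basal PSI
                v = call.pct_of_max if call.gate_open else None
            if v is not None:
                values[p.target_event_id] = v  # keyed by pair identity
        return values

    matrices = {}
    for mode in ("basal_psi", "delta_psi", "pct_max"):
        data = {name: _mode_values(name, mode) for name in tables}
        mat = compstats.pairwise_matrix(data)
        rframe = compstats.matrix_r_frame(mat)
        rframe.to_csv(out / f"pairwise_{mode}_r.tsv", sep="\t")
        matrices[mode] = rframe
    basal_corr = compstats.pearson_with_ci(
        list(_mode_values(source_name, "basal_psi").values()),
        [
            _mode_values(target_name, "basal_psi").get(k)
            for k in _mode_values(source_name, "basal_psi")
        ],
    )

    # AS-class enrichment between the two reference datasets
    universe = {p.target_event_id for p in pairs}
    def _as_set(name: str) -> set[str]:
        vals = _mode_values(name, "basal_psi")
        return {k for k, v in vals.items()
                if ev.classify_psi(v) is ev.InclusionClass.AS}
    enrichment = None
    try:
        enrichment = compstats.class_enrichment(
            _as_set(source_name), _as_set(target_name), universe)
    except ValueError:
        pass

    # --- conserved / species-specific gene sets ------------------------------
    source_datasets = {d.name: calls[d.name] for d in config.datasets
                       if d.species == "source"}
    if pairs:
        background = conservation.build_background(
            pairs, tables[target_name]["counts"],
            {d.name: tables[d.name]["counts"] for d in config.datasets
             if d.species == "source"},
            min_count=config.min_count)
        labels = conservation.label_genes(
            pairs, calls[target_name], source_datasets, background,
            alpha=config.alpha, min_delta=config.min_delta)
    else:  # nothing matched: no orthologous universe to label
        background, labels = set(), {}
    pd.DataFrame([
        {"gene_id": l.gene_id, "label": l.label,
         "supporting_events": ",".join(l.supporting_events)}
        for l in sorted(labels.values(), key=lambda l: l.gene_id)
    ]).to_csv(out / "gene_regulation_labels.tsv", sep="\t", index=False)

    summary = {
        "log": log,
        "orthology": {
            "matched": rates.n_matched,
            "source_rate": rates.source_rate,
            "target_rate": rates.target_rate,
        },
        "basal_correlation": {
            "r": basal_corr.r, "n": basal_corr.n,
            "ci": [basal_corr.ci_low, basal_corr.ci_high],
        },
        "as_class_enrichment": (
            None if enrichment is None else {
                "fold": enrichment.fold_enrichment,
                "ci": [enrichment.fold_ci_low, enrichment.fold_ci_high],
                "fisher_p": enrichment.fisher_p,
                "table": list(enrichment.table),
            }
        ),
        "pairwise_r": {mode: m.to_dict() for mode, m in matrices.items()},
        "gene_sets": {
            label: sorted(g.gene_id for g in labels.values() if g.label == label)
            for label in conservation.LABELS
        },
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n")
    return summary
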