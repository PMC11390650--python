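#!/usr/bin/env python
"""Conserved vs species-specific regulated gene sets and target enrichment.

Runs the full pipeline on the simulated bundle, derives the background of
genes with orthologous expressed events, partitions genes into conserved /
species-specific / unregulated sets, scores recovery against the planted
truth, and tests enrichment of a synthetic splicing-factor target set in
the conserved events.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from orthosplice.conservation import factor_target_enrichment
from orthosplice.pipeline import DatasetSpec, RunConfig, run_full_comparison
from orthosplice.simulate import bundle_from_manifest

ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "results" / "bundle"
OUT = ROOT / "results"


def main() -> None:
    bundle = bundle_from_manifest(BUNDLE / "manifest.json")
    cfg = RunConfig(
        datasets=(
            DatasetSpec("mouse_div4", "source", str(BUNDLE / "source_events.rmats.tsv")),
            DatasetSpec("human_esc", "target", str(BUNDLE / "target_events.rmats.tsv")),
        ),
        chain=str(BUNDLE / "source_to_target.chain"),
        ortholog_map=str(BUNDLE / "ortholog_map.tsv"),
        output_dir=str(OUT / "pipeline_run"),
    )
    summary = run_full_comparison(cfg)

    genes = bundle.truth.genes
    print("gene regulation sets (called | planted):")
    for truth_label, called_label in (("conserved", "conserved"),
                                      ("target_only", "species_specific_A"),
                                      ("source_only", "species_specific_B")):
        true = set(genes[genes["label"] == truth_label]["target_gene_id"])
        called = set(summary["gene_sets"][called_label])
        tp = len(true & called)
        print(f"  {called_label}: {len(called)} | {len(true)}  "
              f"precision {tp / max(len(called), 1):.3f}  "
              f"recall {tp / max(len(true), 1):.3f}")

    # synthetic factor target set: enriched 3x among conserved-response events
    rng = np.random.default_rng(17)
    ev_truth = bundle.truth.events
    orth = ev_truth[ev_truth["orthologous"]]
    conserved_events = set(orth[orth["conserved_response"]]["target_event_id"])
    background = set(orth["target_event_id"])
    targets = {e for e in background
               if rng.random() < (0.45 if e in conserved_events else 0.15)}
    res = factor_target_enrichment({"factorX": targets}, conserved_events,
                                   background)["factorX"]
    print(f"factorX targets in conserved events: odds ratio "
          f"{res.odds_ratio:.2f}, Fisher p = {res.fisher_p:.2e} "
          f"(table {res.table})")
    pd.DataFrame([{
        "factor": "factorX", "a": res.a, "b": res.b, "c": res.c, "d": res.d,
        "fold_enrichment": res.fold_enrichment, "odds_ratio": res.odds_ratio,
        "fisher_p": res.fisher_p,
    }]).to_csv(OUT / "factor_enrichment.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
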