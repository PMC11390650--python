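"""Synthetic-data generator: determinism, planted structure, chain validity."""

import numpy as np
import pytest

from orthosplice.events import compute_psi
from orthosplice.liftover import lift_event, parse_chain_text
from orthosplice.orthologs import match_events, orthology_rates
from orthosplice.simulate import (
    SimConfig,
    bundle_from_manifest,
    planted_pairs,
    simulate_bundle,
    simulate_correlated_panel,
    write_fixture_bundle,
)
from oracles import expand_chain_per_base


class TestConfigValidation:
    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(orthologous_fraction=1.5)

    def test_bad_correlation_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(basal_logit_psi_corr=-2.0)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(replicates=1)


class TestGenomePair:
    def test_full_orthology_zero_jitter_recovers_everything(self):
        cfg = SimConfig(n_genes=40, orthologous_fraction=1.0, jitter=0,
                        decoy_gap_fraction=0.0, seed=2)
        b = simulate_bundle(cfg)
        lifted = [lift_event(b.chains, e) for e in b.events_source]
        pairs = match_events([e for e in lifted if not hasattr(e, "reason")],
                             b.events_target, tolerance=10,
                             ortholog_map=b.ortholog_map)
        rates = orthology_rates(pairs, len(b.events_source), len(b.events_target))
        assert rates.source_rate == 1.0
        assert all(p.offsets == (0, 0, 0, 0) for p in pairs)

    def test_jitter_within_tolerance_always_matches(self, small_bundle):
        b = small_bundle
        lifted = [lift_event(b.chains, e) for e in b.events_source]
        ok = [e for e in lifted if not hasattr(e, "reason")]
        pairs = match_events(ok, b.events_target, tolerance=10,
                             ortholog_map=b.ortholog_map)
        rate = len(pairs) / len(b.events_source)
        assert rate == pytest.approx(b.config.orthologous_fraction, abs=1e-9)
        planted = {(p.source_event_id, p.target_event_id)
                   for p in planted_pairs(b)}
        assert {(p.source_event_id, p.target_event_id) for p in pairs} == planted

    def test_chain_passes_parser_and_per_base_oracle(self, small_bundle):
        chains = parse_chain_text(small_bundle.chain_text)  # re-validates
        rng = np.random.default_rng(0)
        sample = rng.choice(len(chains.chains), size=20, replace=False)
        for idx in sample:
            chain = chains.chains[idx]
            oracle = expand_chain_per_base(chain)
            for pos in range(chain.t_start, chain.t_end, 13):
                q_name, q_pos, flip = oracle[pos]
                got = chain.lift(pos)
                assert got == (q_name, q_pos, flip)

    def test_decoy_events_fail_to_lift(self):
        cfg = SimConfig(n_genes=60, orthologous_fraction=0.5,
                        decoy_gap_fraction=1.0, seed=4)
        b = simulate_bundle(cfg)
        failures = [e for e in (lift_event(b.chains, s) for s in b.events_source)
                    if hasattr(e, "reason")]
        n_non_orth = len(b.events_source) - int(
            b.truth.events["orthologous"].sum())
        assert len(failures) == n_non_orth
        assert all("gap" in f.boundary_statuses for f in failures)


class TestTruth:
    def test_no_response_when_fraction_zero(self):
        cfg = SimConfig(n_genes=30, responsive_fraction=0.0, seed=5)
        ev = simulate_bundle(cfg).truth.events
        assert (ev["stim_psi_source"].dropna()
                == ev["basal_psi_source"].dropna().clip(1, 99)).all()
        assert not ev["responsive_source"].any()

    def test_perfect_basal_correlation_when_rho_one(self):
        cfg = SimConfig(n_genes=30, basal_logit_psi_corr=1.0, seed=6)
        ev = simulate_bundle(cfg).truth.events
        paired = ev[ev["orthologous"]]
        assert np.allclose(paired["basal_psi_source"].astype(float),
                           paired["basal_psi_target"].astype(float))

    def test_moderate_correlation_realized(self):
        cfg = SimConfig(n_genes=400, events_per_gene=3,
                        basal_logit_psi_corr=0.5, seed=7)
        b = simulate_bundle(cfg)
        ev = b.truth.events
        paired = ev[ev["orthologous"]]
        logit = lambda p: np.log(p / (100 - p))
        r = np.corrcoef(logit(paired["basal_psi_source"].astype(float)),
                        logit(paired["basal_psi_target"].astype(float)))[0, 1]
        assert 0.45 <= r <= 0.55

    def test_conserved_responses_share_direction(self, small_bundle):
        ev = small_bundle.truth.events
        cons = ev[ev["conserved_response"]]
        assert len(cons) > 10
        d_src = cons["stim_psi_source"].astype(float) - cons["basal_psi_source"].astype(float)
        d_tgt = cons["stim_psi_target"].astype(float) - cons["basal_psi_target"].astype(float)
        assert (np.sign(d_src) == np.sign(d_tgt)).all()

    def test_gene_labels_match_event_truth(self, small_bundle):
        ev = small_bundle.truth.events
        genes = small_bundle.truth.genes.set_index("target_gene_id")
        orth = ev[ev["orthologous"]]
        for gene, sub in orth.groupby("target_gene_id"):
            row = genes.loc[gene]
            assert row["regulated_source"] == sub["responsive_source"].any()
            assert row["regulated_target"] == sub["responsive_target"].any()


class TestCounts:
    def test_high_depth_recovers_true_psi(self):
        cfg = SimConfig(n_genes=20, depth=1e5, seed=8)
        b = simulate_bundle(cfg)
        truth = b.truth.events.set_index("source_event_id")
        for rc in b.counts[("source", "basal")][:30]:
            est = compute_psi(rc)
            assert est.mean_psi == pytest.approx(
                float(truth.loc[rc.event_id, "basal_psi_source"]), abs=0.5)

    def test_zero_depth_fails_expression_filter(self):
        from orthosplice.events import filter_expressed
        cfg = SimConfig(n_genes=10, depth=0.0, seed=9)
        b = simulate_bundle(cfg)
        assert filter_expressed(b.counts[("source", "basal")], 5) == set()

    def test_dispersion_increases_replicate_variance(self):
        base = simulate_bundle(SimConfig(n_genes=100, seed=10))
        disp = simulate_bundle(SimConfig(n_genes=100, dispersion=0.05, seed=10))

        def rep_var(bundle):
            vs = []
            for rc in bundle.counts[("source", "basal")]:
                psis = [p for p in compute_psi(rc).psi_per_replicate if p is not None]
                if len(psis) == bundle.config.replicates:
                    vs.append(np.var(psis))
            return np.mean(vs)

        assert rep_var(disp) > 2 * rep_var(base)


class TestBundleIO:
    def test_fixed_seed_byte_identical(self, tmp_path):
        cfg = SimConfig(n_genes=25, seed=12)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_fixture_bundle(simulate_bundle(cfg), d1)
        write_fixture_bundle(simulate_bundle(cfg), d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes()

    def test_regenerate_from_manifest(self, tmp_path):
        cfg = SimConfig(n_genes=25, seed=13)
        d1 = tmp_path / "a"
        manifest = write_fixture_bundle(simulate_bundle(cfg), d1)
        bundle2 = bundle_from_manifest(manifest)
        d2 = tmp_path / "b"
        write_fixture_bundle(bundle2, d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes()

    def test_manifest_without_seed_refused(self, tmp_path):
        import json
        path = tmp_path / "manifest.json"
        path.write_text(json.dumps({"config": {"n_genes": 5}}))
        with pytest.raises(ValueError, match="seed"):
            bundle_from_manifest(path)


class TestCorrelatedPanel:
    def test_block_structure_realized(self):
        groups = {"m1": "mouse", "m2": "mouse", "m3": "mouse",
                  "h1": "human", "h2": "human", "h3": "human"}
        panel = simulate_correlated_panel(2000, groups, 0.8, 0.5, seed=14)
        names = list(groups)
        within, between = [], []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                shared = sorted(panel[a])
                r = np.corrcoef([panel[a][k] for k in shared],
                                [panel[b][k] for k in shared])[0, 1]
                (within if groups[a] == groups[b] else between).append(r)
        assert min(within) > max(between)
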