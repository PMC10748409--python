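import json
import os

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panelforge.config import BlockSpec, SimulationConfig
from panelforge.consensus import variant_key
from panelforge.fixtures import make_cohort_fixture
from panelforge.haplotype_blocks import em_haplotypes, dprime_point
from panelforge.synthetic_data import (
    AccountingComposition,
    make_accounting_fixture,
    simulate_caller_vcfs,
    simulate_genome_pair,
    simulate_genotypes_ld,
    simulate_survival,
)


def dir_bytes(path):
    out = {}
    for root, _, files in os.walk(path):
        for f in sorted(files):
            p = os.path.join(root, f)
            out[os.path.relpath(p, path)] = open(p, "rb").read()
    return out


class TestConfig:
    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError, match="caller_fn_rate"):
            SimulationConfig(caller_fn_rate=1.5).validate()

    def test_overplanted_outcomes_rejected(self):
        with pytest.raises(ValueError, match="exceed n_snps"):
            SimulationConfig(n_snps=3, n_no_ortholog=2, n_gap_at_snp=2).validate()

    def test_block_span_must_hold_markers(self):
        with pytest.raises(ValueError, match="cannot hold"):
            BlockSpec(10, 5).validate()

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_snps=7, beta=[0.5, -0.5])
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SimulationConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg


class TestGenomePair:
    def test_zero_edit_config_gives_identity_chain(self):
        pair = simulate_genome_pair(SimulationConfig(seed=1, n_snps=4))
        assert len(pair.chains) == 1
        assert pair.chains[0].blocks == [(len(pair.source["chr1"]), 0, 0)]
        assert pair.source == pair.target

    def test_planted_insertion_marks_window_too_long(self):
        cfg = SimulationConfig(seed=2, n_snps=3, n_too_long=1)
        pair = simulate_genome_pair(cfg)
        labels = [v["expected_status"] for v in pair.truth.values()]
        assert labels.count("too_long") == 1

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_snps=20, n_no_ortholog=3,
                               n_gap_at_snp=2, n_inverted=2,
                               substitution_rate=0.02)
        for d in ("a", "b"):
            simulate_genome_pair(cfg).write(tmp_path / d)
        assert dir_bytes(tmp_path / "a") == dir_bytes(tmp_path / "b")

    def test_truth_json_written(self, tmp_path):
        simulate_genome_pair(SimulationConfig(seed=1, n_snps=3)).write(tmp_path)
        truth = json.load(open(tmp_path / "truth.json"))
        assert len(truth) == 3


class TestAccountingFixture:
    def test_small_composition_arithmetic(self):
        comp = AccountingComposition(10, 2, 0, 0, 1, 0)
        fx = make_accounting_fixture(comp, seed=3)
        labels = [v["expected_status"] for v in fx.pair.truth.values()]
        assert labels.count("conserved") == 7
        assert labels.count("no_ortholog") == 2
        assert labels.count("gap_at_snp") == 1

    def test_empty_composition_is_valid(self):
        comp = AccountingComposition(0, 0, 0, 0, 0, 0)
        fx = make_accounting_fixture(comp, seed=1)
        assert fx.pair.snps.empty and fx.literature_snps.empty

    def test_overdrawn_composition_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            AccountingComposition(10, 8, 1, 1, 1, 0).validate()


class TestLdGenotypes:
    def test_genotype_entry_conservation(self):
        cfg = SimulationConfig(seed=4, n_subjects=50)
        panel, truth = simulate_genotypes_ld(cfg)
        n_markers = sum(b.n_markers for b in cfg.block_spec)
        assert panel.genotypes.shape == (50, n_markers)
        assert truth.haplotypes.shape == (100, n_markers)
        assert ((panel.genotypes >= 0) & (panel.genotypes <= 2)).all()

    def test_truth_blocks_match_block_spec(self):
        cfg = SimulationConfig(seed=4, n_subjects=30)
        _, truth = simulate_genotypes_ld(cfg)
        sizes = [b.last_snp_index - b.first_snp_index + 1 for b in truth.blocks]
        assert sizes == [b.n_markers for b in cfg.block_spec]

    def test_cross_block_dprime_near_zero_in_expectation(self):
        # free recombination between blocks: mean |D'| over seeds is small
        vals = []
        for seed in range(100):
            cfg = SimulationConfig(
                seed=seed, n_subjects=150, founder_haplotypes=2,
                block_spec=[BlockSpec(2, 500, 1.0), BlockSpec(2, 500, 1.0)],
            )
            panel, _ = simulate_genotypes_ld(cfg)
            t = em_haplotypes(panel.genotypes[:, 1], panel.genotypes[:, 2])
            if t.informative:
                vals.append(dprime_point(t))
        assert np.mean(vals) < 0.2

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=8, n_subjects=40)
        a, _ = simulate_genotypes_ld(cfg)
        b, _ = simulate_genotypes_ld(cfg)
        assert (a.genotypes == b.genotypes).all()


class TestCallerVcfs:
    def test_error_free_callers_are_identical(self, tmp_path):
        fx = make_cohort_fixture(seed=6, n_samples=3,
                                 polymorphic_carrier_counts=(2, 3))
        cfg = SimulationConfig(seed=6)
        simulate_caller_vcfs(
            fx.reference, fx.truth_variants[["chrom", "pos", "ref", "alt"]],
            fx.genotypes, cfg, tmp_path,
        )
        for s in fx.samples:
            bodies = []
            for c in ("caller1", "caller2", "caller3"):
                lines = open(tmp_path / f"{s}.{c}.vcf").readlines()
                body = [l.split("\t") for l in lines if not l.startswith("#")]
                bodies.append([(f[0], f[1], f[3], f[4], f[9]) for f in body])
            assert bodies[0] == bodies[1] == bodies[2]

    def test_caller_union_equals_truth_plus_planted_fps(self, tmp_path):
        fx = make_cohort_fixture(seed=7, n_samples=5,
                                 polymorphic_carrier_counts=(3, 2, 4))
        cfg = SimulationConfig(seed=7, caller_fn_rate=0.2, caller_fp_rate=0.1)
        labels = simulate_caller_vcfs(
            fx.reference, fx.truth_variants[["chrom", "pos", "ref", "alt"]],
            fx.genotypes, cfg, tmp_path, rng=np.random.default_rng(1),
        )
        import pysam

        union = set()
        for f in os.listdir(tmp_path):
            if not f.endswith(".vcf"):
                continue
            with pysam.VariantFile(str(tmp_path / f)) as vf:
                for rec in vf:
                    union.add(f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alts[0]}")
        carried = {
            k for k in fx.genotypes.columns if (fx.genotypes[k] > 0).any()
        }
        planted_fps = {k for lab in labels.values() for k in lab["fp"]}
        dropped = set()
        for k in carried:
            carriers = set(fx.genotypes.index[fx.genotypes[k] > 0])
            if all(
                k in labels[f"{s}.{c}"]["fn"]
                for s in carriers for c in ("caller1", "caller2", "caller3")
            ):
                dropped.add(k)
        assert union == (carried - dropped) | planted_fps


class TestSurvival:
    def test_null_betas_balanced_km(self):
        # carriers and non-carriers are exchangeable when beta = 0:
        # logrank-style mean event-time difference stays small over reps
        diffs = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            G = pd.DataFrame({"v": (rng.random(80) < 0.5).astype(int)})
            cfg = SimulationConfig(seed=seed, beta=[], censor_fraction=0.0,
                                   n_subjects=80)
            surv = simulate_survival(G, cfg, np.random.default_rng(seed + 9))
            t = surv["time"].to_numpy()
            diffs.append(t[G["v"] == 1].mean() - t[G["v"] == 0].mean())
        assert abs(np.mean(diffs)) < 15  # days, baseline median ~208

    def test_censor_fraction_calibrated(self):
        fracs = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            G = pd.DataFrame({"v": (rng.random(200) < 0.4).astype(int)})
            cfg = SimulationConfig(seed=seed, beta=[np.log(2)],
                                   censor_fraction=7 / 29, n_subjects=200)
            surv = simulate_survival(G, cfg, np.random.default_rng(seed + 5))
            fracs.append(1 - surv["event"].mean())
        assert np.mean(fracs) == pytest.approx(7 / 29, abs=0.03)

    def test_beta_longer_than_variants_rejected(self):
        G = pd.DataFrame({"v": [0, 1]})
        cfg = SimulationConfig(seed=1, beta=[0.1, 0.2], n_subjects=2)
        with pytest.raises(ValueError, match="more beta"):
            simulate_survival(G, cfg)

    def test_nonfinite_beta_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            SimulationConfig(beta=[float("inf")]).validate()


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(2, 20))
def test_genome_pair_determinism_property(seed, n):
    cfg = SimulationConfig(seed=seed, n_snps=n)
    a = simulate_genome_pair(cfg)
    b = simulate_genome_pair(cfg)
    assert a.source == b.source and a.target == b.target
    assert a.snps.equals(b.snps)
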