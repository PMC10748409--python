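import os
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from panelforge.config import SimulationConfig
from panelforge.consensus import (
    Variant,
    cohort_filter,
    consensus,
    dedup_patterns,
    load_cohort_calls,
    normalize_variant,
    variant_key,
)
from panelforge.fixtures import make_cohort_fixture
from panelforge.synthetic_data import denormalize_variant, simulate_caller_vcfs

from oracles import brute_carrier_filter, consensus_from_labels, leftmost_parsimonious


def random_indel_case(rng):
    """A random reference window plus a denormalizable 1-3 bp indel."""
    seq = "".join(rng.choice(np.array(list("ACGT")), size=60))
    pos = int(rng.integers(5, 40))
    if rng.random() < 0.5:  # deletion
        k = int(rng.integers(1, 4))
        ref = seq[pos - 1 : pos + k]
        alt = seq[pos - 1]
    else:  # insertion
        k = int(rng.integers(1, 4))
        ins = "".join(rng.choice(np.array(list("ACGT")), size=k))
        ref = seq[pos - 1]
        alt = seq[pos - 1] + ins
    return seq, Variant("chr1", pos, ref, alt)


class TestNormalize:
    def test_snp_unchanged(self):
        genome = {"chr1": "ACGTACGT"}
        v = Variant("chr1", 3, "G", "C")
        assert normalize_variant(genome, v) == v

    def test_matches_exhaustive_left_shift_oracle(self, rng):
        for _ in range(150):
            seq, v = random_indel_case(rng)
            genome = {"chr1": seq}
            got = normalize_variant(genome, v)
            p, r, a = leftmost_parsimonious(seq, v.pos, v.ref, v.alt)
            assert (got.pos, got.ref, got.alt) == (p, r, a), (v, got, (p, r, a))

    def test_idempotent(self, rng):
        for _ in range(80):
            seq, v = random_indel_case(rng)
            genome = {"chr1": seq}
            once = normalize_variant(genome, v)
            assert normalize_variant(genome, once) == once

    def test_ref_mismatch_names_site(self):
        with pytest.raises(ValueError, match="chr1:3"):
            normalize_variant({"chr1": "AAAAAA"}, Variant("chr1", 3, "G", "C"))

    @pytest.mark.skipif(shutil.which("bcftools") is None,
                        reason="bcftools not available")
    def test_matches_bcftools_norm(self, rng, tmp_path):
        cases = [random_indel_case(rng) for _ in range(40)]
        for i, (seq, v) in enumerate(cases):
            ref_path = tmp_path / f"r{i}.fa"
            ref_path.write_text(f">chr1\n{seq}\n")
            vcf_path = tmp_path / f"v{i}.vcf"
            vcf_path.write_text(
                "##fileformat=VCFv4.2\n"
                f"##contig=<ID=chr1,length={len(seq)}>\n"
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
                f"chr1\t{v.pos}\t.\t{v.ref}\t{v.alt}\t30\t.\t.\n"
            )
            out = subprocess.run(
                ["bcftools", "norm", "-f", str(ref_path), str(vcf_path)],
                capture_output=True, text=True, check=True,
            )
            line = [l for l in out.stdout.splitlines() if not l.startswith("#")][0]
            _, bpos, _, bref, balt = line.split("\t")[:5]
            got = normalize_variant({"chr1": seq}, v)
            assert (got.pos, got.ref, got.alt) == (int(bpos), bref, balt)


class TestJitter:
    def test_denormalized_form_normalizes_back(self, cohort_run):
        fx = cohort_run["fixture"]
        for row in fx.truth_variants.itertuples(index=False):
            v = Variant(row.chrom, int(row.pos), row.ref, row.alt)
            dv = denormalize_variant(fx.reference, v)
            assert normalize_variant(fx.reference, dv) == v
            if len(v.ref) != len(v.alt):
                assert dv != v  # indels must really be jittered


class TestConsensus:
    def test_jitter_free_simulation_recovers_truth_exactly(self, cohort_run):
        fx = cohort_run["fixture"]
        result = cohort_run["result"]
        assert {variant_key(v) for v in result.pooled} == set(fx.genotypes.columns)
        got = result.matrix.sort_index(axis=1)
        want = fx.genotypes.sort_index(axis=1).astype(got.dtypes.iloc[0])
        assert (got == want).all().all()

    def test_two_of_three_callers_never_pooled(self, tmp_path):
        fx = make_cohort_fixture(seed=9, n_samples=4,
                                 polymorphic_carrier_counts=(2, 3))
        cfg = SimulationConfig(seed=9)
        fx.write(tmp_path, cfg)
        # remove one variant from one caller's files in every sample
        victim = fx.truth_variants.iloc[0]
        for s in fx.samples:
            path = os.path.join(fx.vcf_dir, f"{s}.caller2.vcf")
            lines = [
                l for l in open(path)
                if l.startswith("#")
                or not (l.split("\t")[1] == str(victim.pos)
                        and l.split("\t")[3] == victim.ref)
            ]
            open(path, "w").write("".join(lines))
        calls = load_cohort_calls(fx.vcf_dir, fx.samples)
        result = consensus(calls, fx.reference)
        assert victim.key not in {variant_key(v) for v in result.pooled}

    def test_low_qual_call_blocks_consensus_in_that_sample(self, tmp_path):
        fx = make_cohort_fixture(seed=10, n_samples=4,
                                 polymorphic_carrier_counts=(4, 2))
        cfg = SimulationConfig(seed=10)
        fx.write(tmp_path, cfg)
        victim = fx.truth_variants.iloc[0]
        sample = fx.samples[0]
        path = os.path.join(fx.vcf_dir, f"{sample}.caller1.vcf")
        out = []
        for l in open(path):
            f = l.split("\t")
            if not l.startswith("#") and f[1] == str(victim.pos) and f[3] == victim.ref:
                f[5] = "19.0"  # just below the QUAL >= 20 cut
                l = "\t".join(f)
            out.append(l)
        open(path, "w").write("".join(out))
        calls = load_cohort_calls(fx.vcf_dir, fx.samples)
        result = consensus(calls, fx.reference)
        assert result.matrix.loc[sample, victim.key] == -1  # strict rule: missing

    def test_pooled_set_matches_label_set_algebra(self, tmp_path, rng):
        fx = make_cohort_fixture(seed=11, n_samples=8,
                                 polymorphic_carrier_counts=(3, 4, 5, 2))
        cfg = SimulationConfig(seed=11, caller_fn_rate=0.15, caller_fp_rate=0.1,
                               caller_lowqual_rate=0.1, indel_jitter_rate=0.5)
        labels = simulate_caller_vcfs(
            fx.reference, fx.truth_variants[["chrom", "pos", "ref", "alt"]],
            fx.genotypes, cfg, tmp_path, rng=np.random.default_rng(42),
        )
        calls = load_cohort_calls(tmp_path, fx.samples)
        result = consensus(calls, fx.reference)
        callers = ("caller1", "caller2", "caller3")
        pooled_oracle, per_sample = consensus_from_labels(
            fx.genotypes, labels, callers
        )
        assert {variant_key(v) for v in result.pooled} == pooled_oracle
        for s, cons in result.per_sample_consensus.items():
            assert {variant_key(v) for v in cons} == per_sample[s]

    def test_missing_caller_file_is_an_error(self, cohort_run):
        fx = cohort_run["fixture"]
        with pytest.raises(FileNotFoundError, match="s01/callerX"):
            load_cohort_calls(fx.vcf_dir, ["s01"], callers=("caller1", "callerX"))

    def test_record_order_invariance(self, cohort_run, tmp_path):
        fx = cohort_run["fixture"]
        sample = fx.samples[0]
        import shutil as sh

        for f in os.listdir(cohort_run["fixture"].vcf_dir):
            sh.copy(os.path.join(fx.vcf_dir, f), tmp_path / f)
        # reverse the body of one file
        path = tmp_path / f"{sample}.caller1.vcf"
        lines = open(path).readlines()
        head = [l for l in lines if l.startswith("#")]
        body = [l for l in lines if not l.startswith("#")]
        open(path, "w").write("".join(head + body[::-1]))
        calls = load_cohort_calls(tmp_path, fx.samples)
        result = consensus(calls, fx.reference)
        base = cohort_run["result"]
        assert result.pooled == base.pooled
        assert result.matrix.equals(base.matrix)


class TestCohortFilter:
    def test_carrier_count_boundaries(self):
        m = pd.DataFrame({
            "v10": [1] * 10 + [0] * 19,
            "v11": [1] * 11 + [0] * 18,
            "v18": [2] * 18 + [0] * 11,
            "v19": [1] * 19 + [0] * 10,
        })
        assert cohort_filter(m) == ["v11", "v18"]

    def test_missing_genotype_among_noncarriers_excludes(self):
        m = pd.DataFrame({"v": [1] * 12 + [-1] + [0] * 16})
        assert cohort_filter(m) == []

    def test_matches_brute_force_count_filter(self, rng):
        for _ in range(100):
            m = pd.DataFrame(
                rng.choice([-1, 0, 1, 2], size=(29, 8), p=[0.05, 0.5, 0.3, 0.15]),
                columns=[f"v{i}" for i in range(8)],
            )
            assert cohort_filter(m) == brute_carrier_filter(m)


class TestDedup:
    def test_cohort_fixture_collapses_12_to_10(self, cohort_run):
        assert len(cohort_run["polymorphic"]) == 12
        assert len(cohort_run["kept"]) == 10
        removed_pairs = {(kept, dup) for dup, kept in cohort_run["removed"].items()}
        truth_pairs = {
            (a, b) for a, b in cohort_run["fixture"].truth["duplicate_pairs"]
        }
        assert {(k, d) for k, d in removed_pairs} == truth_pairs

    def test_distinct_patterns_are_identity(self, rng):
        m = pd.DataFrame(rng.integers(0, 3, size=(10, 5)),
                         columns=[f"chr1:{100 + i}:A:G" for i in range(5)])
        kept, removed = dedup_patterns(list(m.columns), m, {})
        # patterns are distinct with overwhelming probability for this seed
        assert removed == {} and len(kept) == 5

    def test_three_identical_patterns_keep_smallest_coordinate(self):
        cols = ["chr1:300:A:G", "chr1:100:A:G", "chr1:200:A:G"]
        m = pd.DataFrame({c: [1, 0, 1] for c in cols})
        target = {c: "t0" for c in cols}
        kept, removed = dedup_patterns(cols, m, target)
        assert kept == ["chr1:100:A:G"]
        assert set(removed) == {"chr1:200:A:G", "chr1:300:A:G"}

    def test_dedup_is_idempotent(self, cohort_run):
        kept, _ = dedup_patterns(
            cohort_run["kept"], cohort_run["result"].matrix, cohort_run["target_of"]
        )
        assert kept == cohort_run["kept"]
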