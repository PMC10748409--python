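import os

import numpy as np
import pytest

from panelforge import harvest as hv
from panelforge.chain import ChainIndex
from panelforge.config import SimulationConfig
from panelforge.consensus import (
    assign_targets,
    cohort_filter,
    consensus,
    dedup_patterns,
    load_cohort_calls,
)
from panelforge.fixtures import (
    make_cohort_fixture,
    make_known_snp_map,
    make_prioritization_fixture,
)
from panelforge.haplotype_blocks import assign_proxies, proxies_table
from panelforge.liftover import run_cascade
from panelforge.panel_builder import build_panel
from panelforge.prioritization import filter_annotation, prioritize, read_gene_models
from panelforge.synthetic_data import make_accounting_fixture


@pytest.fixture(scope="session")
def design_chain(tmp_path_factory):
    """The full panel-design pipeline run once on the composed fixture:
    filter cascade -> prioritization -> proxy assignment -> panel."""
    fx = make_accounting_fixture(seed=1)
    records = hv.merge_sources([fx.pair.snps], origins=["snps"])
    results = run_cascade(
        records, fx.pair.source, fx.pair.target, ChainIndex(fx.pair.chains)
    )
    loci = [(r.snp.rsid, r.target_locus) for r in results if r.status == "conserved"]
    pfx = make_prioritization_fixture(loci)
    gtf = tmp_path_factory.mktemp("annotation") / "genes.gtf"
    pfx.write_gtf(gtf)
    genes = filter_annotation(read_gene_models(gtf))
    selected = prioritize(
        loci, genes, pfx.tf_class_table, pfx.deg_genes,
        pfx.key_regulator_genes, pfx.edges,
    )
    selected_loci = [(p.name, p.locus) for p in selected]
    known = make_known_snp_map(selected_loci)
    assignments, unassigned = assign_proxies(selected_loci, known, 5725.0)
    targets, summary = build_panel(
        proxies_table(assignments), fx.literature_snps, fx.pair.target
    )
    return {
        "fixture": fx,
        "records": records,
        "results": results,
        "loci": loci,
        "pfx": pfx,
        "genes": genes,
        "selected": selected,
        "known": known,
        "assignments": assignments,
        "unassigned": unassigned,
        "targets": targets,
        "summary": summary,
    }


@pytest.fixture(scope="session")
def cohort_run(tmp_path_factory):
    """The 29-sample cohort fixture pushed through consensus genotyping."""
    fx = make_cohort_fixture(seed=5)
    cfg = SimulationConfig(seed=5, indel_jitter_rate=0.3)
    out = tmp_path_factory.mktemp("cohort")
    fx.write(out, cfg)
    calls = load_cohort_calls(fx.vcf_dir, fx.samples)
    result = consensus(calls, fx.reference)
    polymorphic = cohort_filter(result.matrix)
    target_of = assign_targets(result.pooled, fx.target_bed)
    kept, removed = dedup_patterns(polymorphic, result.matrix, target_of)
    return {
        "fixture": fx,
        "out": str(out),
        "calls": calls,
        "result": result,
        "polymorphic": polymorphic,
        "target_of": target_of,
        "kept": kept,
        "removed": removed,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
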