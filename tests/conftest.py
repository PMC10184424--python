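"""Shared fixtures: scaled study conditions and per-seed pipeline bundles."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

import kfcnet as k

#: scaled-down study conditions used by the statistical property tests; all
#: structural knobs (planting strength, homophily, module, biases) stay at
#: the generator defaults
TEST_SCALE = dict(
    n_components=80,
    n_targets=150,
    n_pathogenic=600,
    mean_component_degree=5.0,
    ppi_attachment=2,
    n_planted_key_components=12,
    n_background_genes=2000,
)

N_SEEDS = 20


@dataclass
class SeedRun:
    """Everything one synthetic replicate produces, computed once."""

    dataset: k.SyntheticDataset
    ct: k.CTPNetwork
    ctp: k.CTPNetwork
    results: dict  # method -> ImportanceResult
    ranking_novel: k.CDRRanking
    ranking_degree: k.CDRRanking
    kfc: list
    effective: set
    coverage: dict  # method -> effective-term coverage


def _run_seed(seed: int) -> SeedRun:
    ds = k.generate(k.SyntheticSpec(**TEST_SCALE, seed=seed))
    verdicts = k.select_active_components(ds.components)
    active = [c for c, v in zip(ds.components, verdicts) if v.active]
    ct = k.build_ct_network(active, ds.ct_edges)
    ctp = k.merge_ctp(ct, ds.ppi_edges, ds.pathogenic)
    results = {
        m: k.extract_key_network(ctp, k.score_nodes(ctp, m), m) for m in k.IMPORTANCE_METHODS
    }
    ranking_novel = k.rank_cdr(results["novel"].key_network)
    ranking_degree = k.rank_cdr(results["degree"].key_network)
    kfc = k.select_kfc(ranking_novel, 0.90)
    effective = k.effective_terms(
        ct.nodes_in_layer("target"),
        {g.symbol for g in ds.pathogenic},
        ds.gene_sets,
    )
    coverage = k.method_coverage(results, effective, ds.gene_sets) if effective else {}
    return SeedRun(
        dataset=ds,
        ct=ct,
        ctp=ctp,
        results=results,
        ranking_novel=ranking_novel,
        ranking_degree=ranking_degree,
        kfc=kfc,
        effective=effective,
        coverage=coverage,
    )


@pytest.fixture(scope="session")
def seed_runs() -> list[SeedRun]:
    """Twenty independent synthetic replicates at the scaled study conditions."""
    return [_run_seed(seed) for seed in range(N_SEEDS)]


@pytest.fixture()
def small_dataset() -> k.SyntheticDataset:
    return k.generate(k.SyntheticSpec(**TEST_SCALE, seed=3))


@pytest.fixture()
def tiny_ctp() -> k.CTPNetwork:
    """2 components, 3 targets, a PPI edge, 2 pathogenic genes (1 overlapping)."""
    comps = [
        k.ComponentRecord("c1", "one", frozenset({"HerbA"})),
        k.ComponentRecord("c2", "two", frozenset({"HerbB"})),
    ]
    ct = k.build_ct_network(comps, [("c1", "T1"), ("c1", "T2"), ("c2", "T2"), ("c2", "T3")])
    return k.merge_ctp(
        ct,
        [("T1", "T3"), ("T3", "G1")],
        [k.PathogenicGene("T2", 5), k.PathogenicGene("G1", 2)],
    )
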