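"""Shared fixtures: synthetic datasets are generated once per session."""

from __future__ import annotations

import collections

import pytest

import cypminer as cm
from cypminer.nomenclature import annotate_calls
from cypminer.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic dataset: 3 genomes, 4 families, 8 P450s/genome."""
    config = SimulationConfig(seed=7, n_genomes=3, n_families=4, p450s_per_genome=8)
    panel, records, gene_table, clusters, truth = simulate_all(config)
    return {
        "config": config,
        "panel": panel,
        "records": records,
        "gene_table": gene_table,
        "clusters": clusters,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_results(small_sim):
    """Classification + assignment over the small dataset."""
    records = small_sim["records"]
    calls = cm.classify_all(records)
    p450_calls = [c for c in calls if c.status == "P450"]
    seqs = {r.id: r.sequence for r in records}
    assignments = cm.assign_all(p450_calls, seqs, small_sim["panel"])
    annotate_calls(calls, assignments)
    return {"calls": calls, "p450_calls": p450_calls, "assignments": assignments}


@pytest.fixture(scope="session")
def default_sim():
    """The default study-scale dataset: 10 genomes, 6 families, 200 P450s."""
    config = SimulationConfig(seed=1)
    panel, records, gene_table, clusters, truth = simulate_all(config)
    return {
        "config": config,
        "panel": panel,
        "records": records,
        "gene_table": gene_table,
        "clusters": clusters,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def default_results(default_sim):
    records = default_sim["records"]
    calls = cm.classify_all(records)
    p450_calls = [c for c in calls if c.status == "P450"]
    seqs = {r.id: r.sequence for r in records}
    assignments = cm.assign_all(p450_calls, seqs, default_sim["panel"])
    annotate_calls(calls, assignments)
    signatures, residual = cm.assign_p450s_to_clusters(
        records, calls, default_sim["clusters"]
    )
    return {
        "calls": calls,
        "p450_calls": p450_calls,
        "assignments": assignments,
        "signatures": signatures,
        "residual": residual,
    }


@pytest.fixture(scope="session")
def fixtures():
    return cm.load_fixtures()


def make_p450_sequence(length: int = 420, exxr_frac: float = 0.65, cxg_tail: int = 60) -> str:
    """A minimal complete-P450-shaped sequence on an alanine background with
    ExxR and CxG at window-compliant positions."""
    seq = ["A"] * length
    e = int(length * exxr_frac)
    c = length - cxg_tail
    seq[e] = "E"
    seq[e + 3] = "R"
    seq[c] = "C"
    seq[c + 2] = "G"
    return "".join(seq)
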