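"""End-to-end pipeline orchestration and published-table-shaped reports.

``run_pipeline`` chains mining -> classification -> nomenclature ->
profiling -> cluster linkage -> phylogeny over FASTA/TSV inputs and writes
all machine-readable artifacts plus a provenance manifest (parameters and
input hashes; nothing wall-clock- or host-dependent, so re-runs are
byte-identical). ``report_table1_column`` renders the cross-taxon summary
column (13 key-value rows); ``report_from_fixtures`` recomputes it from the
packaged survey-table transcriptions without any sequence data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from . import bgc as bgc_mod
from .identification import MotifConfig, classify_all, apply_domain_prefilter, read_domain_hits
from .nomenclature import (
    AlignmentParams,
    annotate_calls,
    assign_all,
    read_panel,
    write_assignments,
)
from .phylogeny import build_distance_matrix, family_coloring, nj_tree
from .profiling import (
    SummaryStats,
    build_profile,
    cluster_heatmap,
    compute_stats,
    stats_from_values,
    write_heatmap,
    write_profile,
)
from .sequence_io import FixtureTables, load_fixtures, read_fasta, write_newick

TABLE1_ROWS = [
    "Species analysed",
    "Species without P450s",
    "Species with P450s",
    "Percentage of species with P450s",
    "No. of P450s",
    "No. of families",
    "No. of subfamilies",
    "Dominant P450 family",
    "Average No. of P450s",
    "P450 diversity percentage",
    "No. of P450s part of BGCs",
    "No. of P450 families part of BGCs",
    "Percentage of P450s part of BGCs",
]


@dataclass
class PipelineConfig:
    protein_fastas: list
    panel_path: str
    outdir: str
    clusters_path: str | None = None
    domain_hits_path: str | None = None
    motif: MotifConfig = field(default_factory=MotifConfig)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    membership_mode: str = "containment"
    include_fragments_in_signatures: bool = False
    build_tree: bool = True
    tree_max_leaves: int = 80
    seed: int = 0


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write artifacts under ``config.outdir``.

    Artifacts: calls.tsv, assignments.tsv, profile.tsv, stats.json,
    heatmap.tsv, signatures.tsv, type_aggregates.tsv, tree.nwk (+
    tree_annotation.tsv) and manifest.json. Returns the in-memory stage
    results keyed by stage name. Stage failures propagate with the stage
    name prefixed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def stage(name, fn):
        try:
            results[name] = fn()
            return results[name]
        except Exception as exc:  # annotate with the failing stage
            raise type(exc)(f"[{name}] {exc}") from exc

    records = stage(
        "read", lambda: [r for p in config.protein_fastas for r in read_fasta(p)]
    )
    hits = read_domain_hits(config.domain_hits_path) if config.domain_hits_path else None
    records = stage("prefilter", lambda: apply_domain_prefilter(records, hits))
    calls = stage("identify", lambda: classify_all(records, config.motif))
    seqs = {r.id: r.sequence for r in records}
    panel = read_panel(config.panel_path)
    p450_calls = [c for c in calls if c.status == "P450"]
    assignments = stage(
        "assign", lambda: assign_all(p450_calls, seqs, panel, config.alignment)
    )
    annotate_calls(calls, assignments)
    profile = stage("profile", lambda: build_profile(assignments, calls))

    signatures, residual = [], []
    aggregates = []
    n_in_bgc = 0
    if config.clusters_path:
        clusters = bgc_mod.read_clusters(config.clusters_path)
        signatures, residual = stage(
            "link-bgc",
            lambda: bgc_mod.assign_p450s_to_clusters(
                records,
                calls,
                clusters,
                mode=config.membership_mode,
                include_fragments=config.include_fragments_in_signatures,
            ),
        )
        aggregates = bgc_mod.aggregate_by_type(signatures)
        n_in_bgc = sum(a.n_p450_total for a in aggregates)
    n_subfamilies = int(
        pd.DataFrame(
            [(a.family, a.subfamily) for a in assignments], columns=["f", "s"]
        )
        .drop_duplicates()
        .shape[0]
    )
    stats = stage(
        "stats", lambda: compute_stats(profile, n_subfamilies, n_in_bgc)
    )
    heatmap = None
    if len(profile.genomes) >= 2 and len(profile.families) >= 2:
        heatmap = stage("heatmap", lambda: cluster_heatmap(profile))

    tree = annotation = None
    if config.build_tree and len(p450_calls) >= 3:
        tree_ids = sorted(c.protein_id for c in p450_calls)[: config.tree_max_leaves]
        tree_records = [r for r in records if r.id in set(tree_ids)]
        dm = stage("tree", lambda: build_distance_matrix(tree_records, config.alignment))
        tree = nj_tree(dm)
        annotation = family_coloring(tree, assignments)

    # ---- write artifacts ----
    pd.DataFrame(
        [
            {
                "protein_id": c.protein_id,
                "genome_id": c.genome_id,
                "status": c.status,
                "length_aa": c.evidence.length_aa,
                "has_exxr": c.evidence.has_exxr,
                "has_cxg": c.evidence.has_cxg,
                "family": c.family or "",
                "subfamily": c.subfamily or "",
            }
            for c in calls
        ]
    ).to_csv(outdir / "calls.tsv", sep="\t", index=False)
    write_assignments(assignments, outdir / "assignments.tsv")
    write_profile(profile, outdir / "profile.tsv")
    (outdir / "stats.json").write_text(
        json.dumps({"raw": vars(stats), "report": stats.report()}, indent=2, sort_keys=True)
    )
    if heatmap is not None:
        write_heatmap(heatmap, outdir / "heatmap.tsv")
    if config.clusters_path:
        bgc_mod.write_signatures(signatures, outdir / "signatures.tsv")
        bgc_mod.write_aggregates(aggregates, outdir / "type_aggregates.tsv")
    if tree is not None:
        write_newick(tree, outdir / "tree.nwk")
        annotation.to_csv(outdir / "tree_annotation.tsv", sep="\t", index=False)

    manifest = {
        "parameters": {
            "motif": vars(config.motif),
            "alignment": {
                k: v for k, v in vars(config.alignment).items() if not callable(v)
            },
            "membership_mode": config.membership_mode,
            "seed": config.seed,
            "tree_max_leaves": config.tree_max_leaves,
        },
        "inputs": {
            str(p): _sha256(p)
            for p in [
                *config.protein_fastas,
                config.panel_path,
                *( [config.clusters_path] if config.clusters_path else [] ),
            ]
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results.update(
        {
            "calls": calls,
            "assignments": assignments,
            "profile": profile,
            "stats": stats,
            "aggregates": aggregates,
            "signatures": signatures,
            "residual": residual,
            "tree": tree,
        }
    )
    return results


# ---------------------------------------------------------------------------
# Published-table-shaped reports
# ---------------------------------------------------------------------------


def report_table1_column(
    stats: SummaryStats,
    aggregates: list,
    family_counts: dict[str, int],
) -> dict:
    """The 13-row cross-taxon summary column (species counts, totals,
    dominant family, average, diversity and BGC linkage), using report-time
    rounding: integers for the average and percentages, 2 decimals for the
    diversity percentage."""
    families_in_bgc = bgc_mod.breakdown_from_aggregates(aggregates) if aggregates else {}
    dominant = max(family_counts, key=lambda f: (family_counts[f], f)) if family_counts else ""
    rep = stats.report()
    return {
        "Species analysed": stats.n_species,
        "Species without P450s": stats.n_species - stats.n_species_with_p450,
        "Species with P450s": stats.n_species_with_p450,
        "Percentage of species with P450s": round(
            100.0 * stats.n_species_with_p450 / stats.n_species
        ),
        "No. of P450s": stats.n_p450,
        "No. of families": stats.n_families,
        "No. of subfamilies": stats.n_subfamilies,
        "Dominant P450 family": dominant,
        "Average No. of P450s": rep["avg_p450"],
        "P450 diversity percentage": rep["diversity_pct"],
        "No. of P450s part of BGCs": stats.n_in_bgc,
        "No. of P450 families part of BGCs": len(families_in_bgc),
        "Percentage of P450s part of BGCs": rep["pct_in_bgc"],
    }


def fixture_family_counts(fixtures: FixtureTables) -> dict[str, int]:
    fam = fixtures.table3.drop_duplicates("family").set_index("family")["family_count"]
    return {str(k): int(v) for k, v in fam.items()}


def stats_from_fixtures(fixtures: FixtureTables) -> SummaryStats:
    """Summary statistics recomputed from the packaged survey tables: totals
    from the per-family table, species counts from the per-strain table, and
    BGC membership from the per-cluster-type table."""
    t2, t3, t4 = fixtures.table2, fixtures.table3, fixtures.table4
    fam_counts = fixture_family_counts(fixtures)
    return stats_from_values(
        n_species=len(t2),
        n_species_with_p450=int((t2["n_p450"] > 0).sum()),
        n_p450=int(sum(fam_counts.values())),
        n_families=len(fam_counts),
        n_subfamilies=int(t3[["family", "subfamily"]].drop_duplicates().shape[0]),
        n_in_bgc=int(t4["p450_count"].sum()),
    )


def report_from_fixtures(fixtures: FixtureTables | None = None) -> dict:
    """Fixtures-only mode: the full summary column recomputed from the
    packaged tables (no sequence inputs)."""
    fixtures = fixtures or load_fixtures()
    stats = stats_from_fixtures(fixtures)
    aggregates = bgc_mod.aggregates_from_fixture(fixtures.table4)
    return report_table1_column(stats, aggregates, fixture_family_counts(fixtures))


def known_family_functions() -> pd.DataFrame:
    """Static lookup of literature-known functions for P450 families seen in
    this taxon (annotation only; no computation)."""
    path = resources.files("cypminer").joinpath("data/family_functions.tsv")
    return pd.read_csv(str(path), sep="\t")
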