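"""Synthetic CYPome inputs with planted ground truth.

The generator emulates the statistical structure of a multi-strain bacterial
CYPome survey: a panel of named-P450 archetypes (mutually dissimilar below
the 40% family threshold), genomes carrying P450s whose identity to their
source archetype is calibrated into configured bands around the 40%/55%
nomenclature thresholds, P450 fragments (by truncation or heme-motif
ablation), motif-free decoy proteins, and typed gene clusters containing 0-6
P450s. Everything is emitted in the same FASTA/TSV formats the pipeline
consumes, with a ground-truth record for recovery tests.

Identity bands are enforced by measure-and-resample: alignment identity is
not a simple function of the substitution count once gaps enter, so each
planted protein is mutated, measured with the same global-identity routine
the pipeline uses, and re-mutated with an adjusted substitution count until
its identity lies strictly inside its band (bounded retries). Motif columns
are frozen for complete P450s. Defaults are chosen so that a full run
emulates the published study at desk scale: 10 genomes x 20 P450s/genome
(close to the published per-strain average of 21), a ~5% fragment rate
(129 fragments per 2643 P450s), clusters of 1-6 P450s with the observed
cluster-type frequencies, and band weights dominated by the subfamily band
(strains of the same few species are mutually close).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .identification import MotifConfig, classify_protein
from .nomenclature import AlignmentParams, PanelEntry, ReferencePanel, pairwise_identity
from .sequence_io import ProteinRecord, write_fasta, write_gene_table
from .bgc import BgcCluster, write_clusters

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# cluster-type vocabulary with observed frequencies (P450-containing cluster
# counts per type in the transcribed survey table)
BGC_TYPE_COUNTS = {
    "Bacteriocin": 47, "betalactone": 2, "butyrolactone": 1, "Indole": 54,
    "ladderane": 18, "lanthipeptide": 2, "LAP": 1, "lipolanthine": 2,
    "NRPS": 205, "NRPS-like": 30, "oligosaccharide": 35, "other": 5,
    "T1PKS": 223, "T2PKS": 76, "T3PKS": 8, "Terpene": 61,
    "transAT-PKS": 1, "transAT-PKS-like": 8,
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset (see module docstring for
    the provenance of the defaults)."""

    seed: int = 0
    n_genomes: int = 10
    n_families: int = 6
    archetype_length: int = 420
    p450s_per_genome: int = 20
    # (lo_pct, hi_pct, expected assignment basis); non-overlapping with
    # >= 2-point margins around the 40/55 thresholds
    identity_bands: tuple = (
        (57.0, 90.0, "subfamily-match"),
        (42.0, 53.0, "family-match"),
        (15.0, 38.0, "new-family"),
    )
    band_weights: tuple = (0.80, 0.15, 0.05)
    fragment_rate: float = 0.05
    decoys_per_genome: int = 5
    clusters_per_genome: int = 3
    max_p450s_per_cluster: int = 6
    cluster_size_weights: tuple = (0.45, 0.25, 0.12, 0.08, 0.06, 0.04)
    min_length: int = 300
    max_calibration_tries: int = 80

    def __post_init__(self) -> None:
        for lo, hi, _ in self.identity_bands:
            if not lo < hi:
                raise ValueError("identity band lo must be < hi")
            for t in (40.0, 55.0):
                if lo < t + 2 and hi > t - 2:
                    raise ValueError(
                        f"band ({lo},{hi}) violates the 2-point margin around {t}"
                    )
        if not 0 <= self.fragment_rate <= 1:
            raise ValueError("fragment_rate must be in [0,1]")
        if self.max_p450s_per_cluster > 6:
            raise ValueError("p450s per cluster capped at 6")


def _blosum_replacement_tables():
    """For each residue, a BLOSUM62-weighted distribution over the other 19
    (weights 2^score, favouring conservative replacements)."""
    mat = substitution_matrices.load("BLOSUM62")
    tables = {}
    for a in AA20:
        others = [b for b in AA20 if b != a]
        w = np.array([2.0 ** mat[a][b] for b in others])
        tables[a] = (others, w / w.sum())
    return tables


_REPL = _blosum_replacement_tables()


def _random_protein(rng: np.random.Generator, length: int, alphabet: str = AA20) -> list[str]:
    return list(rng.choice(list(alphabet), size=length))


def _motif_layout(length: int) -> tuple[int, int]:
    """Window-compliant planted positions: ExxR at 65% of the length, CxG 60
    residues from the C-terminus (both remain in-window after truncating a
    full-length protein down to ~280 aa)."""
    return int(length * 0.65), length - 60


def _plant_motifs(seq: list[str], exxr_at: int, cxg_at: int) -> None:
    seq[exxr_at] = "E"
    seq[exxr_at + 3] = "R"
    seq[cxg_at] = "C"
    seq[cxg_at + 2] = "G"


def _frozen_positions(exxr_at: int, cxg_at: int) -> set[int]:
    return set(range(exxr_at, exxr_at + 4)) | set(range(cxg_at, cxg_at + 3))


def _disrupt_spurious_motifs(
    seq: list[str], frozen: set[int], config: MotifConfig | None = None
) -> None:
    """Remove unintended in-window ExxR / CxG matches so motif plants and
    ablations stay unambiguous (offending E -> D, C -> S)."""
    config = config or MotifConfig()
    n = len(seq)
    exxr_lo = int(np.floor(n * (1.0 - config.exxr_cterm_frac)))
    cxg_lo = max(0, n - config.cxg_tail)
    for i in range(exxr_lo, n - 3):
        if i in frozen:
            continue
        if seq[i] == "E" and seq[i + 3] == "R":
            seq[i] = "D"
    for i in range(cxg_lo, n - 2):
        if i in frozen:
            continue
        if seq[i] == "C" and seq[i + 2] == "G":
            seq[i] = "S"


def simulate_panel(config: SimulationConfig) -> ReferencePanel:
    """Archetype panel: one named sequence per family, each carrying both
    diagnostic motifs at window-compliant positions, all pairwise identities
    below the 40% family threshold (rejection-sampled). Deterministic under
    the config seed."""
    rng = np.random.default_rng([config.seed, 0])
    params = AlignmentParams()
    L = config.archetype_length
    exxr_at, cxg_at = _motif_layout(L)
    frozen = _frozen_positions(exxr_at, cxg_at)
    entries: list[PanelEntry] = []
    tries = 0
    while len(entries) < config.n_families:
        tries += 1
        if tries > 50 * config.n_families:
            raise RuntimeError(
                "could not sample mutually dissimilar archetypes; "
                "reduce n_families or increase archetype_length"
            )
        seq = _random_protein(rng, L)
        _plant_motifs(seq, exxr_at, cxg_at)
        _disrupt_spurious_motifs(seq, frozen)
        s = "".join(seq)
        if all(
            pairwise_identity(s, e.sequence, params)[0] < 40.0 - 2.0 for e in entries
        ):
            k = len(entries) + 1
            entries.append(
                PanelEntry(
                    name=f"CYP{9000 + k}A1",
                    family=f"CYP{9000 + k}",
                    subfamily="A",
                    sequence=s,
                )
            )
    return ReferencePanel(entries=entries)


def _mutate_into_band(
    rng: np.random.Generator,
    archetype: str,
    band: tuple[float, float],
    panel: ReferencePanel,
    source_name: str,
    frozen: set[int],
    config: SimulationConfig,
    params: AlignmentParams,
) -> str:
    """Substitution-mutate an archetype until its measured best identity over
    the whole panel lies strictly inside ``band`` and (when the band is above
    the family threshold) the best hit is the source archetype."""
    lo, hi = band
    L = len(archetype)
    mutable = [i for i in range(L) if i not in frozen]
    target = rng.uniform(lo + 1.0, hi - 1.0)
    k = int(round(L * (1.0 - target / 100.0)))
    for _ in range(config.max_calibration_tries):
        k = int(np.clip(k, 1, len(mutable)))
        positions = rng.choice(mutable, size=k, replace=False)
        seq = list(archetype)
        for pos in positions:
            others, w = _REPL[seq[pos]]
            seq[pos] = str(rng.choice(others, p=w))
        _disrupt_spurious_motifs(seq, frozen)
        s = "".join(seq)
        idents = {
            e.name: pairwise_identity(s, e.sequence, params)[0] for e in panel.entries
        }
        best_name = min(idents, key=lambda n: (-idents[n], n))
        best = idents[best_name]
        if lo < best < hi and (best <= 40.0 or best_name == source_name):
            return s
        # adjust substitution count toward the band and retry
        if best >= hi:
            k = max(k + max(1, int(L * (best - hi) / 200.0)), k + 1)
        elif best <= lo:
            k = min(k - max(1, int(L * (lo - best) / 200.0)), k - 1)
    raise RuntimeError(
        f"band calibration failed for band ({lo},{hi}) after "
        f"{config.max_calibration_tries} tries"
    )


def _make_fragment(
    rng: np.random.Generator, full_seq: str, exxr_at: int, cxg_at: int, mode: str
) -> str:
    if mode == "truncation":
        # keep both motifs but fall below the completeness length
        return full_seq[-280:]
    # ablation: break the heme CxG, leaving only ExxR
    seq = list(full_seq)
    seq[cxg_at] = "A"
    _disrupt_spurious_motifs(seq, _frozen_positions(exxr_at, cxg_at) - {cxg_at})
    return "".join(seq)


def simulate_genome(
    config: SimulationConfig, panel: ReferencePanel, genome_index: int
) -> tuple[list[ProteinRecord], pd.DataFrame, dict]:
    """One synthetic genome: planted P450s in identity bands, fragments,
    motif-free decoys, and a gene layout in which planned cluster member
    groups are contiguous gene blocks (so cluster intervals derived later
    contain exactly their planned members).

    Returns (protein records, gene table, ground truth). Deterministic for a
    given (config.seed, genome_index).
    """
    rng = np.random.default_rng([config.seed, 1 + genome_index])
    params = AlignmentParams()
    motif_cfg = MotifConfig(min_length=config.min_length)
    L = config.archetype_length
    exxr_at, cxg_at = _motif_layout(L)
    frozen = _frozen_positions(exxr_at, cxg_at)
    genome_id = f"genome{genome_index:03d}"
    contig_id = f"{genome_id}_c1"

    band_idx = rng.choice(
        len(config.identity_bands), size=config.p450s_per_genome, p=config.band_weights
    )
    proteins: list[tuple[str, str]] = []  # (protein_id, sequence)
    truth_proteins: dict[str, dict] = {}
    p450_ids: list[str] = []
    for i, bi in enumerate(band_idx):
        lo, hi, basis = config.identity_bands[bi]
        src = panel.entries[int(rng.integers(len(panel)))]
        seq = _mutate_into_band(
            rng, src.sequence, (lo, hi), panel, src.name, frozen, config, params
        )
        pid = f"{genome_id}_p{i:03d}"
        proteins.append((pid, seq))
        p450_ids.append(pid)
        truth_proteins[pid] = {
            "status": "P450",
            "source_family": src.family,
            "band": [lo, hi],
            "expected_basis": basis,
        }

    n_fragments = int(rng.binomial(config.p450s_per_genome, config.fragment_rate))
    for i in range(n_fragments):
        src = panel.entries[int(rng.integers(len(panel)))]
        full = _mutate_into_band(
            rng,
            src.sequence,
            config.identity_bands[0][:2],
            panel,
            src.name,
            frozen,
            config,
            params,
        )
        mode = "truncation" if i % 2 == 0 else "ablation"
        seq = _make_fragment(rng, full, exxr_at, cxg_at, mode)
        pid = f"{genome_id}_f{i:03d}"
        proteins.append((pid, seq))
        truth_proteins[pid] = {
            "status": "fragment",
            "source_family": src.family,
            "mode": mode,
        }

    for i in range(config.decoys_per_genome):
        # motif-free by construction: no E or C, so neither pattern can match
        seq = "".join(
            _random_protein(rng, int(rng.integers(250, 380)), alphabet="ADFGHIKLMNPQRSTVWY")
        )
        pid = f"{genome_id}_d{i:03d}"
        proteins.append((pid, seq))
        truth_proteins[pid] = {"status": "non-P450"}

    # self-check: every plant classifies as planned
    for pid, seq in proteins:
        rec = ProteinRecord(pid, genome_id, contig_id, 1, len(seq), "+", seq)
        got = classify_protein(rec, motif_cfg).status
        if got != truth_proteins[pid]["status"]:
            raise RuntimeError(f"plant {pid} classified {got}, planned {truth_proteins[pid]['status']}")

    # plan clusters: contiguous blocks of complete P450s, leaving >= 2 outside
    sizes = []
    budget = max(0, len(p450_ids) - 2)
    for ci in range(config.clusters_per_genome):
        size = 1 + int(
            rng.choice(
                config.max_p450s_per_cluster,
                p=np.array(config.cluster_size_weights[: config.max_p450s_per_cluster])
                / sum(config.cluster_size_weights[: config.max_p450s_per_cluster]),
            )
        )
        sizes.append(size)
    if genome_index == 0 and sizes:
        sizes[0] = config.max_p450s_per_cluster  # guarantee the configured maximum occurs
        if config.max_p450s_per_cluster > budget:
            raise ValueError(
                f"requested {config.max_p450s_per_cluster} cluster members but only "
                f"{budget} P450s available"
            )
    # trim later clusters (dropping empty ones) so plants fit the genome
    while sum(sizes) > budget:
        for ci in range(len(sizes) - 1, -1, -1):
            if sizes[ci] > 0 and not (genome_index == 0 and ci == 0):
                sizes[ci] -= 1
                break
        else:
            raise ValueError(
                f"requested {sum(sizes)} cluster members but only {budget} P450s available"
            )
    sizes = [s for s in sizes if s > 0]
    order = list(rng.permutation(len(p450_ids)))
    blocks: list[list[str]] = []
    cursor = 0
    for size in sizes:
        blocks.append([p450_ids[j] for j in order[cursor : cursor + size]])
        cursor += size
    clustered = {pid for b in blocks for pid in b}

    # gene layout: cluster blocks first (contiguous), then everything else
    tail = [pid for pid, _ in proteins if pid not in clustered]
    tail = [tail[j] for j in rng.permutation(len(tail))]
    layout = [pid for b in blocks for pid in b] + tail
    seq_by_id = dict(proteins)
    records: list[ProteinRecord] = []
    rows = []
    pos = 1
    block_bounds: list[tuple[int, int]] = []
    block_edges = np.cumsum([0] + sizes)
    for idx, pid in enumerate(layout):
        aa = seq_by_id[pid]
        start = pos
        end = start + 3 * len(aa) + 2
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(ProteinRecord(pid, genome_id, contig_id, start, end, strand, aa))
        rows.append(
            {
                "genome_id": genome_id,
                "contig_id": contig_id,
                "gene_id": pid,
                "start": start,
                "end": end,
                "strand": strand,
            }
        )
        pos = end + int(rng.integers(2000, 4000))
    for bi in range(len(sizes)):
        first = records[block_edges[bi]]
        last = records[block_edges[bi + 1] - 1]
        block_bounds.append((first.start, last.end))

    truth = {
        "genome_id": genome_id,
        "proteins": truth_proteins,
        "cluster_plan": [
            {"members": blocks[bi], "bounds": block_bounds[bi]} for bi in range(len(sizes))
        ],
    }
    return records, pd.DataFrame(rows), truth


def simulate_bgc_table(
    config: SimulationConfig, truths: list[dict]
) -> tuple[list[BgcCluster], dict]:
    """Typed cluster intervals for every planned member block (padded by 500
    bp on each side, so planned members are fully contained), with types
    drawn from the observed cluster-type frequencies. Returns the clusters
    and per-cluster ground truth."""
    rng = np.random.default_rng([config.seed, 10_000])
    types = list(BGC_TYPE_COUNTS)
    weights = np.array([BGC_TYPE_COUNTS[t] for t in types], dtype=float)
    weights /= weights.sum()
    clusters: list[BgcCluster] = []
    truth: dict[str, dict] = {}
    for g_truth in truths:
        genome_id = g_truth["genome_id"]
        for ci, plan in enumerate(g_truth["cluster_plan"]):
            lo, hi = plan["bounds"]
            bgc_type = str(rng.choice(types, p=weights))
            cid = f"{genome_id}_bgc{ci:02d}"
            clusters.append(
                BgcCluster(
                    genome_id=genome_id,
                    contig_id=f"{genome_id}_c1",
                    cluster_id=cid,
                    bgc_type=bgc_type,
                    start=max(1, lo - 500),
                    end=hi + 500,
                )
            )
            truth[cid] = {"members": plan["members"], "bgc_type": bgc_type}
    return clusters, truth


def simulate_all(config: SimulationConfig):
    """Panel + genomes + clusters + merged ground truth in one call."""
    panel = simulate_panel(config)
    all_records: list[ProteinRecord] = []
    tables = []
    truths = []
    for gi in range(config.n_genomes):
        records, table, truth = simulate_genome(config, panel, gi)
        all_records.extend(records)
        tables.append(table)
        truths.append(truth)
    clusters, cluster_truth = simulate_bgc_table(config, truths)
    truth = {
        "config_seed": config.seed,
        "proteins": {pid: t for g in truths for pid, t in g["proteins"].items()},
        "clusters": cluster_truth,
    }
    return panel, all_records, pd.concat(tables, ignore_index=True), clusters, truth


def write_simulation(config: SimulationConfig, outdir: str | Path) -> Path:
    """Emit the simulated dataset in pipeline formats: panel.fasta, one
    FASTA + gene-table TSV per genome, clusters.tsv and ground_truth.json."""
    from .nomenclature import write_panel

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel, records, gene_table, clusters, truth = simulate_all(config)
    write_panel(panel, outdir / "panel.fasta")
    for genome_id in sorted({r.genome_id for r in records}):
        write_fasta(
            [r for r in records if r.genome_id == genome_id],
            outdir / f"{genome_id}.fasta",
        )
    write_gene_table(gene_table, outdir / "genes.tsv")
    write_clusters(clusters, outdir / "clusters.tsv")
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return outdir
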