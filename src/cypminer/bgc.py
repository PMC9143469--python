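"""Linking P450 genes to secondary-metabolite biosynthetic gene clusters.

A P450 belongs to an smBGC when its gene interval is fully contained in the
cluster interval on the same genome and contig (an ``any-overlap`` mode is
available behind a flag; cluster callers draw generous boundaries, so genes
genuinely in a cluster lie inside them). Each P450-containing cluster yields
an ordered composition signature -- the family+subfamily labels of its
member P450s in gene order along the contig -- and signatures aggregate by
cluster type into variety tables (distinct signatures with their cluster
counts and P450 totals).
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .identification import P450Call, STATUS_FRAGMENT, STATUS_P450
from .sequence_io import ProteinRecord

LABEL_FAMILY_RE = re.compile(r"^CYP\s*(\d+)")
NEW_FAMILY_LABEL_RE = re.compile(r"^(CYPNEW-\d+)")

CLUSTER_COLUMNS = ["genome_id", "contig_id", "cluster_id", "bgc_type", "start", "end"]


@dataclass
class BgcCluster:
    """A typed genomic interval (1-based inclusive) called as an smBGC."""

    genome_id: str
    contig_id: str
    cluster_id: str
    bgc_type: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"cluster {self.cluster_id}: start > end")


@dataclass
class ClusterSignature:
    cluster_id: str
    bgc_type: str
    member_p450s: list[str]  # family+subfamily labels in gene order
    member_ids: list[str] = field(default_factory=list)

    @property
    def n_p450(self) -> int:
        return len(self.member_p450s)

    @property
    def signature(self) -> str:
        return ",".join(self.member_p450s)


@dataclass
class TypeAggregate:
    bgc_type: str
    n_clusters: int  # P450-containing clusters of this type
    varieties: dict[str, int]  # signature string -> cluster count
    n_p450_total: int


def read_clusters(path: str | Path) -> list[BgcCluster]:
    df = pd.read_csv(
        path, sep="\t", dtype={"genome_id": str, "contig_id": str, "cluster_id": str, "bgc_type": str}
    )
    missing = [c for c in CLUSTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cluster table missing columns {missing}")
    dup = df.duplicated(subset=["genome_id", "cluster_id"])
    if dup.any():
        bad = df.loc[dup, ["genome_id", "cluster_id"]].iloc[0]
        raise ValueError(f"{path}: duplicate cluster {tuple(bad)}")
    return [
        BgcCluster(
            genome_id=r.genome_id,
            contig_id=r.contig_id,
            cluster_id=r.cluster_id,
            bgc_type=r.bgc_type,
            start=int(r.start),
            end=int(r.end),
        )
        for r in df.itertuples()
    ]


def write_clusters(clusters: list[BgcCluster], path: str | Path) -> None:
    pd.DataFrame([vars(c) for c in clusters]).to_csv(
        path, sep="\t", index=False, columns=CLUSTER_COLUMNS
    )


def _call_label(call: P450Call) -> str:
    label = (call.family or "") + (call.subfamily or "")
    return label or call.protein_id


def assign_p450s_to_clusters(
    records: list[ProteinRecord],
    calls: list[P450Call],
    clusters: list[BgcCluster],
    mode: str = "containment",
    include_fragments: bool = False,
) -> tuple[list[ClusterSignature], list[str]]:
    """Place P450 genes into clusters and build composition signatures.

    Membership is strand-agnostic full containment of the gene interval in
    the cluster interval (``mode="overlap"`` relaxes to any overlap).
    Members are ordered by gene start coordinate. Returns the signatures
    (one per input cluster, including empty ones) and a residual list of
    P450 ids falling in no cluster. A gene contained in several overlapping
    clusters is assigned to each, with a warning.

    Fragments never enter signatures unless ``include_fragments`` is set.
    """
    if mode not in ("containment", "overlap"):
        raise ValueError(f"unknown membership mode {mode!r}")
    keep = {STATUS_P450} | ({STATUS_FRAGMENT} if include_fragments else set())
    call_by_id = {c.protein_id: c for c in calls}
    genes = [
        r
        for r in records
        if r.id in call_by_id and call_by_id[r.id].status in keep
    ]
    members: dict[str, list[ProteinRecord]] = {c.cluster_id: [] for c in clusters}
    multiplicity: Counter = Counter()
    placed: set[str] = set()
    for gene in genes:
        hits = []
        for cl in clusters:
            if cl.genome_id != gene.genome_id or cl.contig_id != gene.contig_id:
                continue
            if mode == "containment":
                inside = cl.start <= gene.start and gene.end <= cl.end
            else:
                inside = gene.start <= cl.end and cl.start <= gene.end
            if inside:
                hits.append(cl)
        for cl in hits:
            members[cl.cluster_id].append(gene)
        if hits:
            placed.add(gene.id)
        if len(hits) > 1:
            multiplicity[gene.id] = len(hits)
    if multiplicity:
        warnings.warn(
            f"{len(multiplicity)} gene(s) contained in multiple overlapping clusters "
            f"(e.g. {next(iter(multiplicity))!r}); assigned to each",
            stacklevel=2,
        )
    signatures = []
    for cl in clusters:
        ordered = sorted(members[cl.cluster_id], key=lambda g: (g.start, g.id))
        signatures.append(
            ClusterSignature(
                cluster_id=cl.cluster_id,
                bgc_type=cl.bgc_type,
                member_p450s=[_call_label(call_by_id[g.id]) for g in ordered],
                member_ids=[g.id for g in ordered],
            )
        )
    residual = [g.id for g in genes if g.id not in placed]
    return signatures, residual


def aggregate_by_type(signatures: list[ClusterSignature]) -> list[TypeAggregate]:
    """Group P450-containing signatures by cluster type into variety maps.

    Variety keys are the comma-joined ordered label strings; clusters with no
    P450s are excluded from aggregation.
    """
    by_type: dict[str, list[ClusterSignature]] = {}
    for sig in signatures:
        if sig.n_p450 > 0:
            by_type.setdefault(sig.bgc_type, []).append(sig)
    out = []
    for bgc_type in sorted(by_type):
        sigs = by_type[bgc_type]
        varieties: dict[str, int] = {}
        for s in sigs:
            varieties[s.signature] = varieties.get(s.signature, 0) + 1
        out.append(
            TypeAggregate(
                bgc_type=bgc_type,
                n_clusters=len(sigs),
                varieties=varieties,
                n_p450_total=sum(s.n_p450 for s in sigs),
            )
        )
    return out


def aggregates_from_fixture(table4: pd.DataFrame) -> list[TypeAggregate]:
    """Build type aggregates from a packaged variety table (one row per
    type/variety with its cluster count and P450 total)."""
    out = []
    for bgc_type, grp in table4.groupby("bgc_type", sort=True):
        # the same signature can appear on several printed rows of one type
        varieties: dict[str, int] = {}
        for sig, n in zip(grp["p450_list"], grp["variety_count"].astype(int)):
            varieties[sig] = varieties.get(sig, 0) + n
        out.append(
            TypeAggregate(
                bgc_type=str(bgc_type),
                n_clusters=int(grp["variety_count"].sum()),
                varieties=varieties,
                n_p450_total=int(grp["p450_count"].sum()),
            )
        )
    return out


def max_p450s_per_cluster(signatures: list[ClusterSignature]) -> int:
    """Largest number of P450s found in a single cluster."""
    if not signatures:
        raise ValueError("no cluster signatures")
    return max(s.n_p450 for s in signatures)


def max_p450s_from_aggregates(aggregates: list[TypeAggregate]) -> int:
    """Variety-table form of :func:`max_p450s_per_cluster`: longest member
    list over all variety signature strings."""
    best = 0
    for agg in aggregates:
        for sig in agg.varieties:
            best = max(best, len([x for x in sig.split(",") if x.strip()]))
    if best == 0:
        raise ValueError("no P450-containing varieties")
    return best


def label_family(label: str) -> str:
    """Family from a member label by the leading CYP+digits grammar
    (tolerates allele suffixes, '/' variants, '-fragment' markers and the
    pipeline's own CYPNEW-<k> placeholders)."""
    label = label.strip()
    m = LABEL_FAMILY_RE.match(label)
    if m:
        return f"CYP{m.group(1)}"
    m = NEW_FAMILY_LABEL_RE.match(label)
    if m:
        return m.group(1)
    raise ValueError(f"label {label!r} does not match the CYP family grammar")


def bgc_family_breakdown(
    signatures: list[ClusterSignature],
) -> dict[str, tuple[int, float]]:
    """Per-family count and percentage of all cluster-member P450s."""
    counts: Counter = Counter()
    for sig in signatures:
        for label in sig.member_p450s:
            counts[label_family(label)] += 1
    total = sum(counts.values())
    return {fam: (n, 100.0 * n / total) for fam, n in sorted(counts.items())}


def breakdown_from_aggregates(
    aggregates: list[TypeAggregate],
) -> dict[str, tuple[int, float]]:
    """Family breakdown from variety tables, weighting each variety's member
    labels by its cluster count."""
    counts: Counter = Counter()
    for agg in aggregates:
        for sig, n_clusters in agg.varieties.items():
            for label in sig.split(","):
                label = label.strip()
                if label:
                    counts[label_family(label)] += n_clusters
    total = sum(counts.values())
    return {fam: (n, 100.0 * n / total) for fam, n in sorted(counts.items())}


def write_signatures(signatures: list[ClusterSignature], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "cluster_id": s.cluster_id,
                "bgc_type": s.bgc_type,
                "n_p450": s.n_p450,
                "signature": s.signature,
                "member_ids": ",".join(s.member_ids),
            }
            for s in signatures
        ]
    ).to_csv(path, sep="\t", index=False)


def write_aggregates(aggregates: list[TypeAggregate], path: str | Path) -> None:
    rows = []
    for agg in aggregates:
        for sig, n in sorted(agg.varieties.items()):
            rows.append(
                {
                    "bgc_type": agg.bgc_type,
                    "bgc_type_count": agg.n_clusters,
                    "variety_count": n,
                    "p450_list": sig,
                    "p450_count": n * len([x for x in sig.split(",") if x.strip()]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
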