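"""Readers/writers for protein FASTA, gene tables, packaged fixtures and newick trees.

All coordinates are 1-based inclusive (GFF convention). FASTA headers carry
optional ``key=value`` metadata tokens (``genome=`` ``contig=`` ``start=``
``end=`` ``strand=``); unknown tokens are ignored and absent fields are
defaulted so that heterogeneous exports can be ingested tolerantly.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
FAMILY_RE = re.compile(r"^CYP[0-9]+[A-Z0-9]*$")

GENE_TABLE_COLUMNS = ["genome_id", "contig_id", "gene_id", "start", "end", "strand"]


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the offending line."""


class FixtureIntegrityError(ValueError):
    """Packaged fixture tables fail their manifest row-count/checksum checks."""


@dataclass
class ProteinRecord:
    """One protein sequence with its genomic context.

    ``start``/``end`` are 1-based inclusive coordinates of the encoding gene
    on ``contig_id``; ``sequence`` is an uppercase amino-acid string over the
    20 canonical residues plus ``X``.
    """

    id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.id}: start {self.start} > end {self.end}")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class FixtureTables:
    """Packaged transcriptions of the published per-strain, per-family and
    per-cluster-type summary tables, loaded as DataFrames."""

    table2: pd.DataFrame  # species, n_p450, n_fragments, n_families, n_subfamilies
    table3: pd.DataFrame  # family, family_count, family_pct, subfamily, subfamily_count, subfamily_pct
    table4: pd.DataFrame  # bgc_type, bgc_type_count, variety_count, p450_list, p450_count


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_META_KEYS = {"genome", "contig", "start", "end", "strand"}


def _parse_header(header: str, default_genome: str) -> dict:
    tokens = header.split()
    meta = {"id": tokens[0]}
    for tok in tokens[1:]:
        if "=" in tok:
            key, _, value = tok.partition("=")
            if key in _META_KEYS:
                meta[key] = value
    return meta


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein FASTA into :class:`ProteinRecord` objects.

    Header metadata is parsed from ``key=value`` tokens; missing fields
    default to genome id = file stem, contig id = genome id, coordinates
    ``1..len(sequence)`` (amino-acid units) and strand ``+``. Lowercase
    residues are uppercased. An empty file yields an empty list.
    """
    path = Path(path)
    default_genome = path.stem
    records: list[ProteinRecord] = []
    # validate basic shape before handing to SeqIO: text before first '>'
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header before sequence data"
                )
            break
    seen: set[tuple[str, str]] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = _parse_header(rec.description, default_genome)
        seq = str(rec.seq).upper()
        genome = meta.get("genome", default_genome)
        start = int(meta.get("start", 1))
        end = int(meta.get("end", start + len(seq) - 1 if "start" in meta else len(seq)))
        record = ProteinRecord(
            id=meta["id"],
            genome_id=genome,
            contig_id=meta.get("contig", genome),
            start=start,
            end=end,
            strand=meta.get("strand", "+"),
            sequence=seq,
        )
        key = (record.genome_id, record.id)
        if key in seen:
            raise FastaParseError(f"{path}: duplicate record id {record.id!r} in genome {genome!r}")
        seen.add(key)
        records.append(record)
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    """Write records with full ``key=value`` metadata headers (round-trips
    through :func:`read_fasta`)."""
    seq_records = []
    for r in records:
        desc = (
            f"genome={r.genome_id} contig={r.contig_id} "
            f"start={r.start} end={r.end} strand={r.strand}"
        )
        seq_records.append(SeqRecord(Seq(r.sequence), id=r.id, description=desc))
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Gene / cluster tables
# ---------------------------------------------------------------------------


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited gene coordinate table.

    Columns: genome_id, contig_id, gene_id, start, end, strand. Raises on
    duplicate (genome_id, gene_id) pairs.
    """
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "contig_id": str, "gene_id": str})
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: gene table missing columns {missing}")
    dup = df.duplicated(subset=["genome_id", "gene_id"])
    if dup.any():
        bad = df.loc[dup, ["genome_id", "gene_id"]].iloc[0]
        raise ValueError(f"{path}: duplicate gene entry {tuple(bad)}")
    return df


def write_gene_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=GENE_TABLE_COLUMNS)


def apply_gene_table(records: list[ProteinRecord], table: pd.DataFrame) -> list[ProteinRecord]:
    """Overwrite record coordinates with those from a gene table, matching on
    (genome_id, gene_id)."""
    idx = {(row.genome_id, row.gene_id): row for row in table.itertuples()}
    out = []
    for r in records:
        row = idx.get((r.genome_id, r.id))
        if row is None:
            out.append(r)
        else:
            out.append(
                ProteinRecord(
                    id=r.id,
                    genome_id=r.genome_id,
                    contig_id=str(row.contig_id),
                    start=int(row.start),
                    end=int(row.end),
                    strand=str(row.strand),
                    sequence=r.sequence,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------


def _fixture_dir() -> Path:
    return Path(resources.files("cypminer").joinpath("data/fixtures"))


def load_fixtures(directory: str | Path | None = None) -> FixtureTables:
    """Load the packaged summary-table transcriptions, verifying them against
    the manifest (row counts, column sums, SHA-256 checksums).

    ``directory`` defaults to the fixtures shipped with the package.
    """
    directory = Path(directory) if directory is not None else _fixture_dir()
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FixtureIntegrityError(f"no fixture manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())

    frames: dict[str, pd.DataFrame] = {}
    for name, checks in manifest.items():
        fpath = directory / name
        if not fpath.exists():
            raise FixtureIntegrityError(f"fixture file missing: {fpath}")
        digest = hashlib.sha256(fpath.read_bytes()).hexdigest()
        if digest != checks["sha256"]:
            raise FixtureIntegrityError(f"{name}: checksum mismatch")
        df = pd.read_csv(fpath, sep="\t")
        if len(df) != checks["rows"]:
            raise FixtureIntegrityError(f"{name}: expected {checks['rows']} rows, got {len(df)}")
        frames[name] = df

    t2, t3, t4 = frames["table2.tsv"], frames["table3.tsv"], frames["table4.tsv"]
    m2, m3, m4 = manifest["table2.tsv"], manifest["table3.tsv"], manifest["table4.tsv"]
    if int(t2["n_p450"].sum()) != m2["sum_n_p450"]:
        raise FixtureIntegrityError("table2: P450 column sum mismatch")
    if int(t2["n_fragments"].sum()) != m2["sum_n_fragments"]:
        raise FixtureIntegrityError("table2: fragment column sum mismatch")
    fam_counts = t3.drop_duplicates("family").set_index("family")["family_count"]
    if len(fam_counts) != m3["n_families"]:
        raise FixtureIntegrityError("table3: family count mismatch")
    if int(fam_counts.sum()) != m3["sum_family_counts"]:
        raise FixtureIntegrityError("table3: family count sum mismatch")
    if int(t3["subfamily_count"].sum()) != m3["sum_subfamily_counts"]:
        raise FixtureIntegrityError("table3: subfamily count sum mismatch")
    bad = [f for f in fam_counts.index if not FAMILY_RE.match(f)]
    if bad:
        raise FixtureIntegrityError(f"table3: malformed family names {bad}")
    if int(t4["p450_count"].sum()) != m4["sum_p450_counts"]:
        raise FixtureIntegrityError("table4: P450 count sum mismatch")
    if t4["bgc_type"].nunique() != m4["n_types"]:
        raise FixtureIntegrityError("table4: cluster type count mismatch")
    return FixtureTables(table2=t2, table3=t3, table4=t4)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def _newick_clause(node) -> str:
    # node is an skbio TreeNode
    if node.is_tip():
        label = node.name or ""
        if re.search(r"[\s(),:;]", label):
            label = "'" + label.replace("'", "''") + "'"
        body = label
    else:
        body = "(" + ",".join(_newick_clause(c) for c in node.children) + ")"
        if node.name:
            body += node.name
    if node.length is not None:
        body += f":{node.length:.6f}"
    return body


def write_newick(tree, path: str | Path) -> None:
    """Serialize an skbio ``TreeNode`` to newick with branch lengths printed
    to 6 decimal places. Duplicate leaf labels are rejected."""
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError("duplicate leaf labels in tree")
    Path(path).write_text(_newick_clause(tree) + ";\n")


def read_newick(path: str | Path):
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")
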