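"""Family/subfamily assignment by percent identity to a named reference panel.

The International P450 Nomenclature Committee convention assigns a P450 to
the same family as a named homolog when their percent identity exceeds 40%,
and to the same subfamily when it exceeds 55%; below 40% the protein founds a
new family. Identity here is computed from a global (Needleman-Wunsch style)
alignment of the full-length proteins under BLOSUM62 with gap open 10 and gap
extend 0.5, counting identical aligned residue pairs over all aligned
(non-gap) columns. Thresholds are applied as strict inequalities, so exactly
40.0% falls to new-family and exactly 55.0% to family-match.

Queries that found new families are grouped among themselves by
single-linkage at the 40% threshold, so mutually similar novel queries share
one ``CYPNEW-<k>`` placeholder; analogously, family-matched queries needing a
new subfamily share ``!<ordinal>`` placeholders grouped at 55%.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .identification import P450Call, STATUS_P450
from .sequence_io import ProteinRecord

NAME_RE = re.compile(r"^(CYP\d+)([A-Z]+)?(\d+)?$")

FAMILY_THRESHOLD = 40.0
SUBFAMILY_THRESHOLD = 55.0

BASIS_SUBFAMILY = "subfamily-match"
BASIS_FAMILY = "family-match"
BASIS_NEW = "new-family"


@dataclass
class AlignmentParams:
    """Scoring for global protein alignment (all configurable)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    family_threshold: float = FAMILY_THRESHOLD
    subfamily_threshold: float = SUBFAMILY_THRESHOLD

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        aligner.open_gap_score = -abs(self.gap_open)
        aligner.extend_gap_score = -abs(self.gap_extend)
        return aligner


@dataclass
class PanelEntry:
    name: str  # e.g. CYP105AB1
    family: str  # CYP105
    subfamily: str  # AB
    sequence: str


@dataclass
class ReferencePanel:
    """Named P450 sequences keyed by family/subfamily."""

    entries: list[PanelEntry]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("duplicate names in reference panel")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class IdentityResult:
    query_id: str
    best_hit: str
    identity_pct: float
    n_aligned_pairs: int


@dataclass
class FamilyAssignment:
    query_id: str
    family: str
    subfamily: str
    basis: str  # subfamily-match | family-match | new-family
    best_identity_pct: float
    best_hit: str | None = None
    genome_id: str | None = None


def parse_panel_name(name: str) -> tuple[str, str]:
    """Split a nomenclature-style name into (family, subfamily letters),
    e.g. CYP105AB1 -> (CYP105, AB)."""
    m = NAME_RE.match(name)
    if not m:
        raise ValueError(f"name {name!r} does not follow CYP<digits><letters><allele> grammar")
    return m.group(1), m.group(2) or ""


def read_panel(path: str | Path) -> ReferencePanel:
    """Load a reference panel FASTA. Headers may carry explicit
    ``family=``/``subfamily=`` tokens; otherwise both are derived from the
    nomenclature grammar of the record id."""
    from Bio import SeqIO

    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = dict(
            tok.partition("=")[::2] for tok in rec.description.split()[1:] if "=" in tok
        )
        fam_default, sub_default = parse_panel_name(rec.id)
        entries.append(
            PanelEntry(
                name=rec.id,
                family=tokens.get("family", fam_default),
                subfamily=tokens.get("subfamily", sub_default),
                sequence=str(rec.seq).upper(),
            )
        )
    return ReferencePanel(entries=entries)


def write_panel(panel: ReferencePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in panel.entries:
            fh.write(f">{e.name} family={e.family} subfamily={e.subfamily}\n{e.sequence}\n")


# ---------------------------------------------------------------------------
# Pairwise identity
# ---------------------------------------------------------------------------


def align_pair(seq_a: str, seq_b: str, params: AlignmentParams | None = None):
    """Return the (deterministic, first-optimal) global alignment of two
    sequences under the configured scoring."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    params = params or AlignmentParams()
    return params.aligner().align(seq_a, seq_b)[0]


def pairwise_identity(
    seq_a: str, seq_b: str, params: AlignmentParams | None = None
) -> tuple[float, int]:
    """Percent identity over aligned residue pairs of the global alignment.

    Gap columns are excluded from the denominator. Returns
    ``(identity_pct, n_aligned_pairs)``. The pair is aligned in a canonical
    (lexicographic) order internally so the result is exactly symmetric even
    when co-optimal alignments differ between argument orders.
    """
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    alignment = align_pair(seq_a, seq_b, params)
    counts = alignment.counts()
    n_aligned = counts.identities + counts.mismatches
    if n_aligned == 0:
        return 0.0, 0
    return 100.0 * counts.identities / n_aligned, n_aligned


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------


def best_panel_hit(
    sequence: str, panel: ReferencePanel, params: AlignmentParams | None = None
) -> tuple[PanelEntry, float, int]:
    """Best identity over the panel; ties at the maximum resolve to the
    lexicographically smallest reference name (logged)."""
    if len(panel) == 0:
        raise ValueError("empty reference panel")
    params = params or AlignmentParams()
    results = []
    for entry in panel.entries:
        pct, n_pairs = pairwise_identity(sequence, entry.sequence, params)
        results.append((entry, pct, n_pairs))
    best_pct = max(r[1] for r in results)
    tied = sorted((r for r in results if r[1] == best_pct), key=lambda r: r[0].name)
    if len(tied) > 1:
        warnings.warn(
            f"tie at best identity {best_pct:.2f}% between "
            f"{[r[0].name for r in tied]}; keeping {tied[0][0].name}",
            stacklevel=2,
        )
    return tied[0]


def _basis_for(pct: float, params: AlignmentParams) -> str:
    if pct > params.subfamily_threshold:
        return BASIS_SUBFAMILY
    if pct > params.family_threshold:
        return BASIS_FAMILY
    return BASIS_NEW


def _single_linkage_groups(
    seqs: list[str], threshold: float, params: AlignmentParams
) -> list[int]:
    """Union-find single-linkage clustering: edge when identity > threshold.
    Returns a group index per input, numbered by first occurrence."""
    n = len(seqs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            pct, _ = pairwise_identity(seqs[i], seqs[j], params)
            if pct > threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    labels: dict[int, int] = {}
    out = []
    for i in range(n):
        root = find(i)
        if root not in labels:
            labels[root] = len(labels) + 1
        out.append(labels[root])
    return out


def assign_family(
    call: P450Call,
    sequence: str,
    panel: ReferencePanel,
    params: AlignmentParams | None = None,
) -> FamilyAssignment:
    """Assign one P450 call against the panel (see module docstring for the
    threshold semantics). Singleton form: new families are labelled
    ``CYPNEW-1`` and new subfamilies ``!1``; use :func:`assign_all` for
    consistent placeholder numbering across a batch."""
    if call.status != STATUS_P450:
        raise ValueError(f"{call.protein_id}: only status=P450 calls are assigned")
    params = params or AlignmentParams()
    entry, pct, _ = best_panel_hit(sequence, panel, params)
    basis = _basis_for(pct, params)
    if basis == BASIS_SUBFAMILY:
        family, subfamily = entry.family, entry.subfamily
    elif basis == BASIS_FAMILY:
        family, subfamily = entry.family, "!1"
    else:
        family, subfamily = "CYPNEW-1", ""
    return FamilyAssignment(
        query_id=call.protein_id,
        family=family,
        subfamily=subfamily,
        basis=basis,
        best_identity_pct=pct,
        best_hit=entry.name,
        genome_id=call.genome_id,
    )


def assign_all(
    calls: list[P450Call],
    sequences: dict[str, str],
    panel: ReferencePanel,
    params: AlignmentParams | None = None,
) -> list[FamilyAssignment]:
    """Batch assignment with deterministic placeholder naming.

    ``sequences`` maps protein id -> amino-acid sequence. New-family queries
    are single-linkage grouped at the family threshold so cohesive novel
    queries share one ``CYPNEW-<k>`` label (numbered by first occurrence in
    input order); family-matched queries within one family share ``!<k>``
    subfamily placeholders grouped at the subfamily threshold.
    """
    params = params or AlignmentParams()
    assignments: list[FamilyAssignment] = []
    for call in calls:
        if call.protein_id not in sequences:
            raise KeyError(f"no sequence for call {call.protein_id}")
        entry, pct, _ = best_panel_hit(sequences[call.protein_id], panel, params)
        basis = _basis_for(pct, params)
        assignments.append(
            FamilyAssignment(
                query_id=call.protein_id,
                family=entry.family if basis != BASIS_NEW else "",
                subfamily=entry.subfamily if basis == BASIS_SUBFAMILY else "",
                basis=basis,
                best_identity_pct=pct,
                best_hit=entry.name,
                genome_id=call.genome_id,
            )
        )

    # group new-family queries into shared CYPNEW labels
    new_idx = [i for i, a in enumerate(assignments) if a.basis == BASIS_NEW]
    if new_idx:
        groups = _single_linkage_groups(
            [sequences[assignments[i].query_id] for i in new_idx],
            params.family_threshold,
            params,
        )
        for i, g in zip(new_idx, groups):
            assignments[i].family = f"CYPNEW-{g}"
            assignments[i].subfamily = ""

    # group family-match queries per family into shared new-subfamily labels
    by_family: dict[str, list[int]] = {}
    for i, a in enumerate(assignments):
        if a.basis == BASIS_FAMILY:
            by_family.setdefault(a.family, []).append(i)
    for family, idxs in by_family.items():
        groups = _single_linkage_groups(
            [sequences[assignments[i].query_id] for i in idxs],
            params.subfamily_threshold,
            params,
        )
        for i, g in zip(idxs, groups):
            assignments[i].subfamily = f"!{g}"

    return assignments


def annotate_calls(calls: list[P450Call], assignments: list[FamilyAssignment]) -> None:
    """Copy assigned family/subfamily back onto the calls (in place)."""
    by_id = {a.query_id: a for a in assignments}
    for call in calls:
        a = by_id.get(call.protein_id)
        if a is not None:
            call.family, call.subfamily = a.family, a.subfamily


def write_assignments(assignments: list[FamilyAssignment], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "query_id": a.query_id,
                "genome_id": a.genome_id,
                "family": a.family,
                "subfamily": a.subfamily,
                "basis": a.basis,
                "best_hit": a.best_hit,
                "identity_pct": round(a.best_identity_pct, 4),
            }
            for a in assignments
        ]
    ).to_csv(path, sep="\t", index=False)
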