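"""Cytochrome P450 identification by diagnostic motifs and length.

A complete bacterial P450 carries two near-universal sequence signatures: the
K-helix salt-bridge tetrapeptide ``ExxR`` and the heme-binding loop ``CxG``
whose cysteine is the axial thiolate ligand of the heme iron. Both sit in the
C-terminal portion of the fold, with ExxR upstream of CxG. A protein with
both motifs in that configuration and a plausible full-domain length is
called a P450; a protein with only one motif, or with both but too short, is
called a P450 fragment; a protein with neither motif is not a P450.

The motifs live in a 4-letter pattern space, so spurious matches are common
in unrelated proteins. By default, matches only count toward classification
when they fall in windows reflecting the motifs' known placement (ExxR in the
C-terminal 60% of the sequence, CxG within the final 120 residues, ExxR
strictly before CxG); the reported evidence still records whole-sequence
presence so borderline cases can be inspected.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

from .sequence_io import AA_ALPHABET, ProteinRecord

EXXR_RE = re.compile(r"(?=E[A-Z]{2}R)")
CXG_RE = re.compile(r"(?=C[A-Z]G)")

STATUS_P450 = "P450"
STATUS_FRAGMENT = "fragment"
STATUS_NON_P450 = "non-P450"


@dataclass
class MotifConfig:
    """Tunables for motif matching and the completeness rule.

    min_length: minimum amino-acid length for a complete P450 (default 300,
        below the ~350-400 aa of the shortest complete bacterial P450s, so
        clear truncations are excluded without rejecting compact P450s).
    use_windows: restrict classification-relevant matches to the positional
        windows described in the module docstring.
    exxr_cterm_frac: ExxR must start within this C-terminal fraction.
    cxg_tail: CxG must start within this many residues of the C-terminus.
    """

    min_length: int = 300
    use_windows: bool = True
    exxr_cterm_frac: float = 0.6
    cxg_tail: int = 120


@dataclass
class MotifEvidence:
    """Motif search outcome for one sequence.

    ``has_exxr``/``has_cxg`` report whole-sequence presence. The positions
    (0-based index of the E and the C) prefer the window-compliant ordered
    pair when one exists, otherwise the last match. ``exxr_in_window``,
    ``cxg_in_window`` and ``ordered_in_window`` carry the window-restricted
    view used for classification.
    """

    has_exxr: bool
    exxr_position: int | None
    has_cxg: bool
    cxg_position: int | None
    length_aa: int
    exxr_in_window: bool = False
    cxg_in_window: bool = False
    ordered_in_window: bool = False


@dataclass
class P450Call:
    """Classification outcome for one protein."""

    protein_id: str
    genome_id: str
    status: str  # P450 | fragment | non-P450
    evidence: MotifEvidence
    family: str | None = None
    subfamily: str | None = None


def find_motifs(sequence: str, config: MotifConfig | None = None) -> MotifEvidence:
    """Locate the ExxR and CxG motifs in an uppercase amino-acid sequence.

    ``X`` may occupy wildcard positions but never matches the fixed letters
    E, R, C, G of the patterns. Raises ``ValueError`` on characters outside
    the 21-letter alphabet.
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - AA_ALPHABET
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")
    config = config or MotifConfig()
    n = len(sequence)

    exxr_all = [m.start() for m in EXXR_RE.finditer(sequence)]
    cxg_all = [m.start() for m in CXG_RE.finditer(sequence)]

    if config.use_windows:
        exxr_lo = math.floor(n * (1.0 - config.exxr_cterm_frac))
        cxg_lo = max(0, n - config.cxg_tail)
    else:
        exxr_lo = cxg_lo = 0
    exxr_win = [p for p in exxr_all if p >= exxr_lo]
    cxg_win = [p for p in cxg_all if p >= cxg_lo]

    # chosen pair: last in-window CxG, then the latest in-window ExxR before it
    exxr_pos = cxg_pos = None
    ordered = False
    if cxg_win:
        cxg_pos = cxg_win[-1]
        before = [p for p in exxr_win if p < cxg_pos]
        if before:
            exxr_pos = before[-1]
            ordered = True
    if exxr_pos is None and exxr_all:
        exxr_pos = exxr_win[-1] if exxr_win else exxr_all[-1]
    if cxg_pos is None and cxg_all:
        cxg_pos = cxg_all[-1]

    return MotifEvidence(
        has_exxr=bool(exxr_all),
        exxr_position=exxr_pos,
        has_cxg=bool(cxg_all),
        cxg_position=cxg_pos,
        length_aa=n,
        exxr_in_window=bool(exxr_win),
        cxg_in_window=bool(cxg_win),
        ordered_in_window=ordered,
    )


def classify_protein(record: ProteinRecord, config: MotifConfig | None = None) -> P450Call:
    """Classify one protein as P450, fragment or non-P450.

    status=P450 requires both motifs (window-compliant and ordered when
    windows are enabled) and length >= ``min_length``; exactly one motif, or
    both motifs on a short sequence, gives fragment; neither motif gives
    non-P450. Both motifs present on a full-length sequence but in a
    window/order-noncompliant configuration is called fragment (one match is
    treated as spurious).
    """
    config = config or MotifConfig()
    ev = find_motifs(record.sequence, config)
    if config.use_windows:
        e_ok, c_ok = ev.exxr_in_window, ev.cxg_in_window
        complete_cfg = ev.ordered_in_window
    else:
        e_ok, c_ok = ev.has_exxr, ev.has_cxg
        complete_cfg = (
            e_ok and c_ok and ev.exxr_position is not None
            and ev.cxg_position is not None and ev.exxr_position < ev.cxg_position
        )
    if e_ok and c_ok and complete_cfg and ev.length_aa >= config.min_length:
        status = STATUS_P450
    elif e_ok or c_ok:
        status = STATUS_FRAGMENT
    else:
        status = STATUS_NON_P450
    return P450Call(
        protein_id=record.id, genome_id=record.genome_id, status=status, evidence=ev
    )


def classify_all(
    records: list[ProteinRecord], config: MotifConfig | None = None
) -> list[P450Call]:
    config = config or MotifConfig()
    return [classify_protein(r, config) for r in records]


def apply_domain_prefilter(
    records: list[ProteinRecord], hits: dict[str, bool] | None = None
) -> list[ProteinRecord]:
    """Restrict to proteins flagged P450-domain-positive in a precomputed
    domain-hit table (e.g. an InterPro P450-domain scan supplied as
    ``protein_id -> bool``). With no table, all records pass and the motif
    rule alone governs. Hit-table ids not present among the records trigger a
    warning and are ignored.
    """
    if hits is None:
        return list(records)
    known = {r.id for r in records}
    unknown = [pid for pid in hits if pid not in known]
    if unknown:
        warnings.warn(
            f"domain-hit table references {len(unknown)} unknown protein id(s), "
            f"e.g. {unknown[0]!r}; ignored",
            stacklevel=2,
        )
    return [r for r in records if hits.get(r.id, False)]


def read_domain_hits(path) -> dict[str, bool]:
    """Read an optional precomputed domain-hit TSV with columns
    ``protein_id`` and ``has_ipr001128`` (0/1)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    return {row.protein_id: bool(int(row.has_ipr001128)) for row in df.itertuples()}
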