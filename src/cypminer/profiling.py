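"""Genome x family CYPome profiles, summary statistics, blooming/conservation
detection and presence/absence heat-map clustering.

Summary statistics follow three closed-form definitions over the profile:

    average P450s per species  = n_P450 / n_species
    P450 diversity percentage  = 100 * n_families / (n_P450 * n_species_with_P450)
    percent of P450s in smBGCs = 100 * n_in_BGC / n_P450

Reported values round only at report time (average and BGC percentage to the
nearest integer, diversity to 2 decimals); the raw reals are always kept.

The heat-map encodes family presence as 3 and absence as -3 (the convention
of the MeV-style presence/absence displays this module reproduces), then
clusters rows (genomes) and columns (families) hierarchically with Euclidean
distance and average linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .identification import P450Call, STATUS_FRAGMENT, STATUS_P450
from .nomenclature import FamilyAssignment


@dataclass
class CypomeProfile:
    """Counts of P450s per genome (rows) and family (columns), plus a
    fragment count per genome."""

    counts: pd.DataFrame  # index: genome ids; columns: family names
    fragments_per_genome: pd.Series

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def families(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_p450(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass
class SummaryStats:
    n_species: int
    n_species_with_p450: int
    n_p450: int
    n_families: int
    n_subfamilies: int
    avg_p450: float
    diversity_pct: float
    n_in_bgc: int
    pct_in_bgc: float

    def report(self) -> dict:
        """Rounded, report-time view (raw values remain on the instance)."""
        return {
            "n_species": self.n_species,
            "n_species_with_p450": self.n_species_with_p450,
            "n_p450": self.n_p450,
            "n_families": self.n_families,
            "n_subfamilies": self.n_subfamilies,
            "avg_p450": round(self.avg_p450),
            "diversity_pct": round(self.diversity_pct, 2),
            "n_in_bgc": self.n_in_bgc,
            "pct_in_bgc": round(self.pct_in_bgc),
        }


@dataclass
class HeatmapMatrix:
    values: pd.DataFrame  # entries in {-3, 3}
    row_order: list[int]
    col_order: list[int]
    linkage_rows: np.ndarray | None
    linkage_cols: np.ndarray | None


def build_profile(
    assignments: list[FamilyAssignment], calls: list[P450Call]
) -> CypomeProfile:
    """Tabulate family counts per genome from assignments, and fragment
    counts per genome from the calls.

    Every genome seen in the calls keeps a row even if it has no complete
    P450s; family columns are the assigned families (sorted), so no column is
    all-zero. Raises on an assignment whose query id has no P450 call.
    """
    call_by_id = {c.protein_id: c for c in calls}
    genomes = sorted({c.genome_id for c in calls})
    rows: dict[tuple[str, str], int] = {}
    for a in assignments:
        call = call_by_id.get(a.query_id)
        if call is None or call.status != STATUS_P450:
            raise ValueError(f"assignment {a.query_id!r} has no matching P450 call")
        genome = a.genome_id or call.genome_id
        rows[(genome, a.family)] = rows.get((genome, a.family), 0) + 1
    families = sorted({fam for (_, fam) in rows})
    counts = pd.DataFrame(0, index=genomes, columns=families, dtype=int)
    for (genome, fam), n in rows.items():
        counts.loc[genome, fam] = n
    frags = pd.Series(0, index=genomes, dtype=int)
    for c in calls:
        if c.status == STATUS_FRAGMENT:
            frags[c.genome_id] += 1
    return CypomeProfile(counts=counts, fragments_per_genome=frags)


def compute_stats(
    profile: CypomeProfile, n_subfamilies: int, n_in_bgc: int
) -> SummaryStats:
    """Apply the three summary formulas to a profile (see module docstring)."""
    n_species = len(profile.genomes)
    n_p450 = profile.n_p450
    if n_species == 0:
        raise ValueError("no species in profile")
    if n_p450 == 0:
        raise ValueError("no P450s in profile; ratios undefined")
    n_with = int((profile.counts.sum(axis=1) > 0).sum())
    n_families = len(profile.families)
    return SummaryStats(
        n_species=n_species,
        n_species_with_p450=n_with,
        n_p450=n_p450,
        n_families=n_families,
        n_subfamilies=n_subfamilies,
        avg_p450=n_p450 / n_species,
        diversity_pct=100.0 * n_families / (n_p450 * n_with),
        n_in_bgc=n_in_bgc,
        pct_in_bgc=100.0 * n_in_bgc / n_p450,
    )


def stats_from_values(
    n_species: int,
    n_species_with_p450: int,
    n_p450: int,
    n_families: int,
    n_subfamilies: int,
    n_in_bgc: int,
) -> SummaryStats:
    """Summary statistics straight from scalar totals (e.g. from published
    summary tables rather than a sequence-level profile)."""
    if n_species == 0 or n_p450 == 0:
        raise ValueError("zero species or zero P450s; ratios undefined")
    return SummaryStats(
        n_species=n_species,
        n_species_with_p450=n_species_with_p450,
        n_p450=n_p450,
        n_families=n_families,
        n_subfamilies=n_subfamilies,
        avg_p450=n_p450 / n_species,
        diversity_pct=100.0 * n_families / (n_p450 * n_species_with_p450),
        n_in_bgc=n_in_bgc,
        pct_in_bgc=100.0 * n_in_bgc / n_p450,
    )


def detect_bloomed(
    profile: CypomeProfile, multi_copy_min: int = 3, genome_frac_min: float = 0.5
) -> list[str]:
    """Families carried in >= ``multi_copy_min`` copies by at least
    ``genome_frac_min`` of the genomes (family blooming by gene duplication)."""
    n_genomes = len(profile.genomes)
    out = []
    for fam in profile.families:
        frac = float((profile.counts[fam] >= multi_copy_min).mean()) if n_genomes else 0.0
        if frac >= genome_frac_min:
            out.append(fam)
    return out


def detect_conserved(profile: CypomeProfile, presence_frac_min: float = 1.0) -> list[str]:
    """Families present (count >= 1) in at least ``presence_frac_min`` of the
    genomes; the default of 1.0 demands presence in every genome."""
    out = []
    for fam in profile.families:
        if float((profile.counts[fam] >= 1).mean()) >= presence_frac_min:
            out.append(fam)
    return out


def cluster_heatmap(profile: CypomeProfile) -> HeatmapMatrix:
    """Binary presence/absence heat-map with hierarchical clustering.

    Encodes counts>0 as 3 and 0 as -3, then clusters rows and columns with
    Euclidean distance and average linkage. Deterministic given input order
    (scipy's index-order tie-breaking). A degenerate all-equal matrix keeps
    the identity permutations and warns.
    """
    if len(profile.genomes) < 2 or len(profile.families) < 2:
        raise ValueError("heat-map clustering needs >= 2 genomes and >= 2 families")
    binary = (profile.counts.to_numpy() > 0).astype(float)
    values = pd.DataFrame(
        np.where(binary > 0, 3, -3).astype(int),
        index=profile.genomes,
        columns=profile.families,
    )
    if np.all(binary == binary.flat[0]):
        warnings.warn("degenerate all-equal matrix; identity ordering kept", stacklevel=2)
        return HeatmapMatrix(
            values=values,
            row_order=list(range(len(profile.genomes))),
            col_order=list(range(len(profile.families))),
            linkage_rows=None,
            linkage_cols=None,
        )
    lrow = linkage(pdist(binary, metric="euclidean"), method="average")
    lcol = linkage(pdist(binary.T, metric="euclidean"), method="average")
    return HeatmapMatrix(
        values=values,
        row_order=[int(i) for i in leaves_list(lrow)],
        col_order=[int(i) for i in leaves_list(lcol)],
        linkage_rows=lrow,
        linkage_cols=lcol,
    )


def write_profile(profile: CypomeProfile, path: str | Path) -> None:
    df = profile.counts.copy()
    df.insert(0, "n_fragments", profile.fragments_per_genome)
    df.to_csv(path, sep="\t", index_label="genome_id")


def write_heatmap(hm: HeatmapMatrix, path: str | Path) -> None:
    """Export the -3/3 matrix with clustered row/column orders appended as
    comment lines."""
    with open(path, "w") as fh:
        hm.values.to_csv(fh, sep="\t", index_label="genome_id")
        fh.write("#row_order\t" + ",".join(map(str, hm.row_order)) + "\n")
        fh.write("#col_order\t" + ",".join(map(str, hm.col_order)) + "\n")
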