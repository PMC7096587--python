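"""Alignment-column classification and biochemical property-change annotation.

A *clade-conserved polymorphism* (specificity-determining position
candidate) is a column where each of two groups is conserved above a
threshold but on different residues. Substitutions are annotated against
five fixed residue categorizations — charge, hydrophobicity, size,
polarity, and sidechain flexibility. Two cells of those tables are
deliberately absent: cysteine carries no polarity label and glycine no
flexibility label; such dimensions are reported as unclassified rather
than silently repaired (a repair option exists but defaults off).
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .seqio import AMINO_ACIDS, AlignedFamily, GAP

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
MAX_IC = math.log2(20)


class ConservationError(ValueError):
    pass


# ------------------------------------------------------- property tables

_RAW_TABLES: dict[str, dict[str, str]] = {
    "charge": {
        "positive": "RHK",
        "negative": "DE",
        "uncharged": "ANCQGILMFPSTWYV",
    },
    "hydrophobicity": {
        "hydrophobic": "ILVCAMF",
        "neutral/hydrophilic": "GYWHKTREQDNSP",
    },
    "size": {
        "small": "AGCS",
        "medium": "VTNPD",
        "large": "QEHKRFYWMIL",
    },
    "polarity": {
        "charged polar": "HRKED",
        "uncharged polar": "QTSNYW",
        "non-polar": "AGVLIPFM",
    },
    "flexibility": {
        "high": "KEMQR",
        "moderate": "DFHILNWY",
        "low": "CSTV",
        "limited": "A",
        "restricted": "P",
    },
}

# sha256 over the canonical serialization of the table above; guards the
# residue memberships against accidental edits.
_TABLES_SHA256 = "094055ebf1dd5ea38e0a88d5799776db40eb0843c7a4104fad531d43e19513a9"

DIMENSIONS = tuple(_RAW_TABLES)


@dataclass(frozen=True)
class PropertyTable:
    """The five residue categorizations, as residue -> label maps."""

    maps: dict[str, dict[str, str]]
    repaired: bool = False

    @classmethod
    def load(cls, repair: bool = False) -> "PropertyTable":
        _validate_tables()
        maps: dict[str, dict[str, str]] = {}
        for dim, groups in _RAW_TABLES.items():
            m: dict[str, str] = {}
            for label, residues in groups.items():
                for aa in residues:
                    if aa in m:
                        raise ConservationError(
                            f"{dim}: residue {aa} in two labels"
                        )
                    m[aa] = label
            maps[dim] = m
        if repair:
            maps["polarity"]["C"] = "non-polar"
            maps["flexibility"]["G"] = "high"
        return cls(maps=maps, repaired=repair)

    def label(self, dim: str, aa: str) -> str | None:
        if aa not in AMINO_ACIDS:
            raise ConservationError(f"non-standard residue {aa!r}")
        return self.maps[dim].get(aa)

    def unclassified(self, dim: str) -> set[str]:
        return set(AMINO_ACIDS) - set(self.maps[dim])


def _canonical_serialization() -> str:
    parts = []
    for dim in sorted(_RAW_TABLES):
        for label in sorted(_RAW_TABLES[dim]):
            parts.append(f"{dim}:{label}:{''.join(sorted(_RAW_TABLES[dim][label]))}")
    return ";".join(parts)


def _validate_tables() -> None:
    digest = hashlib.sha256(_canonical_serialization().encode()).hexdigest()
    if digest != _TABLES_SHA256:
        raise ConservationError(
            "property tables have been modified (checksum mismatch)"
        )
    covered = {
        "charge": set(AMINO_ACIDS),
        "hydrophobicity": set(AMINO_ACIDS),
        "size": set(AMINO_ACIDS),
        "polarity": set(AMINO_ACIDS) - {"C"},
        "flexibility": set(AMINO_ACIDS) - {"G"},
    }
    for dim, expected in covered.items():
        members = set("".join(_RAW_TABLES[dim].values()))
        if members != expected:
            raise ConservationError(f"{dim}: membership set incorrect")


# ------------------------------------------------------------- frequencies


def column_frequencies(
    family: AlignedFamily, group: list[str], column: int
) -> np.ndarray | None:
    """Gap-excluded residue frequencies (20-vector, MEME alphabet order) of
    one 1-based column within a group of sequence ids; None if all-gap.
    'X' residues are excluded along with gaps."""
    if not group:
        raise ConservationError("empty group")
    if not 1 <= column <= family.ncols:
        raise ConservationError(f"column {column} out of range 1..{family.ncols}")
    counts = np.zeros(20)
    for sid in group:
        ch = family.aligned(sid)[column - 1]
        if ch in AA_INDEX:
            counts[AA_INDEX[ch]] += 1
    total = counts.sum()
    if total == 0:
        return None
    return counts / total


def information_content(freqs: np.ndarray) -> float:
    """IC in bits: log2(20) minus the Shannon entropy of the frequencies.

    No small-sample correction is applied."""
    f = np.asarray(freqs, dtype=float)
    if not np.isclose(f.sum(), 1.0, atol=1e-6):
        raise ConservationError("frequency vector must sum to 1")
    nz = f[f > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return MAX_IC - entropy


def group_consensus(
    family: AlignedFamily,
    group: list[str],
    column: int,
    conservation_threshold: float = 0.8,
) -> str | None:
    """The residue whose gap-excluded frequency meets the threshold, or None.

    A column with more than 50% gaps within the group yields no consensus.
    """
    if not 0.5 < conservation_threshold <= 1:
        raise ConservationError("conservation_threshold must be in (0.5, 1]")
    gaps = sum(
        1 for sid in group if family.aligned(sid)[column - 1] not in AA_INDEX
    )
    if gaps > 0.5 * len(group):
        return None
    freqs = column_frequencies(family, group, column)
    if freqs is None:
        return None
    best = int(freqs.argmax())
    if freqs[best] >= conservation_threshold:
        return AMINO_ACIDS[best]
    return None


# --------------------------------------------------------- property changes


def annotate_property_change(
    aaA: str, aaB: str, tables: PropertyTable | None = None
) -> tuple[list[tuple[str, str, str]], list[str]]:
    """Per-dimension label changes between two residues.

    Returns (changes, unclassified): changes is a list of
    (dimension, labelA, labelB) where both residues are classified and
    their labels differ; unclassified lists dimensions where either
    residue has no label.
    """
    tables = tables or PropertyTable.load()
    changes: list[tuple[str, str, str]] = []
    unclassified: list[str] = []
    for dim in DIMENSIONS:
        la = tables.label(dim, aaA)
        lb = tables.label(dim, aaB)
        if la is None or lb is None:
            unclassified.append(dim)
        elif la != lb:
            changes.append((dim, la, lb))
    return changes, unclassified


@dataclass
class PolymorphismRecord:
    column: int  # 1-based alignment column
    group_a: str
    consensus_a: str
    group_b: str
    consensus_b: str
    property_changes: list[tuple[str, str, str]]
    unclassified_dimensions: list[str]
    reference_position: int | None = None  # ungapped position in a reference seq


def detect_group_polymorphisms(
    family: AlignedFamily,
    group_a_ids: list[str],
    group_b_ids: list[str],
    threshold: float = 0.8,
    tables: PropertyTable | None = None,
    group_a_label: str = "A",
    group_b_label: str = "B",
    reference_id: str | None = None,
) -> list[PolymorphismRecord]:
    """Columns where both groups are conserved (>= threshold) on different
    residues, annotated with biochemical property changes."""
    if not group_a_ids or not group_b_ids:
        raise ConservationError("both groups must be non-empty")
    if set(group_a_ids) & set(group_b_ids):
        raise ConservationError("groups overlap")
    tables = tables or PropertyTable.load()
    refmap = (
        _reference_positions(family, reference_id) if reference_id else None
    )
    out: list[PolymorphismRecord] = []
    for col in range(1, family.ncols + 1):
        ca = group_consensus(family, group_a_ids, col, threshold)
        cb = group_consensus(family, group_b_ids, col, threshold)
        if ca is None or cb is None or ca == cb:
            continue
        changes, unclassified = annotate_property_change(ca, cb, tables)
        out.append(
            PolymorphismRecord(
                column=col,
                group_a=group_a_label,
                consensus_a=ca,
                group_b=group_b_label,
                consensus_b=cb,
                property_changes=changes,
                unclassified_dimensions=unclassified,
                reference_position=refmap.get(col) if refmap else None,
            )
        )
    return out


def _reference_positions(family: AlignedFamily, seq_id: str) -> dict[int, int]:
    """Alignment column -> 1-based ungapped position in the reference."""
    out: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(family.aligned(seq_id), start=1):
        if ch != GAP:
            pos += 1
            out[col] = pos
    return out


# ----------------------------------------------------------- column reports

SHADING_BINS = ("100", "80-100", "60-80", "<60")


def shading_bin(majority_frequency: float) -> str:
    """Conservation shading bin of a pooled majority frequency."""
    if majority_frequency >= 1.0:
        return "100"
    if majority_frequency >= 0.8:
        return "80-100"
    if majority_frequency >= 0.6:
        return "60-80"
    return "<60"


@dataclass
class ColumnReport:
    column: int
    category: str  # core_conserved | class_characteristic | clade_polymorphic | unconserved
    detail: str  # class or clade-pair the category refers to, if any
    class_consensus: dict[str, str | None]
    pooled_majority: float
    shading: str
    pocket_flag: str | None = None  # e.g. substrate_contact / pocket_lining
    reference_position: int | None = None


def classify_columns(
    family: AlignedFamily,
    threshold: float = 0.8,
    clades: tuple[str, str] | None = None,
    pocket_flags: dict[int, str] | None = None,
    tables: PropertyTable | None = None,
    reference_id: str | None = None,
) -> list[ColumnReport]:
    """Classify every alignment column.

    core_conserved: one residue is the consensus of every class;
    class_characteristic(c): class c has a consensus differing from the
    shared consensus of all other classes; clade_polymorphic: the two
    designated clades have differing consensus residues; otherwise
    unconserved. Pocket flags (from the structure stage) are attached
    orthogonally; the shading bin comes from the pooled majority frequency.
    """
    classes = family.classes()
    if len(classes) < 2:
        raise ConservationError("need >= 2 classes to classify columns")
    usable = []
    for c in classes:
        members = family.members_of_class(c)
        if len(members) < 2:
            warnings.warn(f"class {c!r} has < 2 members; skipped", stacklevel=2)
            continue
        usable.append((c, members))
    if len(usable) < 2:
        raise ConservationError("fewer than 2 usable classes")

    clade_cols: dict[int, PolymorphismRecord] = {}
    if clades is not None:
        a_ids = family.members_of_clade(clades[0])
        b_ids = family.members_of_clade(clades[1])
        for rec in detect_group_polymorphisms(
            family, a_ids, b_ids, threshold,
            tables=tables, group_a_label=clades[0], group_b_label=clades[1],
        ):
            clade_cols[rec.column] = rec

    refmap = (
        _reference_positions(family, reference_id) if reference_id else None
    )
    pocket_flags = pocket_flags or {}
    reports: list[ColumnReport] = []
    for col in range(1, family.ncols + 1):
        cons = {
            c: group_consensus(family, members, col, threshold)
            for c, members in usable
        }
        values = list(cons.values())
        category, detail = "unconserved", ""
        if all(v is not None for v in values) and len(set(values)) == 1:
            category = "core_conserved"
        else:
            for c, v in cons.items():
                others = [cons[o] for o in cons if o != c]
                if (
                    v is not None
                    and all(o is not None for o in others)
                    and len(set(others)) == 1
                    and others[0] != v
                ):
                    category, detail = "class_characteristic", c
                    break
        if col in clade_cols:
            # clade polymorphism takes precedence: it is the pipeline's
            # candidate specificity signal
            rec = clade_cols[col]
            category = "clade_polymorphic"
            detail = f"{rec.group_a}:{rec.consensus_a}>{rec.group_b}:{rec.consensus_b}"

        pooled = column_frequencies(family, family.ids, col)
        maj = float(pooled.max()) if pooled is not None else 0.0
        reports.append(
            ColumnReport(
                column=col,
                category=category,
                detail=detail,
                class_consensus=cons,
                pooled_majority=maj,
                shading=shading_bin(maj),
                pocket_flag=pocket_flags.get(col),
                reference_position=refmap.get(col) if refmap else None,
            )
        )
    return reports


# ------------------------------------------------------------------- export


def polymorphisms_to_tsv(records: list[PolymorphismRecord]) -> str:
    lines = [
        "column\tref_position\tgroup_a\tconsensus_a\tgroup_b\tconsensus_b"
        "\tproperty_changes\tunclassified"
    ]
    for r in records:
        ch = ";".join(f"{d}:{a}->{b}" for d, a, b in r.property_changes)
        lines.append(
            f"{r.column}\t{r.reference_position or ''}\t{r.group_a}\t"
            f"{r.consensus_a}\t{r.group_b}\t{r.consensus_b}\t{ch}\t"
            f"{';'.join(r.unclassified_dimensions)}"
        )
    return "\n".join(lines) + "\n"


def reports_to_tsv(reports: list[ColumnReport]) -> str:
    lines = [
        "column\tref_position\tcategory\tdetail\tpooled_majority\tshading\tpocket_flag"
    ]
    for r in reports:
        lines.append(
            f"{r.column}\t{r.reference_position or ''}\t{r.category}\t{r.detail}"
            f"\t{r.pooled_majority:.4f}\t{r.shading}\t{r.pocket_flag or ''}"
        )
    return "\n".join(lines) + "\n"


def logo_data(
    family: AlignedFamily, group: list[str]
) -> list[tuple[int, np.ndarray | None, float | None]]:
    """Per-column (column, frequencies, IC) for logo rendering by external
    plotters."""
    out = []
    for col in range(1, family.ncols + 1):
        f = column_frequencies(family, group, col)
        out.append((col, f, information_content(f) if f is not None else None))
    return out


def logo_to_tsv(family: AlignedFamily, group: list[str]) -> str:
    """Stacked per-column frequencies plus IC as TSV (one row per column),
    directly consumable by standard logo plotters."""
    lines = ["column\tic_bits\t" + "\t".join(AMINO_ACIDS)]
    for col, f, ic in logo_data(family, group):
        if f is None:
            lines.append(f"{col}\t\t" + "\t".join([""] * 20))
        else:
            lines.append(
                f"{col}\t{ic:.4f}\t" + "\t".join(f"{v:.4f}" for v in f)
            )
    return "\n".join(lines) + "\n"
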