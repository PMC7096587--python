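"""Sequence and alignment I/O, pairwise global alignment, identity/similarity.

Percent similarity follows the criterion used throughout the pipeline's
alignment figures: two aligned residues count as *similar* when their
BLOSUM62 score is >= 1 (which includes every identical pair of standard
residues, since the BLOSUM62 diagonal is >= 1 everywhere).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
GAP = "-"

DenominatorPolicy = str  # {"alignment_length", "shorter_sequence", "ungapped_columns"}
_DENOMINATORS = ("alignment_length", "shorter_sequence", "ungapped_columns")


class SeqIOError(ValueError):
    """Raised on malformed sequence, alignment, or group-table input."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence: 20 standard residues plus 'X' for unknown."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise SeqIOError(f"sequence {self.id!r}: empty residues")
        up = self.residues.upper()
        for pos, ch in enumerate(up, start=1):
            if ch not in ALPHABET:
                raise SeqIOError(
                    f"sequence {self.id!r}: illegal residue {ch!r} at position {pos}"
                )
        object.__setattr__(self, "residues", up)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignedFamily:
    """Labeled aligned protein family: the substrate of all sequence stages.

    ``records`` preserves input order; every id carries a class label
    (e.g. GA20OX / GA3OX / C19-GA2OX / C20-GA2OX / non-GAOX) and optionally
    a clade label (e.g. monocot / Brassicales).
    """

    records: list[tuple[str, str]]
    class_of: dict[str, str]
    clade_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise SeqIOError("alignment has no records")
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SeqIOError(f"duplicate sequence ids: {dupes}")
        ncols = len(self.records[0][1])
        ragged = [i for i, s in self.records if len(s) != ncols]
        if ragged:
            raise SeqIOError(f"ragged alignment; offending ids: {ragged}")
        missing = [i for i in ids if i not in self.class_of]
        if missing:
            raise SeqIOError(f"ids missing from group table: {missing}")

    @property
    def ncols(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    def aligned(self, seq_id: str) -> str:
        for i, s in self.records:
            if i == seq_id:
                return s
        raise KeyError(seq_id)

    def ungapped(self, seq_id: str) -> str:
        return self.aligned(seq_id).replace(GAP, "")

    def members_of_class(self, label: str) -> list[str]:
        return [i for i in self.ids if self.class_of[i] == label]

    def members_of_clade(self, label: str) -> list[str]:
        return [i for i in self.ids if self.clade_of.get(i) == label]

    def classes(self) -> list[str]:
        seen: list[str] = []
        for i in self.ids:
            c = self.class_of[i]
            if c not in seen:
                seen.append(c)
        return seen

    def column(self, col: int) -> str:
        """1-based alignment column as a string of characters."""
        if not 1 <= col <= self.ncols:
            raise SeqIOError(f"column {col} out of range 1..{self.ncols}")
        return "".join(s[col - 1] for _, s in self.records)

    def subfamily(self, ids: list[str]) -> "AlignedFamily":
        keep = set(ids)
        return AlignedFamily(
            records=[(i, s) for i, s in self.records if i in keep],
            class_of={i: c for i, c in self.class_of.items() if i in keep},
            clade_of={i: c for i, c in self.clade_of.items() if i in keep},
        )

    def with_columns(self, cols: list[int]) -> "AlignedFamily":
        """New family keeping the given 1-based columns, in the given order."""
        idx = [c - 1 for c in cols]
        return AlignedFamily(
            records=[(i, "".join(s[j] for j in idx)) for i, s in self.records],
            class_of=dict(self.class_of),
            clade_of=dict(self.clade_of),
        )


@dataclass(frozen=True)
class SubstitutionMatrix:
    name: str
    scores: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                if (a, b) not in self.scores:
                    raise SeqIOError(f"matrix {self.name}: missing pair ({a},{b})")
                if self.scores[(a, b)] != self.scores[(b, a)]:
                    raise SeqIOError(f"matrix {self.name}: asymmetric at ({a},{b})")

    def score(self, a: str, b: str) -> float:
        # 'X' scores 0 against everything, including itself.
        if a == "X" or b == "X":
            return 0.0
        return float(self.scores[(a, b)])


def read_ncbi_matrix(path_or_text, name: str = "custom") -> SubstitutionMatrix:
    """Parse an NCBI-format substitution matrix ('#' comments, letter header)."""
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        with open(path_or_text) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split()
    scores: dict[tuple[str, str], int] = {}
    for ln in lines[1:]:
        parts = ln.split()
        row = parts[0]
        for colname, v in zip(header, parts[1:]):
            if row in AMINO_ACIDS and colname in AMINO_ACIDS:
                scores[(row, colname)] = int(v)
    return SubstitutionMatrix(name=name, scores=scores)


def blosum62() -> SubstitutionMatrix:
    """The bundled BLOSUM62 matrix (half-bit units)."""
    ref = importlib.resources.files("sdpscan.data").joinpath("BLOSUM62.txt")
    with ref.open() as fh:
        return read_ncbi_matrix(fh, name="BLOSUM62")


@dataclass(frozen=True)
class SimilarityConfig:
    """Scoring configuration for pairwise alignment and similarity counts.

    ``similar_threshold`` of 1 means a residue pair is similar iff its
    matrix score is >= 1. A gap of length L costs
    ``gap_open + (L - 1) * gap_extend``.
    """

    matrix: SubstitutionMatrix = field(default_factory=blosum62)
    similar_threshold: int = 1
    gap_open: float = 10.0
    gap_extend: float = 0.5
    denominator: DenominatorPolicy = "ungapped_columns"

    def __post_init__(self) -> None:
        if self.denominator not in _DENOMINATORS:
            raise SeqIOError(
                f"denominator must be one of {_DENOMINATORS}, got {self.denominator!r}"
            )


# ---------------------------------------------------------------- FASTA I/O


def read_fasta(path) -> list[ProteinSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SeqIOError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.append(ProteinSequence(id=rec.id, residues=str(rec.seq), description=desc))
    return out


def write_fasta(path, seqs: list[ProteinSequence], width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            header = s.id if not s.description else f"{s.id} {s.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i:i + width] + "\n")


def read_groups(path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a tab-separated ``id<TAB>class[<TAB>clade]`` table ('#' comments)."""
    class_of: dict[str, str] = {}
    clade_of: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise SeqIOError(f"{path}:{lineno}: expected id<TAB>class[<TAB>clade]")
            class_of[parts[0]] = parts[1]
            if len(parts) >= 3 and parts[2]:
                clade_of[parts[0]] = parts[2]
    if not class_of:
        raise SeqIOError(f"{path}: empty group table")
    return class_of, clade_of


def write_groups(path, class_of: dict[str, str], clade_of: dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("# id\tclass\tclade\n")
        for i, c in class_of.items():
            fh.write(f"{i}\t{c}\t{clade_of.get(i, '')}\n")


def read_alignment(path, groups_path) -> AlignedFamily:
    """Read an aligned FASTA plus its group table into an AlignedFamily."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SeqIOError(f"{path}: no FASTA records found")
    recs: list[tuple[str, str]] = []
    for rec in records:
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq, start=1):
            if ch not in ALPHABET and ch != GAP:
                raise SeqIOError(
                    f"{path}: sequence {rec.id!r}: illegal character {ch!r} "
                    f"at column {pos}"
                )
        recs.append((rec.id, seq))
    class_of, clade_of = read_groups(groups_path)
    return AlignedFamily(records=recs, class_of=class_of, clade_of=clade_of)


def write_alignment(path, family: AlignedFamily, width: int = 60) -> None:
    with open(path, "w") as fh:
        for i, s in family.records:
            fh.write(f">{i}\n")
            for k in range(0, len(s), width):
                fh.write(s[k:k + width] + "\n")


# ------------------------------------------------- pairwise global alignment


def pairwise_align(
    a: ProteinSequence, b: ProteinSequence, cfg: SimilarityConfig | None = None
) -> tuple[str, str, float]:
    """Global affine-gap alignment (Gotoh), maximizing the matrix score.

    Returns (gapped_a, gapped_b, score). Traceback ties are broken
    deterministically: diagonal first, then gap-in-b (consume a), then
    gap-in-a.
    """
    cfg = cfg or SimilarityConfig()
    sa, sb = a.residues, b.residues
    n, m = len(sa), len(sb)
    go, ge = cfg.gap_open, cfg.gap_extend
    neg = float("-inf")

    # M: both consumed; U: gap in b (a consumed); L: gap in a (b consumed)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    U = [[neg] * (m + 1) for _ in range(n + 1)]
    L = [[neg] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        U[i][0] = -(go + (i - 1) * ge)
    for j in range(1, m + 1):
        L[0][j] = -(go + (j - 1) * ge)

    for i in range(1, n + 1):
        Mi, Ui, Li = M[i], U[i], L[i]
        Mp, Up, Lp = M[i - 1], U[i - 1], L[i - 1]
        ca = sa[i - 1]
        for j in range(1, m + 1):
            s = cfg.matrix.score(ca, sb[j - 1])
            Mi[j] = max(Mp[j - 1], Up[j - 1], Lp[j - 1]) + s
            Ui[j] = max(Mp[j] - go, Up[j] - ge, Lp[j] - go)
            Li[j] = max(Mi[j - 1] - go, Ui[j - 1] - go, Li[j - 1] - ge)
        U[i][0] = -(go + (i - 1) * ge)

    i, j = n, m
    # entry state at (n, m): prefer M, then U, then L
    score = max(M[n][m], U[n][m], L[n][m])
    if M[i][j] == score:
        state = "M"
    elif U[i][j] == score:
        state = "U"
    else:
        state = "L"

    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = cfg.matrix.score(sa[i - 1], sb[j - 1])
            prev = M[i][j] - s
            ra.append(sa[i - 1])
            rb.append(sb[j - 1])
            i, j = i - 1, j - 1
            if M[i][j] == prev:
                state = "M"
            elif U[i][j] == prev:
                state = "U"
            else:
                state = "L"
        elif state == "U":
            if i == 0:
                raise AssertionError("traceback underflow")
            v = U[i][j]
            ra.append(sa[i - 1])
            rb.append(GAP)
            i -= 1
            if j == 0:
                state = "U" if i > 0 else "M"
                continue
            if M[i][j] - go == v:
                state = "M"
            elif U[i][j] - ge == v:
                state = "U"
            else:
                state = "L"
        else:  # L
            v = L[i][j]
            ra.append(GAP)
            rb.append(sb[j - 1])
            j -= 1
            if i == 0:
                state = "L" if j > 0 else "M"
                continue
            if M[i][j] - go == v:
                state = "M"
            elif U[i][j] - go == v:
                state = "U"
            else:
                state = "L"
        if i == 0 and j == 0:
            break
    return "".join(reversed(ra)), "".join(reversed(rb)), score


# ------------------------------------------------------ identity / similarity


def _column_counts(alnA: str, alnB: str):
    if len(alnA) != len(alnB):
        raise SeqIOError("aligned strings differ in length")
    pairs = []
    for x, y in zip(alnA, alnB):
        if x == GAP and y == GAP:
            continue  # gap-gap columns never counted
        pairs.append((x, y))
    return pairs


def _denominator(alnA: str, alnB: str, policy: DenominatorPolicy) -> int:
    pairs = _column_counts(alnA, alnB)
    if policy == "alignment_length":
        return len(pairs)
    if policy == "shorter_sequence":
        return min(
            len(alnA.replace(GAP, "")), len(alnB.replace(GAP, ""))
        )
    if policy == "ungapped_columns":
        return sum(1 for x, y in pairs if x != GAP and y != GAP)
    raise SeqIOError(f"unknown denominator policy {policy!r}")


def percent_identity(
    alnA: str, alnB: str, denominator_policy: DenominatorPolicy = "ungapped_columns"
) -> float:
    """Percent of aligned residue pairs that are identical ('X' never counts)."""
    denom = _denominator(alnA, alnB, denominator_policy)
    if denom == 0:
        raise SeqIOError("zero denominator for percent identity")
    ident = sum(
        1
        for x, y in _column_counts(alnA, alnB)
        if x != GAP and y != GAP and x == y and x != "X"
    )
    return 100.0 * ident / denom


def percent_similarity(
    alnA: str, alnB: str, cfg: SimilarityConfig | None = None
) -> float:
    """Percent of aligned residue pairs scoring >= the similarity threshold."""
    cfg = cfg or SimilarityConfig()
    denom = _denominator(alnA, alnB, cfg.denominator)
    if denom == 0:
        raise SeqIOError("zero denominator for percent similarity")
    sim = sum(
        1
        for x, y in _column_counts(alnA, alnB)
        if x != GAP
        and y != GAP
        and cfg.matrix.score(x, y) >= cfg.similar_threshold
    )
    return 100.0 * sim / denom


def similarity_with_policy(
    alnA: str, alnB: str, policy: DenominatorPolicy, cfg: SimilarityConfig | None = None
) -> float:
    cfg = cfg or SimilarityConfig()
    return percent_similarity(alnA, alnB, replace(cfg, denominator=policy))
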