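"""Ground-truth generators for every pipeline stage.

Families are evolved leaf-ward along a known tree under a 20-state
Jukes-Cantor-like Poisson process (uniform replacement), then clade-specific
conserved polymorphisms and class-specific motif instances are planted;
toy structures place residues with known proximity and sidechain
orientation around a planted ligand, Fe site, and 2-oxoglutarate site.
Everything is deterministic given the seed.

The generated data emulate the statistical structure the pipeline targets
(clade-conserved columns, class-specific motifs, pocket geometry) but not
indels (families are gapless; gap handling is exercised by hand fixtures),
rate heterogeneity, or realistic substitution matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .seqio import AMINO_ACIDS, AlignedFamily
from .structure import (
    LigandSite,
    StructureModel,
    read_pdb,
    select_contact_residues,
)


class SyntheticError(ValueError):
    pass


# ------------------------------------------------------------- family truth


@dataclass
class FamilyTruth:
    tree_newick: str
    polymorphic_columns: dict[int, dict[str, str]]  # column -> clade -> residue
    motif_positions: dict[str, dict[str, int]]  # motif consensus -> seq -> start
    groups: dict[str, tuple[str, str]]  # leaf -> (class, clade)


def two_clade_tree(
    n_per_clade: int = 10,
    terminal: float = 0.05,
    internal: float = 0.05,
    between: float = 0.2,
    clade_names: tuple[str, str] = ("monocot", "brassicales"),
) -> tuple[str, dict[str, tuple[str, str]]]:
    """Two-clade binary (balanced-within-clade) newick tree and its
    leaf -> (class, clade) map.

    ``terminal``/``internal`` are within-clade branch lengths and
    ``between`` the total stem length separating the clades (subs/site);
    the defaults give a root-to-leaf depth of roughly 0.3
    substitutions/site and a fully resolved topology.
    """

    def balanced(leaves: list[str]) -> str:
        if len(leaves) == 1:
            return f"{leaves[0]}:{terminal}"
        mid = len(leaves) // 2
        return (
            f"({balanced(leaves[:mid])},{balanced(leaves[mid:])}):{internal}"
        )

    groups: dict[str, tuple[str, str]] = {}
    parts = []
    for cname in clade_names:
        leaves = [f"{cname}_{k}" for k in range(n_per_clade)]
        for leaf in leaves:
            groups[leaf] = ("GA3OX", cname)
        sub = balanced(leaves)
        parts.append(f"{sub[:sub.rfind(':')]}:{between / 2}")
    return "(" + ",".join(parts) + ");", groups


@dataclass
class FamilySpec:
    """Conditions for a simulated family.

    Defaults mirror the pipeline's reference recovery experiment: two
    clades of 10 sequences each, 300 columns, 5 planted clade-polymorphic
    columns, zero planting noise.
    """

    tree: str = ""
    groups: dict[str, tuple[str, str]] = field(default_factory=dict)
    length: int = 300
    planted_polymorphisms: dict[int, dict[str, str]] = field(default_factory=dict)
    planted_motifs: list[tuple[str, frozenset[str], int]] = field(
        default_factory=list
    )  # (consensus, class set, start window offset)
    noise: float = 0.0
    seed: int = 0
    # columns are scrubbed so that, at this consensus threshold, the planted
    # columns are exactly the clade-polymorphic ones (ground-truth control)
    scrub_threshold: float = 0.8

    def __post_init__(self) -> None:
        if not self.tree:
            self.tree, groups = two_clade_tree()
            if not self.groups:
                self.groups = groups
        if not 0 <= self.noise < 1:
            raise SyntheticError("noise must be in [0, 1)")
        for col in self.planted_polymorphisms:
            if not 1 <= col <= self.length:
                raise SyntheticError(f"planted column {col} beyond length {self.length}")
            residues = list(self.planted_polymorphisms[col].values())
            if len(set(residues)) < len(residues):
                raise SyntheticError(
                    f"planted column {col}: clade residues must differ"
                )


def default_polymorphic_columns(
    n: int = 5, length: int = 300, clades: tuple[str, str] = ("monocot", "brassicales")
) -> dict[int, dict[str, str]]:
    """Evenly spaced planted columns with property-contrasting residue pairs."""
    pairs = [("A", "I"), ("K", "D"), ("S", "W"), ("G", "R"), ("T", "F"),
             ("N", "L"), ("Q", "C"), ("E", "V")]
    cols = np.linspace(20, length - 20, n).astype(int)
    out = {}
    for k, col in enumerate(cols):
        a, b = pairs[k % len(pairs)]
        out[int(col)] = {clades[0]: a, clades[1]: b}
    return out


def _evolve(
    tree: dendropy.Tree, length: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Evolve integer-coded sequences leaf-ward under the 20-state JC-like
    process: along a branch of length t (expected subs/site), a site keeps
    its state with probability e^(-20 t / 19), else becomes uniform over
    all 20 states."""
    seqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    seqs[id(root)] = rng.integers(0, 20, size=length)
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        parent_seq = seqs[id(node.parent_node)]
        p_keep = math.exp(-20.0 * t / 19.0)
        resample = rng.random(length) >= p_keep
        child = parent_seq.copy()
        n_re = int(resample.sum())
        if n_re:
            child[resample] = rng.integers(0, 20, size=n_re)
        seqs[id(node)] = child
        if node.is_leaf():
            out[node.taxon.label] = child
    return out


def simulate_family(spec: FamilySpec) -> tuple[AlignedFamily, FamilyTruth]:
    """Simulate an aligned (gapless) family with planted ground truth."""
    rng = np.random.default_rng(spec.seed)
    tree = dendropy.Tree.get(
        data=spec.tree, schema="newick", preserve_underscores=True
    )
    leaf_seqs = _evolve(tree, spec.length, rng)
    missing = [lf for lf in leaf_seqs if lf not in spec.groups]
    if missing:
        raise SyntheticError(f"leaves missing from groups: {missing}")

    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")

    # scrub incidental clade polymorphisms from non-planted columns: where
    # two clades happen to have fixed different residues, flip just enough
    # members of the second clade to break its consensus at scrub_threshold
    clades = sorted({clade for _, clade in spec.groups.values()})
    members = {
        cl: [lf for lf in leaf_seqs if spec.groups[lf][1] == cl] for cl in clades
    }

    def consensus_state(clade: str, col: int) -> int | None:
        states = [leaf_seqs[lf][col - 1] for lf in members[clade]]
        vals, counts = np.unique(states, return_counts=True)
        k = int(counts.argmax())
        if counts[k] / len(states) >= spec.scrub_threshold:
            return int(vals[k])
        return None

    for col in range(1, spec.length + 1):
        if col in spec.planted_polymorphisms:
            continue
        for ai in range(len(clades)):
            for bi in range(ai + 1, len(clades)):
                ca = consensus_state(clades[ai], col)
                cb = consensus_state(clades[bi], col)
                if ca is None or cb is None or ca == cb:
                    continue
                group = members[clades[bi]]
                n = len(group)
                majority = [lf for lf in group if leaf_seqs[lf][col - 1] == cb]
                # leave at most ceil(threshold * n) - 1 copies of the residue;
                # the flipped members are drawn at random so the scrub adds no
                # systematic grouping signal
                allowed = int(np.ceil(spec.scrub_threshold * n)) - 1
                n_flip = max(0, len(majority) - allowed)
                flip = rng.choice(len(majority), size=n_flip, replace=False)
                for k in flip:
                    leaf_seqs[majority[int(k)]][col - 1] = ca

    # plant clade-specific conserved polymorphisms, then add noise
    for col, clade_res in spec.planted_polymorphisms.items():
        for leaf, seq in leaf_seqs.items():
            clade = spec.groups[leaf][1]
            if clade in clade_res:
                seq[col - 1] = AMINO_ACIDS.index(clade_res[clade])
        if spec.noise > 0:
            for leaf, seq in leaf_seqs.items():
                if rng.random() < spec.noise:
                    cur = seq[col - 1]
                    alt = rng.integers(0, 19)
                    seq[col - 1] = alt if alt < cur else alt + 1

    # plant class-specific motif instances (overwriting background)
    motif_positions: dict[str, dict[str, int]] = {}
    for consensus, class_set, start in spec.planted_motifs:
        w = len(consensus)
        if start < 1 or start + w - 1 > spec.length:
            raise SyntheticError(f"motif window [{start}, {start + w - 1}] out of range")
        positions: dict[str, int] = {}
        enc = np.array([AMINO_ACIDS.index(c) for c in consensus])
        for leaf, seq in leaf_seqs.items():
            if spec.groups[leaf][0] in class_set:
                seq[start - 1:start - 1 + w] = enc
                positions[leaf] = start
        motif_positions[consensus] = positions

    records = [
        (leaf, "".join(aa[leaf_seqs[leaf]]))
        for leaf in sorted(leaf_seqs)
    ]
    family = AlignedFamily(
        records=records,
        class_of={lf: spec.groups[lf][0] for lf in leaf_seqs},
        clade_of={lf: spec.groups[lf][1] for lf in leaf_seqs},
    )
    truth = FamilyTruth(
        tree_newick=spec.tree,
        polymorphic_columns=dict(spec.planted_polymorphisms),
        motif_positions=motif_positions,
        groups=dict(spec.groups),
    )
    return family, truth


def expected_p_distance(t: float) -> float:
    """Expected proportion of differing sites between two sequences
    separated by path length t under the 20-state process."""
    return (19.0 / 20.0) * (1.0 - math.exp(-20.0 * t / 19.0))


# ----------------------------------------------------------- toy structures


@dataclass
class ToyStructureSpec:
    """Geometry for a toy pocket: residue counts per planted role.

    Contacts and lining residues sit with nearest sidechain/backbone atom at
    U(3.5, 4.9) A from the substrate; cofactor residues place a sidechain
    atom 2.2 A from the Fe site; background residues sit beyond 6 A.
    """

    n_contact: int = 3
    n_lining: int = 2
    n_cofactor: int = 2
    n_background: int = 5
    seed: int = 0


@dataclass
class StructureTruth:
    roles: dict[tuple[str, int, str], str]  # residue key -> planted role


def _pdb_atom_line(
    serial: int, name: str, resname: str, chain: str, resnum: int,
    xyz: np.ndarray, element: str, het: bool = False,
) -> str:
    rec = "HETATM" if het else "ATOM  "
    return (
        f"{rec}{serial:>5} {name:<4}{resname:>4} {chain}{resnum:>4}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          "
        f"{element:>2}"
    )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


_ROLE_NAMES = {
    "cofactor": "cofactor_coordinating",
    "contact": "substrate_contact",
    "lining": "pocket_lining_only",
    "background": "none",
}

_SUBSTRATE = np.array([[0.0, 0.0, 0.0], [1.2, 0.0, 0.0], [0.0, 1.2, 0.0]])
_FE = np.array([0.4, 0.4, -3.0])  # reaction center below the substrate
_OG = np.array([[1.8, 0.4, -3.2], [2.6, 0.4, -3.6]])

_AA_3LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def _residue_atoms(role: str, rng: np.random.Generator):
    """CA/CB/CG coordinates realizing one planted role around the pocket."""
    def rand_dir() -> np.ndarray:
        return _unit(rng.normal(size=3))

    if role == "cofactor":
        # sidechain tip 2.2 A from Fe, between Fe and substrate so it stays
        # within the substrate cutoff
        u = _unit(_SUBSTRATE.mean(axis=0) - _FE)
        tip = _FE + 2.2 * u
        cb = tip + 1.0 * u
        ca = tip + 2.5 * u + 0.5 * rand_dir()
    elif role == "background":
        # all atoms beyond 6 A from any substrate atom
        ca = _SUBSTRATE.mean(axis=0) + rng.uniform(11.0, 15.0) * rand_dir()
        cb = ca + 1.5 * rand_dir()
        tip = cb + 1.5 * rand_dir()
    else:
        anchor = _SUBSTRATE[rng.integers(len(_SUBSTRATE))]
        d = rng.uniform(3.5, 4.9)
        tip = anchor + d * rand_dir()
        if role == "contact":
            # sidechain nearer the reaction center (Fe) than CA
            w = _unit(tip - _FE)
            cb = tip + 0.8 * w
            ca = tip + 2.2 * w
        else:  # lining: CA nearest, sidechain pointing away from center
            ca = tip
            w = _unit(ca - _FE)
            cb = ca + 1.5 * w
            tip = ca + 2.8 * w
    return [("CA", ca), ("CB", cb), ("CG", tip)]


def _build_pdb(
    roles_by_resnum: dict[int, str],
    names_by_resnum: dict[int, str],
    rng: np.random.Generator,
) -> tuple[str, StructureTruth]:
    lines: list[str] = []
    serial = 1
    roles: dict[tuple[str, int, str], str] = {}
    for resnum in sorted(roles_by_resnum):
        role = roles_by_resnum[resnum]
        for name, xyz in _residue_atoms(role, rng):
            lines.append(
                _pdb_atom_line(
                    serial, name, names_by_resnum[resnum], "A", resnum, xyz, "C"
                )
            )
            serial += 1
        roles[("A", resnum, "")] = _ROLE_NAMES[role]

    hetnum = max(roles_by_resnum) + 1
    for k, xyz in enumerate(_SUBSTRATE):
        lines.append(
            _pdb_atom_line(serial, f"C{k + 1}", "LIG", "L", hetnum, xyz, "C", het=True)
        )
        serial += 1
    lines.append(
        _pdb_atom_line(serial, "FE", "FE", "L", hetnum + 1, _FE, "FE", het=True)
    )
    serial += 1
    for k, xyz in enumerate(_OG):
        lines.append(
            _pdb_atom_line(
                serial, f"O{k + 1}", "AKG", "L", hetnum + 2, xyz, "O", het=True
            )
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n", StructureTruth(roles=roles)


def _realize(
    roles_by_resnum: dict[int, str],
    names_by_resnum: dict[int, str],
    seed: int,
):
    """Build a PDB realizing the planted roles; re-draw geometry until the
    pocket triage reproduces the plan exactly (error after 100 attempts)."""
    for attempt in range(100):
        rng = np.random.default_rng(seed + attempt * 7919)
        text, truth = _build_pdb(roles_by_resnum, names_by_resnum, rng)
        model, hets = read_pdb_from_text(text)
        site = LigandSite.from_het_groups(hets)
        pocket = select_contact_residues(model, site)
        got = {e.residue.key: e.role for e in pocket.entries}
        if got == truth.roles:
            return text, model, site, truth
    raise SyntheticError("infeasible toy-structure geometry after 100 attempts")


def simulate_structure(
    spec: ToyStructureSpec,
) -> tuple[str, StructureModel, LigandSite, StructureTruth]:
    """Generate a toy pocket as PDB text plus the parsed model, ligand site,
    and planted role truth. Each residue carries CA plus a 2-atom
    pseudo-sidechain (CB, CG)."""
    plan: dict[int, str] = {}
    resnum = 1
    for role, count in (
        ("contact", spec.n_contact),
        ("lining", spec.n_lining),
        ("cofactor", spec.n_cofactor),
        ("background", spec.n_background),
    ):
        for _ in range(count):
            plan[resnum] = role
            resnum += 1
    names = {r: "LEU" for r in plan}
    return _realize(plan, names, spec.seed)


def simulate_pocket_structure(
    sequence: str,
    roles_by_position: dict[int, str],
    seed: int = 0,
) -> tuple[str, StructureModel, LigandSite, StructureTruth]:
    """Toy pocket whose chain A mirrors a reference protein sequence.

    ``roles_by_position`` maps 1-based sequence positions to planted roles
    ('contact' | 'lining' | 'cofactor'); all other positions become
    background residues. Residue names follow the sequence, so the chain
    maps 1:1 onto the reference for column<->residue mapping.
    """
    plan = {
        pos: roles_by_position.get(pos, "background")
        for pos in range(1, len(sequence) + 1)
    }
    bad = [p for p in roles_by_position if not 1 <= p <= len(sequence)]
    if bad:
        raise SyntheticError(f"planted positions out of range: {bad}")
    unknown = [r for r in roles_by_position.values() if r not in _ROLE_NAMES]
    if unknown:
        raise SyntheticError(f"unknown roles: {unknown}")
    names = {
        pos: _AA_3LETTER[sequence[pos - 1]] for pos in plan
    }
    return _realize(plan, names, seed)


def read_pdb_from_text(text: str):
    """Parse PDB text via the same reader used for files."""
    import tempfile
    import os

    fd, path = tempfile.mkstemp(suffix=".pdb")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        return read_pdb(path)
    finally:
        os.remove(path)
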