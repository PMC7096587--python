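"""Structure reading and substrate-pocket residue triage.

The triage mirrors how contact residues are nominated in 2-oxoglutarate
dioxygenase active sites: residues with any heavy atom within a distance
cutoff (default 5 A, inclusive) of the docked substrate, whose sidechain
centroid points inward toward the reaction center (default: the Fe(II)
site), are *flagged*; among those, residues whose sidechains sit at
coordination/H-bond range of the Fe(II) or the 2-oxoglutarate co-substrate
are set aside as cofactor-coordinating, and the remainder are the
substrate-contact candidates. Within-cutoff residues that fail the
orientation test are pocket-lining only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException
from Bio.PDB.Polypeptide import protein_letters_3to1

from .motifs import MotifArchitecture
from .seqio import AlignedFamily, GAP

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]

    @property
    def coord(self) -> np.ndarray:
        return np.array(self.xyz)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class Residue:
    chain: str
    name: str  # 3-letter
    number: int  # author numbering
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.icode)

    @property
    def has_ca(self) -> bool:
        return any(a.name == "CA" for a in self.atoms)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise StructureError(f"residue {self.name}{self.number}: no atom {name!r}")

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coord for a in self.atoms if not a.is_hydrogen]
        if not pts:
            raise StructureError(f"residue {self.name}{self.number}: no heavy atoms")
        return np.vstack(pts)

    def sidechain_coords(self) -> np.ndarray | None:
        pts = [
            a.coord
            for a in self.atoms
            if not a.is_hydrogen and a.name not in BACKBONE_ATOMS
        ]
        return np.vstack(pts) if pts else None


@dataclass
class StructureModel:
    chains: dict[str, list[Residue]]

    def residues(self, chain: str | None = None) -> list[Residue]:
        if chain is not None:
            if chain not in self.chains:
                raise StructureError(f"no chain {chain!r}")
            return list(self.chains[chain])
        return [r for ress in self.chains.values() for r in ress]

    def chain_sequence(self, chain: str) -> str:
        """1-letter sequence of a chain ('X' for unknown residue names)."""
        return "".join(
            protein_letters_3to1.get(r.name, "X") for r in self.residues(chain)
        )


@dataclass
class LigandSite:
    substrate_atoms: np.ndarray  # (k, 3) docked substrate heavy atoms
    fe_site: np.ndarray  # (3,)
    og_site: np.ndarray  # (m, 3) 2-oxoglutarate heavy atoms
    reaction_center: np.ndarray | None = None  # defaults to fe_site

    def __post_init__(self) -> None:
        self.substrate_atoms = np.atleast_2d(np.asarray(self.substrate_atoms, float))
        self.fe_site = np.asarray(self.fe_site, float).reshape(3)
        self.og_site = np.atleast_2d(np.asarray(self.og_site, float))
        if self.substrate_atoms.size == 0:
            raise StructureError("substrate_atoms must be non-empty")
        if self.reaction_center is None:
            self.reaction_center = self.fe_site.copy()
        else:
            self.reaction_center = np.asarray(self.reaction_center, float).reshape(3)

    @classmethod
    def from_het_groups(
        cls,
        het_groups: dict[str, list[Residue]],
        substrate_het: str = "LIG",
        fe_het: str = "FE",
        og_het: str = "AKG",
        reaction_center: str = "fe",
    ) -> "LigandSite":
        def coords(name: str) -> np.ndarray:
            if name not in het_groups:
                raise StructureError(f"no HETATM group {name!r} in structure")
            return np.vstack(
                [r.heavy_coords() for r in het_groups[name]]
            )
        sub = coords(substrate_het)
        fe = coords(fe_het)
        if fe.shape[0] != 1:
            raise StructureError(f"expected a single {fe_het} atom, got {fe.shape[0]}")
        og = coords(og_het)
        center = fe[0] if reaction_center == "fe" else sub.mean(axis=0)
        return cls(
            substrate_atoms=sub, fe_site=fe[0], og_site=og, reaction_center=center
        )


@dataclass(frozen=True)
class PocketConfig:
    substrate_cutoff: float = 5.0  # A, inclusive
    fe_cutoff: float = 2.6  # typical Fe coordination distance
    og_cutoff: float = 3.5  # H-bond / salt-bridge range
    orientation: str = "centroid"  # or "angle"
    exclude_nonreactive: bool = False  # optionally drop ALA/GLY sidechains

    def __post_init__(self) -> None:
        if self.substrate_cutoff <= 0:
            raise StructureError("substrate_cutoff must be positive")
        if self.orientation not in ("centroid", "angle"):
            raise StructureError(f"unknown orientation test {self.orientation!r}")


@dataclass
class ResidueTriage:
    residue: Residue
    min_substrate_dist: float
    min_fe_sidechain_dist: float | None
    min_og_sidechain_dist: float | None
    orientation_pass: bool
    glycine: bool
    role: str  # cofactor_coordinating | substrate_contact | pocket_lining_only | none


@dataclass
class PocketResidueSet:
    entries: list[ResidueTriage]

    def with_role(self, role: str) -> list[ResidueTriage]:
        return [e for e in self.entries if e.role == role]

    @property
    def flagged(self) -> list[ResidueTriage]:
        """Within cutoff, inward-oriented: contact + cofactor sets."""
        return [
            e
            for e in self.entries
            if e.role in ("cofactor_coordinating", "substrate_contact")
        ]

    def counts(self) -> dict[str, int]:
        return {
            "flagged": len(self.flagged),
            "cofactor_coordinating": len(self.with_role("cofactor_coordinating")),
            "substrate_contact": len(self.with_role("substrate_contact")),
            "pocket_lining_only": len(self.with_role("pocket_lining_only")),
        }

    def to_tsv(self) -> str:
        lines = [
            "chain\tresnum\ticode\tresname\trole\tmin_substrate_dist"
            "\tmin_fe_sidechain_dist\tmin_og_sidechain_dist\torientation_pass"
        ]
        for e in self.entries:
            r = e.residue
            fe = "" if e.min_fe_sidechain_dist is None else f"{e.min_fe_sidechain_dist:.3f}"
            og = "" if e.min_og_sidechain_dist is None else f"{e.min_og_sidechain_dist:.3f}"
            lines.append(
                f"{r.chain}\t{r.number}\t{r.icode}\t{r.name}\t{e.role}\t"
                f"{e.min_substrate_dist:.3f}\t{fe}\t{og}\t{e.orientation_pass}"
            )
        return "\n".join(lines) + "\n"


# -------------------------------------------------------------------- PDB I/O


def read_pdb(path) -> tuple[StructureModel, dict[str, list[Residue]]]:
    """Parse a PDB file into (StructureModel, het groups keyed by residue
    name). First MODEL only; for altloc alternatives the highest-occupancy
    atom is kept (ties resolved toward altloc 'A'); waters are dropped."""
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        struct = parser.get_structure("model", str(path))
    except (PDBConstructionException, ValueError) as e:
        raise StructureError(f"{path}: cannot parse PDB: {e}") from e
    models = list(struct)
    if not models:
        raise StructureError(f"{path}: no models in file")
    model = models[0]

    chains: dict[str, list[Residue]] = {}
    hets: dict[str, list[Residue]] = {}
    n_atoms = 0
    for chain in model:
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag == "W":
                continue
            atoms: dict[str, Atom] = {}
            best_occ: dict[str, tuple[float, str]] = {}
            for atom in res.get_unpacked_list():
                occ = atom.get_occupancy() or 1.0
                alt = atom.get_altloc() or " "
                name = atom.get_name()
                prev = best_occ.get(name)
                # higher occupancy wins; on ties, the earlier altloc letter
                if prev is None or occ > prev[0] or (occ == prev[0] and alt < prev[1]):
                    best_occ[name] = (occ, alt)
                    x, y, z = atom.get_coord()
                    if not np.all(np.isfinite([x, y, z])):
                        raise StructureError(
                            f"{path}: non-finite coordinate in atom {name}"
                        )
                    atoms[name] = Atom(
                        name=name,
                        element=(atom.element or "").strip() or name[0],
                        xyz=(float(x), float(y), float(z)),
                    )
            rec = Residue(
                chain=chain.id,
                name=res.get_resname().strip(),
                number=resseq,
                icode=icode.strip(),
                atoms=list(atoms.values()),
            )
            n_atoms += len(rec.atoms)
            if hetflag.strip():
                hets.setdefault(rec.name, []).append(rec)
            else:
                chains.setdefault(chain.id, []).append(rec)
    if not any(chains.values()):
        raise StructureError(f"{path}: no ATOM records")
    for ress in chains.values():
        for r in ress:
            if not r.has_ca:
                warnings.warn(
                    f"residue {r.name}{r.number} chain {r.chain} lacks CA; "
                    "flagged incomplete",
                    stacklevel=2,
                )
    return StructureModel(chains=chains), hets


# ------------------------------------------------------------ pocket triage


def residues_within(
    residues: list[Residue], points: np.ndarray, cutoff: float
) -> dict[tuple[str, int, str], float]:
    """Residues with any heavy atom within cutoff (inclusive) of any point;
    returns residue key -> minimum distance."""
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.size == 0:
        raise StructureError("empty point set")
    if cutoff <= 0:
        raise StructureError("cutoff must be positive")
    out: dict[tuple[str, int, str], float] = {}
    for r in residues:
        coords = r.heavy_coords()
        d = np.sqrt(((coords[:, None, :] - pts[None, :, :]) ** 2).sum(-1)).min()
        if d <= cutoff:
            out[r.key] = float(d)
    return out


def min_distance(coords: np.ndarray | None, points: np.ndarray) -> float | None:
    if coords is None:
        return None
    pts = np.atleast_2d(points)
    return float(
        np.sqrt(((coords[:, None, :] - pts[None, :, :]) ** 2).sum(-1)).min()
    )


@dataclass(frozen=True)
class OrientationResult:
    inward: bool
    glycine: bool = False


def sidechain_inward(
    residue: Residue, reaction_center: np.ndarray, mode: str = "centroid"
) -> OrientationResult:
    """Whether the sidechain points toward the reaction center.

    centroid mode: the sidechain heavy-atom centroid is strictly closer to
    the center than CA is. angle mode: the CA->centroid direction makes an
    angle < 90 degrees with CA->center. Glycine (no sidechain) is never
    inward and is flagged as such.
    """
    if not residue.has_ca:
        raise StructureError(
            f"residue {residue.name}{residue.number}: no CA atom"
        )
    sc = residue.sidechain_coords()
    if sc is None:
        return OrientationResult(inward=False, glycine=True)
    center = np.asarray(reaction_center, float).reshape(3)
    ca = residue.atom("CA").coord
    centroid = sc.mean(axis=0)
    if mode == "centroid":
        return OrientationResult(
            inward=bool(
                np.linalg.norm(centroid - center) < np.linalg.norm(ca - center)
            )
        )
    v1 = centroid - ca
    v2 = center - ca
    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
    if denom == 0:
        return OrientationResult(inward=False)
    return OrientationResult(inward=bool(np.dot(v1, v2) / denom > 0))


def select_contact_residues(
    structure: StructureModel,
    site: LigandSite,
    cfg: PocketConfig | None = None,
    chain: str | None = None,
) -> PocketResidueSet:
    """Triage residues into cofactor-coordinating / substrate-contact /
    pocket-lining-only / none (see module docstring)."""
    cfg = cfg or PocketConfig()
    residues = structure.residues(chain)
    within = residues_within(residues, site.substrate_atoms, cfg.substrate_cutoff)
    entries: list[ResidueTriage] = []
    for r in residues:
        sc = r.sidechain_coords()
        d_sub = min_distance(r.heavy_coords(), site.substrate_atoms)
        d_fe = min_distance(sc, site.fe_site)
        d_og = min_distance(sc, site.og_site)
        orient = sidechain_inward(r, site.reaction_center, cfg.orientation)
        inward = orient.inward
        if cfg.exclude_nonreactive and r.name in ("ALA", "GLY"):
            inward = False
        if r.key not in within:
            role = "none"
        elif not inward:
            role = "pocket_lining_only"
        elif (d_fe is not None and d_fe <= cfg.fe_cutoff) or (
            d_og is not None and d_og <= cfg.og_cutoff
        ):
            role = "cofactor_coordinating"
        else:
            role = "substrate_contact"
        entries.append(
            ResidueTriage(
                residue=r,
                min_substrate_dist=d_sub,
                min_fe_sidechain_dist=d_fe,
                min_og_sidechain_dist=d_og,
                orientation_pass=inward,
                glycine=orient.glycine,
                role=role,
            )
        )
    return PocketResidueSet(entries=entries)


# ------------------------------------------------- alignment <-> structure


@dataclass
class ResidueMap:
    """Bidirectional map between alignment columns, ungapped reference
    positions, and chain residues."""

    col_to_res: dict[int, tuple[str, int, str]]
    res_to_col: dict[tuple[str, int, str], int]
    pos_to_res: dict[int, tuple[str, int, str]]
    res_to_pos: dict[tuple[str, int, str], int]


def map_columns_to_residues(
    family: AlignedFamily,
    seq_id: str,
    structure: StructureModel,
    chain: str,
    min_identity: float = 0.95,
) -> ResidueMap:
    """Map the k-th non-gap column of seq_id to the k-th residue of the
    chain. The ungapped sequence and the chain sequence must agree at >=
    min_identity over their common length (and have equal lengths)."""
    aligned = family.aligned(seq_id)
    ungapped = aligned.replace(GAP, "")
    chain_res = structure.residues(chain)
    chain_seq = structure.chain_sequence(chain)
    if len(ungapped) != len(chain_seq):
        raise StructureError(
            f"{seq_id}: sequence length {len(ungapped)} != chain {chain!r} "
            f"length {len(chain_seq)}"
        )
    mismatches = [
        (k + 1, a, b)
        for k, (a, b) in enumerate(zip(ungapped, chain_seq))
        if a != b
    ]
    identity = 1 - len(mismatches) / len(ungapped)
    if identity < min_identity:
        k, a, b = mismatches[0]
        raise StructureError(
            f"{seq_id} vs chain {chain!r}: identity {identity:.2%} < "
            f"{min_identity:.0%}; first mismatch at position {k} ({a} vs {b})"
        )
    col_to_res: dict[int, tuple[str, int, str]] = {}
    pos_to_res: dict[int, tuple[str, int, str]] = {}
    pos = 0
    for col, ch in enumerate(aligned, start=1):
        if ch == GAP:
            continue
        key = chain_res[pos].key
        pos += 1
        col_to_res[col] = key
        pos_to_res[pos] = key
    return ResidueMap(
        col_to_res=col_to_res,
        res_to_col={v: k for k, v in col_to_res.items()},
        pos_to_res=pos_to_res,
        res_to_pos={v: k for k, v in pos_to_res.items()},
    )


def project_motifs(
    arch: MotifArchitecture, rmap: ResidueMap
) -> dict[tuple[str, int, str], str]:
    """Label each residue covered by a motif hit with that motif's id.

    Architecture hits are non-overlapping, so each residue gets at most one
    label; residues outside any hit are absent from the map.
    """
    out: dict[tuple[str, int, str], str] = {}
    for hit in arch.hits:
        for pos in range(hit.start, hit.end + 1):
            key = rmap.pos_to_res.get(pos)
            if key is not None:
                out[key] = hit.motif_id
    return out


def pocket_motif_composition(
    pocket: PocketResidueSet, labels: dict[tuple[str, int, str], str]
) -> dict[str, set[str]]:
    """Which motifs the pocket roles draw their residues from."""
    out: dict[str, set[str]] = {}
    for e in pocket.entries:
        if e.role in ("substrate_contact", "cofactor_coordinating"):
            mid = labels.get(e.residue.key)
            if mid is not None:
                out.setdefault(e.role, set()).add(mid)
    return out
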