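"""Pharmacophore-aware heterogeneous molecular graphs.

A molecule is represented as three coupled views:

* **atom view** (``alpha``) — atoms as nodes, chemical bonds as directed
  edge pairs;
* **pharm view** (``beta``) — BRICS fragments (pharmacophore carriers) as
  nodes, the cleaved BRICS bonds as directed *reaction* edges labelled with
  the ordered pair of BRICS link-rule classes;
* **junction view** (``gamma``) — atoms and fragments together, with
  membership edges linking each atom to the fragment that owns it.

All three views share a canonical 0-based atom ordering obtained by
round-tripping the input SMILES through RDKit canonicalization, so any
spelling of the same structure produces an identical graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import BRICS

logger = logging.getLogger(__name__)

__all__ = [
    "Molecule",
    "AtomRecord",
    "BondRecord",
    "FragmentAssignment",
    "ViewGraph",
    "HeteroMolGraph",
    "MoleculeParseError",
    "canonicalize_molecule",
    "brics_decompose",
    "featurize_atom",
    "featurize_bond",
    "build_atom_view",
    "build_pharm_view",
    "build_junction_view",
    "build_hetero_graph",
    "graph_to_json_record",
    "ATOM_FDIM",
    "BOND_FDIM",
    "FRAG_FDIM",
    "REACTION_FDIM",
    "JUNCTION_FDIM",
    "N_BRICS_RULES",
]


class MoleculeParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


# ---------------------------------------------------------------------------
# feature vocabularies (DMPNN-style standard)
# ---------------------------------------------------------------------------

_ELEMENTS = ["B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I"]
_DEGREES = [0, 1, 2, 3, 4, 5]
_CHARGES = [-2, -1, 0, 1, 2]
_CHIRAL_TAGS = ["CHI_UNSPECIFIED", "CHI_TETRAHEDRAL_CW", "CHI_TETRAHEDRAL_CCW"]
_NUM_HS = [0, 1, 2, 3, 4]
_HYBRIDIZATIONS = ["SP", "SP2", "SP3", "SP3D", "SP3D2"]
_BOND_ORDERS = ["SINGLE", "DOUBLE", "TRIPLE", "AROMATIC"]
_BOND_STEREO = ["STEREONONE", "STEREOANY", "STEREOZ", "STEREOE", "STEREOCIS", "STEREOTRANS"]

#: number of BRICS link-rule classes (labels 7a/7b collapse onto class 7)
N_BRICS_RULES = 16

ATOM_FDIM = (
    len(_ELEMENTS) + 1  # element one-hot + "other"
    + len(_DEGREES)
    + len(_CHARGES) + 1
    + len(_CHIRAL_TAGS) + 1
    + len(_NUM_HS)
    + len(_HYBRIDIZATIONS) + 1
    + 1  # aromatic flag
    + 1  # scaled mass
)
BOND_FDIM = len(_BOND_ORDERS) + 1 + 1 + len(_BOND_STEREO)  # order, conj, ring, stereo
FRAG_FDIM = ATOM_FDIM + 2  # summed atom features + [atom count, internal bond count]
REACTION_FDIM = 2 * N_BRICS_RULES
JUNCTION_FDIM = 1  # single constant type slot for membership edges


def _one_hot(value, choices, other: bool = True) -> list[float]:
    vec = [0.0] * (len(choices) + (1 if other else 0))
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        if other:
            vec[-1] = 1.0
    return vec


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomRecord:
    element: str
    degree: int
    formal_charge: int
    num_h: int
    hybridization: str
    aromatic: bool
    in_ring: bool
    mass: float
    chiral_tag: str = "CHI_UNSPECIFIED"


@dataclass(frozen=True)
class BondRecord:
    i: int
    j: int
    order: str
    conjugated: bool
    in_ring: bool
    stereo: str

    def __post_init__(self):
        if self.i >= self.j:
            raise ValueError("bond endpoints must satisfy i < j")


@dataclass(frozen=True)
class Molecule:
    canonical_smiles: str
    atoms: tuple[AtomRecord, ...]
    bonds: tuple[BondRecord, ...]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)


@dataclass(frozen=True)
class FragmentAssignment:
    """BRICS partition of a molecule's atoms.

    ``fragments`` is ordered by each fragment's smallest member-atom index;
    ``cleaved_bonds`` records ``(atom_i, atom_j, rule_i, rule_j)`` with the
    BRICS link-rule class (1..16) on each side of the broken bond.
    """

    fragments: tuple[frozenset[int], ...]
    atom_to_fragment: dict[int, int]
    cleaved_bonds: tuple[tuple[int, int, int, int], ...]

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


@dataclass
class ViewGraph:
    view_tag: str  # alpha | beta | gamma
    node_types: list[str]  # atom | pharm
    node_features: np.ndarray  # (N, Dv)
    directed_edges: list[tuple[int, int]]
    edge_types: list[str]  # bond | reaction | junction
    edge_features: np.ndarray  # (M, De)
    reverse_index: np.ndarray  # (M,) int, involution

    @property
    def n_nodes(self) -> int:
        return len(self.node_types)

    @property
    def n_edges(self) -> int:
        return len(self.directed_edges)


@dataclass
class HeteroMolGraph:
    molecule: Molecule
    assignment: FragmentAssignment
    atom_view: ViewGraph
    pharm_view: ViewGraph
    junction_view: ViewGraph

    def view(self, tag: str) -> ViewGraph:
        return {"alpha": self.atom_view, "beta": self.pharm_view, "gamma": self.junction_view}[tag]


# ---------------------------------------------------------------------------
# canonicalization
# ---------------------------------------------------------------------------


def _largest_component(mol: "Chem.Mol") -> "Chem.Mol":
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return mol
    logger.warning(
        "multi-component SMILES: keeping largest of %d components", len(frags)
    )
    # deterministic choice: most heavy atoms, canonical SMILES as tie-break
    return max(frags, key=lambda m: (m.GetNumAtoms(), Chem.MolToSmiles(m)))


def _rdkit_mol(smiles: str) -> "Chem.Mol":
    if not smiles:
        raise MoleculeParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonicalize_molecule(smiles: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule` in canonical atom order.

    Any spelling of the same structure yields an identical record. For
    multi-component inputs (dot-separated salts/solvents) only the largest
    component is kept, with a logged warning.
    """
    mol = _largest_component(_rdkit_mol(smiles))
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)  # re-parse: canonical atom order
    if mol is None:  # pragma: no cover - canonical SMILES always reparses
        raise MoleculeParseError(f"canonical SMILES failed to re-parse: {canonical!r}")

    atoms = tuple(
        AtomRecord(
            element=a.GetSymbol(),
            degree=a.GetDegree(),
            formal_charge=a.GetFormalCharge(),
            num_h=a.GetTotalNumHs(),
            hybridization=str(a.GetHybridization()),
            aromatic=a.GetIsAromatic(),
            in_ring=a.IsInRing(),
            mass=a.GetMass(),
            chiral_tag=str(a.GetChiralTag()),
        )
        for a in mol.GetAtoms()
    )
    bonds = tuple(
        BondRecord(
            i=min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
            j=max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
            order=str(b.GetBondType()),
            conjugated=b.GetIsConjugated(),
            in_ring=b.IsInRing(),
            stereo=str(b.GetStereo()),
        )
        for b in mol.GetBonds()
    )
    return Molecule(canonical_smiles=canonical, atoms=atoms, bonds=bonds)


# ---------------------------------------------------------------------------
# BRICS decomposition
# ---------------------------------------------------------------------------


def _brics_rule_class(label: str) -> int:
    """Map an RDKit BRICS link label ('1'..'16', '7a', '7b') to its class 1..16."""
    return int(label.rstrip("ab"))


def brics_decompose(mol: Molecule) -> FragmentAssignment:
    """Partition a molecule's atoms by breaking all BRICS-cleavable bonds at once.

    A molecule with no cleavable bond yields a single fragment and no
    cleaved-bond records.
    """
    rd = _rdkit_mol(mol.canonical_smiles)
    seen: set[tuple[int, int]] = set()
    cleaved: list[tuple[int, int, int, int]] = []
    for (i, j), (li, lj) in BRICS.FindBRICSBonds(rd):
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        cleaved.append((i, j, _brics_rule_class(li), _brics_rule_class(lj)))

    # connected components of the bond graph minus the cleaved bonds
    parent = list(range(mol.n_atoms))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for b in mol.bonds:
        if (b.i, b.j) in seen:
            continue
        ri, rj = find(b.i), find(b.j)
        if ri != rj:
            parent[ri] = rj

    groups: dict[int, set[int]] = {}
    for a in range(mol.n_atoms):
        groups.setdefault(find(a), set()).add(a)
    fragments = tuple(
        frozenset(g) for g in sorted(groups.values(), key=min)
    )
    atom_to_fragment = {a: fi for fi, frag in enumerate(fragments) for a in frag}
    return FragmentAssignment(
        fragments=fragments,
        atom_to_fragment=atom_to_fragment,
        cleaved_bonds=tuple(cleaved),
    )


# ---------------------------------------------------------------------------
# featurizers
# ---------------------------------------------------------------------------


def featurize_atom(atom: AtomRecord) -> np.ndarray:
    """Fixed-length atom feature vector (length :data:`ATOM_FDIM`)."""
    vec = (
        _one_hot(atom.element, _ELEMENTS)
        + _one_hot(atom.degree, _DEGREES, other=False)
        + _one_hot(atom.formal_charge, _CHARGES)
        + _one_hot(atom.chiral_tag, _CHIRAL_TAGS)
        + _one_hot(atom.num_h, _NUM_HS, other=False)
        + _one_hot(atom.hybridization, _HYBRIDIZATIONS)
        + [1.0 if atom.aromatic else 0.0]
        + [atom.mass / 100.0]
    )
    return np.asarray(vec, dtype=np.float64)


def featurize_bond(bond: BondRecord) -> np.ndarray:
    """Fixed-length bond feature vector (length :data:`BOND_FDIM`).

    Both directed edges of one bond share this vector.
    """
    vec = (
        _one_hot(bond.order, _BOND_ORDERS, other=False)
        + [1.0 if bond.conjugated else 0.0]
        + [1.0 if bond.in_ring else 0.0]
        + _one_hot(bond.stereo, _BOND_STEREO, other=False)
    )
    return np.asarray(vec, dtype=np.float64)


# ---------------------------------------------------------------------------
# view builders
# ---------------------------------------------------------------------------


def _reverse_pairs(n_edges: int) -> np.ndarray:
    idx = np.arange(n_edges)
    rev = idx ^ 1  # edges are laid out as (2k, 2k+1) directed pairs
    return rev


def build_atom_view(mol: Molecule) -> ViewGraph:
    """Atom-level view: every bond contributes two directed ``bond`` edges."""
    node_features = (
        np.stack([featurize_atom(a) for a in mol.atoms])
        if mol.n_atoms
        else np.zeros((0, ATOM_FDIM))
    )
    edges: list[tuple[int, int]] = []
    efeats: list[np.ndarray] = []
    for b in mol.bonds:
        f = featurize_bond(b)
        edges.append((b.i, b.j))
        edges.append((b.j, b.i))
        efeats.append(f)
        efeats.append(f)
    return ViewGraph(
        view_tag="alpha",
        node_types=["atom"] * mol.n_atoms,
        node_features=node_features,
        directed_edges=edges,
        edge_types=["bond"] * len(edges),
        edge_features=np.stack(efeats) if efeats else np.zeros((0, BOND_FDIM)),
        reverse_index=_reverse_pairs(len(edges)),
    )


def _fragment_features(mol: Molecule, frags: FragmentAssignment) -> np.ndarray:
    atom_feats = np.stack([featurize_atom(a) for a in mol.atoms])
    rows = []
    for frag in frags.fragments:
        members = sorted(frag)
        internal_bonds = sum(1 for b in mol.bonds if b.i in frag and b.j in frag)
        summed = atom_feats[members].sum(axis=0)
        rows.append(np.concatenate([summed, [float(len(members)), float(internal_bonds)]]))
    return np.stack(rows)


def _rule_one_hot(rule: int) -> np.ndarray:
    vec = np.zeros(N_BRICS_RULES)
    vec[rule - 1] = 1.0
    return vec


def build_pharm_view(mol: Molecule, frags: FragmentAssignment) -> ViewGraph:
    """Pharm-level view: fragments as nodes, cleaved BRICS bonds as reaction edges.

    A reaction edge's feature is the ordered concatenation of the source-side
    and target-side BRICS rule one-hots; the reverse edge swaps the halves.
    """
    edges: list[tuple[int, int]] = []
    efeats: list[np.ndarray] = []
    for (ai, aj, ri, rj) in frags.cleaved_bonds:
        fa, fb = frags.atom_to_fragment[ai], frags.atom_to_fragment[aj]
        edges.append((fa, fb))
        efeats.append(np.concatenate([_rule_one_hot(ri), _rule_one_hot(rj)]))
        edges.append((fb, fa))
        efeats.append(np.concatenate([_rule_one_hot(rj), _rule_one_hot(ri)]))
    return ViewGraph(
        view_tag="beta",
        node_types=["pharm"] * frags.n_fragments,
        node_features=_fragment_features(mol, frags),
        directed_edges=edges,
        edge_types=["reaction"] * len(edges),
        edge_features=np.stack(efeats) if efeats else np.zeros((0, REACTION_FDIM)),
        reverse_index=_reverse_pairs(len(edges)),
    )


def build_junction_view(
    mol: Molecule,
    frags: FragmentAssignment,
    membership: str = "all",
) -> ViewGraph:
    """Junction view: atoms then fragments as nodes, membership edges between them.

    ``membership="all"`` links every atom to its owning fragment (default);
    ``membership="cleavage"`` restricts to atoms incident to a cleaved bond.
    Node features are the atom/fragment vectors zero-padded to a common width.
    """
    if membership not in ("all", "cleavage"):
        raise ValueError(f"membership must be 'all' or 'cleavage', got {membership!r}")
    n_atoms = mol.n_atoms
    width = max(ATOM_FDIM, FRAG_FDIM)
    atom_feats = np.zeros((n_atoms, width))
    for i, a in enumerate(mol.atoms):
        atom_feats[i, :ATOM_FDIM] = featurize_atom(a)
    frag_feats = np.zeros((frags.n_fragments, width))
    frag_feats[:, :FRAG_FDIM] = _fragment_features(mol, frags)

    if membership == "all":
        linked_atoms = range(n_atoms)
    else:
        linked_atoms = sorted({a for (ai, aj, *_r) in frags.cleaved_bonds for a in (ai, aj)})

    edges: list[tuple[int, int]] = []
    for a in linked_atoms:
        f = n_atoms + frags.atom_to_fragment[a]
        edges.append((a, f))
        edges.append((f, a))
    return ViewGraph(
        view_tag="gamma",
        node_types=["atom"] * n_atoms + ["pharm"] * frags.n_fragments,
        node_features=np.vstack([atom_feats, frag_feats]),
        directed_edges=edges,
        edge_types=["junction"] * len(edges),
        edge_features=np.ones((len(edges), JUNCTION_FDIM)),
        reverse_index=_reverse_pairs(len(edges)),
    )


def build_hetero_graph(smiles: str, membership: str = "all") -> HeteroMolGraph:
    """Full pipeline: SMILES -> canonical molecule -> BRICS -> three views."""
    mol = canonicalize_molecule(smiles)
    frags = brics_decompose(mol)
    return HeteroMolGraph(
        molecule=mol,
        assignment=frags,
        atom_view=build_atom_view(mol),
        pharm_view=build_pharm_view(mol, frags),
        junction_view=build_junction_view(mol, frags, membership=membership),
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def graph_to_json_record(graph: HeteroMolGraph) -> dict:
    """One-molecule JSON record for the JSONL interoperability export."""
    record: dict = {"smiles": graph.molecule.canonical_smiles}
    for tag in ("alpha", "beta", "gamma"):
        view = graph.view(tag)
        record[tag] = {
            "nodes": [
                {"type": t, "features": row.tolist()}
                for t, row in zip(view.node_types, view.node_features)
            ],
            "edges": [
                {"src": s, "dst": d, "type": t, "features": row.tolist()}
                for (s, d), t, row in zip(
                    view.directed_edges, view.edge_types, view.edge_features
                )
            ],
        }
    return record
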