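"""Molecular graphs and electrotopological-state atom typing.

Structures enter as a small organic SMILES subset — C, N, O, Cl heavy atoms
with implicit hydrogens; no stereochemistry, isotopes, or formal charges —
or as MOL/SDF V2000 blocks. RDKit does the actual SMILES/molblock parsing
and aromaticity perception; this module wraps it in strict validation so
that unsupported input is rejected with the offending token named rather
than silently reinterpreted, and converts the result into a plain
:class:`MolecularGraph` that the descriptor engine consumes.

E-state atom typing follows the Kier–Hall naming scheme used by descriptor
programs in this field: each heavy atom gets a label built from its bond
types (``s`` single, ``d`` double, ``t`` triple, ``a`` aromatic), element
symbol and hydrogen count — e.g. ``sCH3`` for a methyl carbon, ``ssO`` for
an ether oxygen, ``dsCH`` for a =CH- carbon, ``aaCH`` for an aromatic CH.
"""

from __future__ import annotations

import json
import re
from collections import deque
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # we raise our own errors; keep stderr clean

AROMATIC = "aromatic"

#: heavy elements accepted anywhere in this toolkit
SUPPORTED_ELEMENTS = frozenset({"C", "N", "O", "Cl"})

#: standard valences used for implicit-hydrogen consistency checks
STANDARD_VALENCE = {"C": 4, "N": 3, "O": 2, "Cl": 1}


class ParseError(ValueError):
    """Raised when a structure cannot be parsed under the supported subset."""


@dataclass(frozen=True)
class Atom:
    element: str
    aromatic: bool = False
    formal_charge: int = 0
    n_h: int = 0


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: object  # 1 | 2 | 3 | AROMATIC

    def numeric_order(self) -> float:
        """Bond order for valence arithmetic (aromatic counts 1.5)."""
        return 1.5 if self.order == AROMATIC else float(self.order)


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed molecular graph.

    Heavy atoms carry implicit-hydrogen counts; bonds carry order 1/2/3 or
    the aromatic flag. All structure-derived descriptors are computed from
    this representation.
    """

    atoms: list[Atom]
    bonds: list[Bond]
    name: str = ""

    # -- basic accessors ---------------------------------------------------
    @property
    def n_heavy(self) -> int:
        return len(self.atoms)

    @property
    def n_hydrogens(self) -> int:
        return sum(a.n_h for a in self.atoms)

    @property
    def total_atom_count(self) -> int:
        """Heavy atoms plus implicit hydrogens."""
        return self.n_heavy + self.n_hydrogens

    def neighbors(self, i: int) -> list[tuple[int, object]]:
        """(neighbor index, bond order) pairs of atom ``i``."""
        out = []
        for b in self.bonds:
            if b.i == i:
                out.append((b.j, b.order))
            elif b.j == i:
                out.append((b.i, b.order))
        return out

    def is_connected(self) -> bool:
        if self.n_heavy <= 1:
            return True
        seen = {0}
        queue = deque([0])
        adj = self._adjacency()
        while queue:
            for j in adj[queue.popleft()]:
                if j not in seen:
                    seen.add(j)
                    queue.append(j)
        return len(seen) == self.n_heavy

    def _adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        return adj

    def distances(self) -> list[list[int]]:
        """All-pairs topological distances in bond counts (BFS per atom)."""
        n = self.n_heavy
        adj = self._adjacency()
        dist = [[-1] * n for _ in range(n)]
        for s in range(n):
            dist[s][s] = 0
            queue = deque([s])
            while queue:
                u = queue.popleft()
                for v in adj[u]:
                    if dist[s][v] < 0:
                        dist[s][v] = dist[s][u] + 1
                        queue.append(v)
        return dist

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        n = self.n_heavy
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ParseError(f"bond ({b.i},{b.j}) references missing atom")
            if b.i == b.j:
                raise ParseError(f"self-bond on atom {b.i}")
        for idx, a in enumerate(self.atoms):
            if a.element not in SUPPORTED_ELEMENTS:
                raise ParseError(f"unsupported element {a.element!r} at atom {idx}")
            if a.formal_charge != 0:
                raise ParseError(f"non-zero formal charge on atom {idx}")
            if a.n_h < 0:
                raise ParseError(f"negative hydrogen count on atom {idx}")
            order_sum = sum(
                b.numeric_order() for b in self.bonds if idx in (b.i, b.j)
            )
            valence = round(order_sum) + a.n_h
            if valence != STANDARD_VALENCE[a.element]:
                raise ParseError(
                    f"atom {idx} ({a.element}) has valence {valence}, "
                    f"expected {STANDARD_VALENCE[a.element]}"
                )
        if not self.is_connected():
            raise ParseError("graph is disconnected (multi-fragment input)")

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        """Canonical adjacency JSON, for debugging and round-trip tests."""
        payload = {
            "name": self.name,
            "atoms": [
                {
                    "element": a.element,
                    "aromatic": a.aromatic,
                    "charge": a.formal_charge,
                    "h": a.n_h,
                }
                for a in self.atoms
            ],
            "bonds": [[b.i, b.j, b.order] for b in self.bonds],
        }
        return json.dumps(payload, indent=None, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MolecularGraph":
        payload = json.loads(text)
        g = cls(
            atoms=[
                Atom(a["element"], a["aromatic"], a["charge"], a["h"])
                for a in payload["atoms"]
            ],
            bonds=[Bond(i, j, order) for i, j, order in payload["bonds"]],
            name=payload.get("name", ""),
        )
        g.validate()
        return g


# ---------------------------------------------------------------------------
# parsing


_SMILES_TOKEN = re.compile(r"Cl|[CNO]|[cno]|[()=#]|[0-9]")


def _scan_smiles_tokens(text: str) -> None:
    """Reject any token outside the supported SMILES subset, by position."""
    pos = 0
    while pos < len(text):
        m = _SMILES_TOKEN.match(text, pos)
        if m is None:
            raise ParseError(
                f"unsupported token {text[pos]!r} at position {pos} in SMILES {text!r}"
            )
        pos = m.end()


def _graph_from_rdkit(mol: Chem.Mol, name: str) -> MolecularGraph:
    if mol.GetNumConformers():  # descriptors here are 2-D; drop coordinates
        mol.RemoveAllConformers()
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in SUPPORTED_ELEMENTS:
            raise ParseError(f"unsupported element {sym!r}")
        if atom.GetFormalCharge() != 0:
            raise ParseError(f"non-zero formal charge on {sym} atom")
        if atom.GetIsotope() != 0:
            raise ParseError(f"isotope specification on {sym} atom")
        if atom.GetNumRadicalElectrons() != 0:
            raise ParseError(f"radical electrons on {sym} atom")
    order_map = {
        Chem.BondType.SINGLE: 1,
        Chem.BondType.DOUBLE: 2,
        Chem.BondType.TRIPLE: 3,
        Chem.BondType.AROMATIC: AROMATIC,
    }
    atoms = [
        Atom(
            element=a.GetSymbol(),
            aromatic=a.GetIsAromatic(),
            formal_charge=0,
            n_h=a.GetTotalNumHs(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        if b.GetBondType() not in order_map:
            raise ParseError(f"unsupported bond type {b.GetBondType()}")
        bonds.append(
            Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order_map[b.GetBondType()])
        )
    g = MolecularGraph(atoms=atoms, bonds=bonds, name=name)
    g.validate()
    return g


def parse_smiles(text: str, name: str = "") -> MolecularGraph:
    """Parse a SMILES string from the supported organic subset.

    Aromatic (lowercase) input is accepted directly; Kekulé input of
    benzene-like rings is aromatized during perception.
    """
    text = text.strip()
    if not text:
        raise ParseError("empty SMILES string")
    _scan_smiles_tokens(text)
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise ParseError(f"invalid SMILES syntax: {text!r}")
    return _graph_from_rdkit(mol, name)


def parse_molblock(text: str, name: str = "") -> MolecularGraph:
    """Parse a MOL/SDF V2000 connection table."""
    mol = Chem.MolFromMolBlock(text, sanitize=True, removeHs=True)
    if mol is None:
        raise ParseError("invalid or unsupported MOL/SDF block")
    if not name:
        name = (text.splitlines() or [""])[0].strip()
    return _graph_from_rdkit(mol, name)


def parse_structure(text: str, name: str = "") -> MolecularGraph:
    """Parse either a SMILES string or a MOL/SDF V2000 block.

    Molblocks are recognized by the ``V2000`` marker; anything else is
    treated as SMILES.
    """
    if "V2000" in text:
        return parse_molblock(text, name)
    return parse_smiles(text, name)


def read_smiles_file(path) -> list[MolecularGraph]:
    """Read a SMILES file: one molecule per line, optional name column."""
    graphs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            try:
                graphs.append(parse_smiles(smiles, name))
            except ParseError as err:
                raise ParseError(f"line {lineno}: {err}") from err
    if not graphs:
        raise ParseError(f"no molecules found in {path}")
    return graphs


def read_sdf(path) -> list[MolecularGraph]:
    """Read an SDF file of V2000 records."""
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    graphs = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise ParseError(f"record {idx}: invalid molblock")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{idx + 1}"
        graphs.append(_graph_from_rdkit(mol, name))
    if not graphs:
        raise ParseError(f"no molecules found in {path}")
    return graphs


# ---------------------------------------------------------------------------
# E-state atom typing

#: label assembly order for bond symbols: double, triple, aromatic, single —
#: reproduces the conventional names dsCH, tsC, aasC, aaCH, dssC, ...
_BOND_SYMBOL_PRIORITY = {"d": 0, "t": 1, "a": 2, "s": 3}

#: atom environments with a conventional E-state name; anything else → "other"
KNOWN_TYPES = frozenset(
    {
        # carbon
        "sCH3", "ssCH2", "sssCH", "ssssC",
        "dCH2", "dsCH", "dssC", "ddC",
        "tCH", "tsC",
        "aaCH", "aasC", "aaaC",
        # nitrogen
        "sNH2", "ssNH", "sssN", "dNH", "dsN", "tN", "aaN",
        # oxygen
        "sOH", "dO", "ssO", "aaO",
        # chlorine
        "sCl",
    }
)


@dataclass(frozen=True)
class EStateTyping:
    """Per-heavy-atom E-state type labels plus hydrogen associations.

    ``labels[i]`` is the type of heavy atom ``i``; ``hydrogens`` holds one
    ``(parent index, parent label)`` entry per implicit hydrogen.
    """

    labels: tuple[str, ...]
    hydrogens: tuple[tuple[int, str], ...] = field(default_factory=tuple)


def estate_type_label(g: MolecularGraph, i: int) -> str:
    """Raw bond-symbol + element + H-count label for heavy atom ``i``."""
    a = g.atoms[i]
    symbols = []
    for _, order in g.neighbors(i):
        if order == AROMATIC:
            symbols.append("a")
        elif order == 1:
            symbols.append("s")
        elif order == 2:
            symbols.append("d")
        elif order == 3:
            symbols.append("t")
    symbols.sort(key=_BOND_SYMBOL_PRIORITY.__getitem__)
    h_suffix = "" if a.n_h == 0 else ("H" if a.n_h == 1 else f"H{a.n_h}")
    return "".join(symbols) + a.element + h_suffix


def assign_estate_types(g: MolecularGraph) -> EStateTyping:
    """Assign one E-state type label per heavy atom.

    Labels are a pure function of element, bond orders and hydrogen count,
    hence invariant under atom reordering. Environments without a
    conventional name (e.g. the isolated carbon of methane) are typed
    ``"other"`` — they still count toward nHeavyAtom but contribute to no
    named E-state sum.
    """
    labels = []
    for i in range(g.n_heavy):
        raw = estate_type_label(g, i)
        labels.append(raw if raw in KNOWN_TYPES else "other")
    hydrogens = []
    for i, a in enumerate(g.atoms):
        hydrogens.extend((i, labels[i]) for _ in range(a.n_h))
    return EStateTyping(labels=tuple(labels), hydrogens=tuple(hydrogens))
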