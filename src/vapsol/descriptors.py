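"""The 15-descriptor block: E-state sums, counts, and quantum-chemical terms.

The structure-derived part rests on Kier–Hall electrotopological states.
Each heavy atom gets an intrinsic state

    I = ((2/N)^2 * dv + 1) / d

with ``dv = Zv - h`` the valence electrons minus bonded hydrogens, ``d`` the
heavy-atom sigma degree and ``N`` the principal quantum number, and an
E-state value

    S_i = I_i + sum_j (I_i - I_j) / (r_ij + 1)^2

where ``r_ij`` is the topological distance in bonds. Named descriptor sums
(SsOH, SssO, SsCH3, SsNH2, SssCH2) aggregate S over atoms of one type;
SHBa sums heavy-atom S over hydrogen-bond acceptors (N and O); SHBd and
SHdsCH sum *hydrogen* E-states over H on N/O and on =CH- carbons.

Hydrogen E-states use the same intrinsic-state formula applied to an
explicit hydrogen (dv = d = 1, N = 1, hence I_H = 5) perturbed against the
heavy-atom intrinsic states at hydrogen-augmented distances, while the
heavy-atom S values stay on the hydrogen-suppressed graph — the standard
convention, kept so the heavy-atom values agree with independent E-state
implementations.

The quantum-chemical block is taken from user-supplied electronic-structure
output: atomization energy AE passes through unchanged, QM is one third of
the trace of the second-moment-of-charge tensor, chemical hardness
``eta = E_LUMO - E_HOMO`` and Mulliken-style electronegativity
``chi = -(E_LUMO + E_HOMO)/2``. Units are whatever the quantum code emitted;
nothing is converted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .molgraph import MolecularGraph, EStateTyping, assign_estate_types

#: canonical descriptor order, identical everywhere (matrices, CSV, models)
DESCRIPTOR_ORDER = (
    "AE",
    "QM",
    "nAromBond",
    "nHeavyAtom",
    "nAcid",
    "SsOH",
    "SssO",
    "SsCH3",
    "SsNH2",
    "SHBa",
    "SHdsCH",
    "SssCH2",
    "SHBd",
    "eta",
    "chi",
)

#: the eight named E-state sums among the fifteen
ESTATE_SUM_NAMES = ("SsOH", "SssO", "SsCH3", "SsNH2", "SHBa", "SHdsCH", "SssCH2", "SHBd")

_VALENCE_ELECTRONS = {"C": 4, "N": 5, "O": 6, "Cl": 7}
_PRINCIPAL_QUANTUM = {"C": 2, "N": 2, "O": 2, "Cl": 3}

#: hydrogen intrinsic state: ((2/1)^2 * 1 + 1) / 1
HYDROGEN_INTRINSIC_STATE = 5.0


class DescriptorError(ValueError):
    pass


@dataclass(frozen=True)
class DescriptorVector:
    """The fifteen selected descriptors in canonical order.

    Quantum entries (AE, QM, eta, chi) are NaN when no quantum input was
    supplied for the molecule.
    """

    AE: float
    QM: float
    nAromBond: int
    nHeavyAtom: int
    nAcid: int
    SsOH: float
    SssO: float
    SsCH3: float
    SsNH2: float
    SHBa: float
    SHdsCH: float
    SssCH2: float
    SHBd: float
    eta: float
    chi: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in DESCRIPTOR_ORDER}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in DESCRIPTOR_ORDER], dtype=float)

    @classmethod
    def from_mapping(cls, mapping) -> "DescriptorVector":
        missing = [n for n in DESCRIPTOR_ORDER if n not in mapping]
        if missing:
            raise DescriptorError(f"missing descriptor fields: {missing}")
        return cls(**{n: mapping[n] for n in DESCRIPTOR_ORDER})


assert tuple(f.name for f in fields(DescriptorVector)) == DESCRIPTOR_ORDER


@dataclass(frozen=True)
class QuantumInput:
    """Per-molecule electronic-structure quantities.

    Orbital energies and the diagonal second-moment elements are in the
    units of the producing quantum code; they are stored, never converted.
    """

    EHOMO: float
    ELUMO: float
    Qxx: float
    Qyy: float
    Qzz: float
    AE: float

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise DescriptorError(f"quantum input field {f.name!r} is missing")
        if self.ELUMO < self.EHOMO:
            warnings.warn(
                f"ELUMO ({self.ELUMO}) below EHOMO ({self.EHOMO}); "
                "check orbital energy ordering",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# intrinsic states and E-state values


def intrinsic_state(
    element: str, n_h: int, degree: int, *, single_atom: bool = False
) -> float:
    """Kier–Hall intrinsic state of a heavy atom.

    ``degree`` is the heavy-atom sigma degree (number of heavy neighbors).
    A degree of zero is only meaningful for a single-heavy-atom molecule
    (methane-like), where the conventional ``d = 1`` is substituted; pass
    ``single_atom=True`` to allow it.
    """
    if element not in _VALENCE_ELECTRONS:
        raise DescriptorError(f"unsupported element {element!r}")
    dv = _VALENCE_ELECTRONS[element] - n_h
    if dv < 0:
        raise DescriptorError(f"negative valence delta for {element} with {n_h} H")
    if degree < 1:
        if not single_atom:
            raise DescriptorError(
                "degree 0 is only defined for single-heavy-atom molecules"
            )
        degree = 1
    n = _PRINCIPAL_QUANTUM[element]
    return ((2.0 / n) ** 2 * dv + 1.0) / degree


def intrinsic_states(g: MolecularGraph) -> np.ndarray:
    """Intrinsic state of every heavy atom of ``g``."""
    single = g.n_heavy == 1
    out = np.empty(g.n_heavy)
    for i, atom in enumerate(g.atoms):
        out[i] = intrinsic_state(
            atom.element, atom.n_h, len(g.neighbors(i)), single_atom=single
        )
    return out


def estate_values(g: MolecularGraph) -> np.ndarray:
    """Per-heavy-atom E-state values S on the hydrogen-suppressed graph.

    The pairwise perturbation terms are antisymmetric, so the sum of S over
    the molecule equals the sum of intrinsic states.
    """
    if not g.is_connected():
        raise DescriptorError("E-states are undefined for a disconnected graph")
    I = intrinsic_states(g)
    n = g.n_heavy
    if n == 1:
        return I.copy()
    dist = np.asarray(g.distances(), dtype=float)
    diff = I[:, None] - I[None, :]
    pert = diff / (dist + 1.0) ** 2
    np.fill_diagonal(pert, 0.0)
    return I + pert.sum(axis=1)


def hydrogen_estate_values(g: MolecularGraph) -> list[tuple[int, float]]:
    """E-state values of the implicit hydrogens, as (parent index, S_H).

    Every hydrogen carries the intrinsic state I_H = 5 and is perturbed by
    the heavy atoms at hydrogen-augmented distances (1 bond to its parent,
    parent distance + 1 to everything else).
    """
    I = intrinsic_states(g)
    dist = np.asarray(g.distances(), dtype=float)
    out = []
    for i, atom in enumerate(g.atoms):
        if atom.n_h == 0:
            continue
        d_h = dist[i] + 1.0  # H sits one bond beyond its parent
        s_h = HYDROGEN_INTRINSIC_STATE + np.sum(
            (HYDROGEN_INTRINSIC_STATE - I) / (d_h + 1.0) ** 2
        )
        out.extend((i, float(s_h)) for _ in range(atom.n_h))
    return out


# ---------------------------------------------------------------------------
# descriptor sums and counts


def _is_acceptor(g: MolecularGraph, i: int) -> bool:
    # every neutral N or O in the supported subset keeps at least one lone pair
    return g.atoms[i].element in ("N", "O")


def estate_sums(
    g: MolecularGraph, typing: EStateTyping | None = None
) -> dict[str, float]:
    """The eight named E-state sum descriptors; absent types contribute 0."""
    if typing is None:
        typing = assign_estate_types(g)
    S = estate_values(g)
    sums = dict.fromkeys(ESTATE_SUM_NAMES, 0.0)
    by_type = {"sOH": "SsOH", "ssO": "SssO", "sCH3": "SsCH3",
               "sNH2": "SsNH2", "ssCH2": "SssCH2"}
    for i, label in enumerate(typing.labels):
        if label in by_type:
            sums[by_type[label]] += float(S[i])
        if _is_acceptor(g, i):
            sums["SHBa"] += float(S[i])
    for parent, s_h in hydrogen_estate_values(g):
        if g.atoms[parent].element in ("N", "O"):
            sums["SHBd"] += s_h
        if typing.labels[parent] == "dsCH":
            sums["SHdsCH"] += s_h
    return sums


def count_acid_groups(g: MolecularGraph) -> int:
    """Carboxylic-acid count: carbons bearing both =O and -OH."""
    n_acid = 0
    for i, atom in enumerate(g.atoms):
        if atom.element != "C":
            continue
        has_carbonyl = False
        has_hydroxyl = False
        for j, order in g.neighbors(i):
            if g.atoms[j].element != "O":
                continue
            if order == 2:
                has_carbonyl = True
            elif order == 1 and g.atoms[j].n_h == 1:
                has_hydroxyl = True
        if has_carbonyl and has_hydroxyl:
            n_acid += 1
    return n_acid


def count_descriptors(g: MolecularGraph) -> dict[str, int]:
    from .molgraph import AROMATIC

    return {
        "nAromBond": sum(1 for b in g.bonds if b.order == AROMATIC),
        "nHeavyAtom": g.n_heavy,
        "nAcid": count_acid_groups(g),
    }


def quantum_block(q: QuantumInput) -> dict[str, float]:
    """AE pass-through, QM = tr(Q)/3, eta = gap, chi = -(mean frontier energy)."""
    return {
        "AE": q.AE,
        "QM": (q.Qxx + q.Qyy + q.Qzz) / 3.0,
        "eta": q.ELUMO - q.EHOMO,
        "chi": -(q.ELUMO + q.EHOMO) / 2.0,
    }


def compute_descriptors(
    g: MolecularGraph, quantum: QuantumInput | None = None
) -> DescriptorVector:
    """Full 15-entry descriptor vector for one molecule."""
    values: dict[str, float] = dict.fromkeys(("AE", "QM", "eta", "chi"), float("nan"))
    if quantum is not None:
        values.update(quantum_block(quantum))
    values.update(count_descriptors(g))
    values.update(estate_sums(g))
    return DescriptorVector.from_mapping(values)


# ---------------------------------------------------------------------------
# tables


def descriptor_table(
    graphs: list[MolecularGraph], quantum_table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Descriptor CSV table: one row per molecule, name + canonical columns.

    ``quantum_table`` is joined by molecule name and must carry columns
    name, EHOMO, ELUMO, Qxx, Qyy, Qzz, AE.
    """
    qmap: dict[str, QuantumInput] = {}
    if quantum_table is not None:
        required = ["name", "EHOMO", "ELUMO", "Qxx", "Qyy", "Qzz", "AE"]
        missing = [c for c in required if c not in quantum_table.columns]
        if missing:
            raise DescriptorError(f"quantum table lacks columns: {missing}")
        for _, row in quantum_table.iterrows():
            qmap[str(row["name"])] = QuantumInput(
                EHOMO=float(row["EHOMO"]),
                ELUMO=float(row["ELUMO"]),
                Qxx=float(row["Qxx"]),
                Qyy=float(row["Qyy"]),
                Qzz=float(row["Qzz"]),
                AE=float(row["AE"]),
            )
    rows = []
    for g in graphs:
        vec = compute_descriptors(g, qmap.get(g.name))
        rows.append({"name": g.name, **vec.as_dict()})
    return pd.DataFrame(rows, columns=["name", *DESCRIPTOR_ORDER])
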