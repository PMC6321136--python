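"""3D conformers -> typed pharmacophore points -> canonical triplet keys.

Every heavy atom (or aromatic ring centroid) of a conformer may become one
or more potential pharmacophore points (PPPs) of six types: hydrogen-bond
donor, hydrogen-bond acceptor, positively charged / protonatable,
negatively charged / deprotonatable, aromatic, lipophilic.  All unordered
triples of PPPs within a distance cutoff are converted into canonical
(type, binned-distance) keys; the union of per-conformer key sets is the
compound's modal fingerprint.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from pharmfish.errors import StructureError

# Type codes in canonical sort order.
PPP_TYPES = ("donor", "acceptor", "positive", "negative", "aromatic", "lipophilic")
_TYPE_CODE = {"donor": "D", "acceptor": "A", "positive": "P",
              "negative": "N", "aromatic": "R", "lipophilic": "L"}
_CODE_TYPE = {v: k for k, v in _TYPE_CODE.items()}
_TYPE_ORDER = {t: i for i, t in enumerate(PPP_TYPES)}

MAX_CONFORMERS = 10


@dataclass(frozen=True)
class Conformer:
    """A single 3D conformation of a compound.

    atoms: sequence of (element symbol, x, y, z) with coordinates in Angstrom.
    bonds: sequence of (i, j, order); order 1/2/3 or 12 for aromatic.
    charges: optional per-atom formal charges (defaults to all zero).
    """

    compound_id: str
    atoms: tuple
    bonds: tuple
    conformer_index: int = 0
    charges: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(tuple(a) for a in self.atoms))
        object.__setattr__(self, "bonds", tuple(tuple(b) for b in self.bonds))
        object.__setattr__(self, "charges", tuple(self.charges))
        n = len(self.atoms)
        for sym, x, y, z in self.atoms:
            if not all(math.isfinite(v) for v in (x, y, z)):
                raise StructureError(self.compound_id, "non-finite coordinate")
        seen_bonds = set()
        for i, j, _order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise StructureError(self.compound_id, f"invalid bond ({i},{j})")
            pair = (min(i, j), max(i, j))
            if pair in seen_bonds:
                raise StructureError(self.compound_id, f"duplicate bond {pair}")
            seen_bonds.add(pair)
        if self.charges and len(self.charges) != n:
            raise StructureError(self.compound_id, "charges length != atom count")


@dataclass(frozen=True)
class PharmacophorePoint:
    """One typed feature point (a PPP) of a conformer."""

    position: tuple
    ppp_type: str
    source_atoms: frozenset

    def __post_init__(self):
        if self.ppp_type not in PPP_TYPES:
            raise ValueError(f"unknown PPP type {self.ppp_type!r}")
        object.__setattr__(self, "position", tuple(float(v) for v in self.position))
        object.__setattr__(self, "source_atoms", frozenset(self.source_atoms))


class TripletKey(tuple):
    """Canonical key for a 3-PPP triplet.

    Stored as a sorted tuple of three (type_order, bin) pairs, where each
    pair carries a point's type together with the distance bin of the edge
    OPPOSITE that point.  Because any relabelling of the three points is a
    permutation of the pairs, sorting them yields a canonical form that is
    invariant under all 6 rotations/reflections of the triangle.
    """

    __slots__ = ()

    def __new__(cls, pairs: Iterable) -> "TripletKey":
        pairs = tuple(sorted((int(o), int(b)) for o, b in pairs))
        if len(pairs) != 3:
            raise ValueError("a triplet key needs exactly 3 (type, bin) pairs")
        return super().__new__(cls, pairs)

    @classmethod
    def from_types_bins(cls, types: Sequence[str], bins: Sequence[int]) -> "TripletKey":
        return cls((_TYPE_ORDER[t], b) for t, b in zip(types, bins, strict=True))

    def serialize(self) -> str:
        codes = "".join(_TYPE_CODE[PPP_TYPES[o]] for o, _ in self)
        bins = ",".join(str(b) for _, b in self)
        return f"{codes}:{bins}"

    @classmethod
    def deserialize(cls, text: str) -> "TripletKey":
        codes, _, bins = text.partition(":")
        types = [_CODE_TYPE[c] for c in codes]
        return cls.from_types_bins(types, [int(b) for b in bins.split(",")])


@dataclass(frozen=True)
class ModalFingerprint:
    """Union of a compound's per-conformer triplet-key sets."""

    compound_id: str
    keys: frozenset

    def __post_init__(self):
        object.__setattr__(self, "keys", frozenset(self.keys))

    def __len__(self) -> int:
        return len(self.keys)

    def __or__(self, other: "ModalFingerprint") -> "ModalFingerprint":
        if other.compound_id != self.compound_id:
            raise ValueError("cannot union fingerprints of different compounds")
        return ModalFingerprint(self.compound_id, self.keys | other.keys)


@dataclass(frozen=True)
class BinningSpec:
    """Half-open distance bins [edges[k], edges[k+1]) in Angstrom.

    Pairs at or beyond the last edge are out of range; any triplet with an
    out-of-range edge is discarded.
    """

    edges: tuple = tuple(float(x) for x in range(0, 21))

    def __post_init__(self):
        edges = tuple(float(e) for e in self.edges)
        if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin edges must be strictly increasing, >= 2 values")
        if edges[0] != 0.0:
            raise ValueError("first bin edge must be 0")
        object.__setattr__(self, "edges", edges)

    @property
    def max_distance(self) -> float:
        return self.edges[-1]

    def bin(self, distance: float) -> int | None:
        """Bin index for a distance, or None if >= max_distance."""
        if distance < 0 or not math.isfinite(distance):
            raise ValueError(f"bad distance {distance}")
        if distance >= self.max_distance:
            return None
        # searchsorted(right) - 1: d exactly on an edge opens the next bin
        return int(np.searchsorted(self.edges, distance, side="right")) - 1


# --------------------------------------------------------------------------
# PPP assignment rules
# --------------------------------------------------------------------------

# Each entry: SMARTS pattern plus the index (within the match) of the atom
# that carries the point.  The "aromatic" type is special-cased to ring
# centroids and takes no SMARTS.  The table is deliberately conventional
# and editable; load_rule_table accepts the same structure from YAML/JSON.
DEFAULT_RULES: dict = {
    "donor": [
        {"smarts": "[#7;!H0]", "atom": 0},
        {"smarts": "[#8;!H0]", "atom": 0},
    ],
    "acceptor": [
        {"smarts": "[O;X2]", "atom": 0},
        {"smarts": "[O;X1]", "atom": 0},
        # sp3 N with a lone pair, excluding amides/sulfonamides and anilines
        {"smarts": "[N;X3;v3;!$([N]-[#6,#16,#15]=[O,S,N]);!$([N]-a)]", "atom": 0},
        # sp2 / aromatic N with an in-plane lone pair
        {"smarts": "[n;X2]", "atom": 0},
        {"smarts": "[N;X2;$([N]=[#6,#7])]", "atom": 0},
    ],
    "positive": [
        {"smarts": "[#7;+]", "atom": 0},
        {"smarts": "[N;X4]", "atom": 0},
        # protonatable primary/secondary/tertiary amine
        {"smarts": "[N;X3;v3;!$([N]-[#6,#16,#15]=[O,S,N]);!$([N]-a);!$([N]~[O,S,P])]",
         "atom": 0},
        # amidine / guanidine sp2 nitrogen
        {"smarts": "[NX2]=[CX3][NX3]", "atom": 0},
    ],
    "negative": [
        {"smarts": "[#8;-]", "atom": 0},
        {"smarts": "[CX3](=O)[OX2H1]", "atom": 0},          # carboxylic acid C
        {"smarts": "[PX4](=O)([OX2H1,OX1-])", "atom": 0},    # phosphate P
        {"smarts": "[SX4](=O)(=O)[OX2H1,OX1-]", "atom": 0},  # sulfonate S
        {"smarts": "c1nnn[nH]1", "atom": 0},                 # tetrazole
        {"smarts": "c1nnn[n-]1", "atom": 0},
    ],
    "lipophilic": [
        # carbon with no polar/charged neighbourhood
        {"smarts": "[#6;!$([#6]~[#7,#8,#15,#16,F,Cl,Br,I]);!$([#6;+,-])]", "atom": 0},
    ],
    "aromatic": "ring_centroid",
}


def load_rule_table(path: str) -> dict:
    """Load a PPP rule table from a YAML (or JSON) file."""
    import yaml

    with open(path) as fh:
        table = yaml.safe_load(fh)
    for ppp_type in table:
        if ppp_type not in PPP_TYPES:
            raise ValueError(f"unknown PPP type in rule table: {ppp_type!r}")
    return table


def _conformer_to_mol(conformer: Conformer):
    """Build a sanitized RDKit Mol (with 3D coordinates) from a Conformer."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    order_map = {
        1: Chem.BondType.SINGLE,
        2: Chem.BondType.DOUBLE,
        3: Chem.BondType.TRIPLE,
        12: Chem.BondType.AROMATIC,
    }
    mol = Chem.RWMol()
    for idx, (sym, _x, _y, _z) in enumerate(conformer.atoms):
        try:
            atom = Chem.Atom(sym)
        except Exception as exc:  # unknown element symbol
            raise StructureError(conformer.compound_id, f"bad element {sym!r}") from exc
        if conformer.charges:
            atom.SetFormalCharge(int(conformer.charges[idx]))
        mol.AddAtom(atom)
    for i, j, order in conformer.bonds:
        bt = order_map.get(order)
        if bt is None:
            raise StructureError(conformer.compound_id, f"bad bond order {order}")
        mol.AddBond(int(i), int(j), bt)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for idx, (_sym, x, y, z) in enumerate(conformer.atoms):
        conf.SetAtomPosition(idx, Point3D(x, y, z))
    mol.AddConformer(conf, assignId=True)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise StructureError(conformer.compound_id, str(exc)) from exc
    return mol.GetMol()


def assign_ppps(conformer: Conformer, rules: Mapping | None = None) -> list:
    """Convert a conformer's heavy atoms into typed pharmacophore points.

    An atom may yield several PPPs of different types.  Aromatic points sit
    at ring centroids; every other point sits on its heavy atom.  Hydrogens
    never yield points.  Duplicate (type, source-atom-set) matches from
    symmetric SMARTS are collapsed.
    """
    from rdkit import Chem

    rules = DEFAULT_RULES if rules is None else rules
    mol = _conformer_to_mol(conformer)
    conf = mol.GetConformer()
    coords = conf.GetPositions()

    points: list[PharmacophorePoint] = []
    seen: set = set()
    for ppp_type, entries in rules.items():
        if entries == "ring_centroid":
            continue
        for entry in entries:
            patt = Chem.MolFromSmarts(entry["smarts"])
            if patt is None:
                raise ValueError(f"invalid SMARTS {entry['smarts']!r}")
            for match in mol.GetSubstructMatches(patt):
                carrier = match[entry.get("atom", 0)]
                if mol.GetAtomWithIdx(carrier).GetAtomicNum() == 1:
                    continue
                tag = (ppp_type, carrier)
                if tag in seen:
                    continue
                seen.add(tag)
                points.append(PharmacophorePoint(
                    position=tuple(coords[carrier]),
                    ppp_type=ppp_type,
                    source_atoms=frozenset(match),
                ))
    if rules.get("aromatic") == "ring_centroid":
        for ring in mol.GetRingInfo().AtomRings():
            if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
                centroid = coords[list(ring)].mean(axis=0)
                points.append(PharmacophorePoint(
                    position=tuple(centroid),
                    ppp_type="aromatic",
                    source_atoms=frozenset(ring),
                ))
    return points


def enumerate_triplets(ppps: Sequence, binning: BinningSpec | None = None) -> frozenset:
    """Canonical triplet keys for all unordered PPP triples within range.

    The edge opposite each point is binned and paired with that point's
    type; a triple with any pairwise distance >= max_distance is dropped.
    Fewer than 3 points yields the empty set.
    """
    binning = binning or BinningSpec()
    if len(ppps) < 3:
        return frozenset()
    pos = np.asarray([p.position for p in ppps], dtype=float)
    keys = set()
    for i, j, k in itertools.combinations(range(len(ppps)), 3):
        # edge opposite point i is (j,k), etc.
        d_jk = float(np.linalg.norm(pos[j] - pos[k]))
        d_ik = float(np.linalg.norm(pos[i] - pos[k]))
        d_ij = float(np.linalg.norm(pos[i] - pos[j]))
        bins = [binning.bin(d) for d in (d_jk, d_ik, d_ij)]
        if any(b is None for b in bins):
            continue
        types = (ppps[i].ppp_type, ppps[j].ppp_type, ppps[k].ppp_type)
        keys.add(TripletKey.from_types_bins(types, bins))
    return frozenset(keys)


def modal_fingerprint(conformers: Sequence[Conformer],
                      rules: Mapping | None = None,
                      binning: BinningSpec | None = None) -> ModalFingerprint:
    """Union of per-conformer triplet fingerprints for one compound.

    At most MAX_CONFORMERS conformers are used (first ones in input order).
    """
    if not conformers:
        raise ValueError("at least one conformer required")
    ids = {c.compound_id for c in conformers}
    if len(ids) != 1:
        raise ValueError(f"mixed compound_ids in conformer list: {sorted(ids)}")
    keys: set = set()
    for conformer in conformers[:MAX_CONFORMERS]:
        keys |= enumerate_triplets(assign_ppps(conformer, rules), binning)
    return ModalFingerprint(conformers[0].compound_id, frozenset(keys))


def fold_fingerprint(fp: ModalFingerprint, n_bits: int = 2048) -> np.ndarray:
    """Fold a sparse key set into a fixed-width bit vector (interop only)."""
    vec = np.zeros(n_bits, dtype=np.uint8)
    for key in fp.keys:
        vec[hash(key) % n_bits] = 1
    return vec
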