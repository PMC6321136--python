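import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pharmfish.errors import StructureError
from pharmfish.pharmacophore import (
    PPP_TYPES,
    BinningSpec,
    Conformer,
    ModalFingerprint,
    PharmacophorePoint,
    TripletKey,
    assign_ppps,
    enumerate_triplets,
    modal_fingerprint,
)
from pharmfish.synthetic import gen_point_cloud_molecule


def brute_force_keys(points, binning):
    """Independent oracle: enumerate every ordered triple, bin the opposite
    edges by hand, canonicalize by explicit minimum over all 6 orderings."""
    keys = set()
    for triple in itertools.combinations(range(len(points)), 3):
        forms = []
        out_of_range = False
        for perm in itertools.permutations(triple):
            pairs = []
            for idx in perm:
                j, k = [q for q in perm if q != idx]
                d = math.dist(points[j].position, points[k].position)
                b = binning.bin(d)
                if b is None:
                    out_of_range = True
                pairs.append((PPP_TYPES.index(points[idx].ppp_type), b))
            forms.append(tuple(pairs))
        if not out_of_range:
            keys.add(min(forms))
    return keys


# ---------------------------------------------------------------------------
# PPP assignment
# ---------------------------------------------------------------------------

def test_no_heavy_atoms_gives_no_ppps():
    conf = Conformer("h2", (("H", 0.0, 0.0, 0.0), ("H", 0.74, 0.0, 0.0)),
                     ((0, 1, 1),))
    assert assign_ppps(conf) == []


def test_benzene_one_aromatic_centroid_six_lipophilic(benzene):
    ppps = assign_ppps(benzene)
    counts = Counter(p.ppp_type for p in ppps)
    assert counts == {"aromatic": 1, "lipophilic": 6}
    centroid = next(p for p in ppps if p.ppp_type == "aromatic")
    assert np.allclose(centroid.position, (0.0, 0.0, 0.0), atol=1e-9)
    assert centroid.source_atoms == frozenset(range(6))


def test_protonated_primary_amine_is_donor_and_positive():
    conf = Conformer("methylammonium",
                     (("C", 0.0, 0.0, 0.0), ("N", 1.47, 0.0, 0.0)),
                     ((0, 1, 1),), charges=(0, 1))
    types = {p.ppp_type for p in assign_ppps(conf) if 1 in p.source_atoms}
    assert {"donor", "positive"} <= types


def test_carboxylate_yields_negative():
    # acetate: CH3-C(=O)[O-]
    conf = Conformer("acetate",
                     (("C", 0.0, 0.0, 0.0), ("C", 1.5, 0.0, 0.0),
                      ("O", 2.1, 1.0, 0.0), ("O", 2.1, -1.0, 0.0)),
                     ((0, 1, 1), (1, 2, 2), (1, 3, 1)), charges=(0, 0, 0, -1))
    assert any(p.ppp_type == "negative" for p in assign_ppps(conf))


def test_malformed_structure_names_compound():
    # pentavalent carbon: sanitization must fail and name the compound
    atoms = (("C", 0.0, 0.0, 0.0),) + tuple(
        ("C", math.cos(i), math.sin(i), float(i)) for i in range(5))
    bonds = tuple((0, i, 1) for i in range(1, 6))
    conf = Conformer("badmol", atoms, bonds)
    with pytest.raises(StructureError, match="badmol"):
        assign_ppps(conf)


def test_duplicate_bond_rejected():
    with pytest.raises(StructureError, match="duplicate bond"):
        Conformer("dup", (("C", 0.0, 0.0, 0.0), ("C", 1.5, 0.0, 0.0)),
                  ((0, 1, 1), (1, 0, 1)))


def test_invalid_bond_index_rejected():
    with pytest.raises(StructureError):
        Conformer("x", (("C", 0.0, 0.0, 0.0),), ((0, 5, 1),))


# ---------------------------------------------------------------------------
# Triplet enumeration and canonicalization
# ---------------------------------------------------------------------------

def _point(x, y, z, t, idx=0):
    return PharmacophorePoint((x, y, z), t, frozenset({idx}))


def test_fewer_than_three_ppps_empty_set():
    pts = [_point(0, 0, 0, "donor", 0), _point(3, 0, 0, "acceptor", 1)]
    assert enumerate_triplets(pts) == frozenset()


def test_three_ppps_single_canonical_key_order_invariant():
    # pairwise distances 3.4 / 5.1 / 7.2 A -> bins 3 / 5 / 7 with 1 A bins
    pts = [
        _point(0.0, 0.0, 0.0, "donor", 0),
        _point(3.4, 0.0, 0.0, "acceptor", 1),
    ]
    # place third point at distances 5.1 from donor, 7.2 from acceptor
    d01, d02, d12 = 3.4, 5.1, 7.2
    x = (d01**2 + d02**2 - d12**2) / (2 * d01)
    y = math.sqrt(d02**2 - x**2)
    pts.append(_point(x, y, 0.0, "lipophilic", 2))
    reference = enumerate_triplets(pts)
    assert len(reference) == 1
    for perm in itertools.permutations(pts):
        assert enumerate_triplets(list(perm)) == reference
    assert reference == frozenset(TripletKey(k) for k in
                                  brute_force_keys(pts, BinningSpec()))


def test_six_random_points_match_brute_force():
    binning = BinningSpec()
    pts = gen_point_cloud_molecule(6, box_size=8.0, seed=3)
    keys = enumerate_triplets(pts, binning)
    oracle = {TripletKey(k) for k in brute_force_keys(pts, binning)}
    assert keys == oracle
    assert len(keys) <= math.comb(6, 3)


@pytest.mark.parametrize("n", range(3, 13))
def test_triple_count_bound_vs_brute_force(n):
    binning = BinningSpec()
    pts = gen_point_cloud_molecule(n, box_size=6.0, seed=n)
    candidates = 0
    for i, j, k in itertools.combinations(range(n), 3):
        ds = [math.dist(pts[a].position, pts[b].position)
              for a, b in ((i, j), (i, k), (j, k))]
        if all(d < binning.max_distance for d in ds):
            candidates += 1
    assert candidates == math.comb(n, 3)  # box smaller than max_distance
    keys = enumerate_triplets(pts, binning)
    assert keys == {TripletKey(k) for k in brute_force_keys(pts, binning)}
    assert len(keys) <= candidates


def test_triples_beyond_max_distance_dropped():
    pts = [_point(0, 0, 0, "donor", 0), _point(5, 0, 0, "acceptor", 1),
           _point(25, 0, 0, "lipophilic", 2)]
    assert enumerate_triplets(pts) == frozenset()


def test_coincident_points_bin_zero():
    pts = [_point(0, 0, 0, "donor", 0), _point(0, 0, 0, "acceptor", 1),
           _point(3, 0, 0, "lipophilic", 2)]
    (key,) = enumerate_triplets(pts)
    assert (PPP_TYPES.index("lipophilic"), 0) in key


@given(st.lists(
    st.tuples(st.integers(0, 5), st.integers(0, 19)), min_size=3, max_size=3))
def test_canonicalization_idempotent_and_permutation_invariant(pairs):
    key = TripletKey(pairs)
    assert TripletKey(key) == key
    for perm in itertools.permutations(pairs):
        assert TripletKey(perm) == key
    assert TripletKey.deserialize(key.serialize()) == key


# ---------------------------------------------------------------------------
# Modal fingerprints
# ---------------------------------------------------------------------------

def test_single_conformer_union_identity(benzene):
    fp = modal_fingerprint([benzene])
    assert fp.keys == enumerate_triplets(assign_ppps(benzene))


def test_duplicated_conformer_idempotent(benzene):
    once = modal_fingerprint([benzene])
    thrice = modal_fingerprint([benzene] * 3)
    assert once.keys == thrice.keys


def test_union_of_two_conformers_matches_set_arithmetic(benzene):
    shifted = Conformer("benzene",
                        tuple((s, x * 1.3, y * 1.3, z) for s, x, y, z in benzene.atoms),
                        benzene.bonds, conformer_index=1)
    a = enumerate_triplets(assign_ppps(benzene))
    b = enumerate_triplets(assign_ppps(shifted))
    fp = modal_fingerprint([benzene, shifted])
    assert fp.keys == a | b
    assert len(fp) == len(a | b)


def test_adding_conformer_never_removes_keys(benzene):
    shifted = Conformer("benzene",
                        tuple((s, x * 1.2, y * 1.2, z) for s, x, y, z in benzene.atoms),
                        benzene.bonds, conformer_index=1)
    assert modal_fingerprint([benzene]).keys <= modal_fingerprint(
        [benzene, shifted]).keys


def test_mixed_compound_ids_rejected(benzene):
    other = Conformer("toluene?", benzene.atoms, benzene.bonds)
    with pytest.raises(ValueError, match="mixed compound_ids"):
        modal_fingerprint([benzene, other])


def test_conformer_cap_keeps_first_ten(benzene):
    # conformer 11 is wildly different; it must be ignored
    scaled = Conformer("benzene",
                       tuple((s, x * 2.0, y * 2.0, z) for s, x, y, z in benzene.atoms),
                       benzene.bonds)
    fp_capped = modal_fingerprint([benzene] * 10 + [scaled])
    assert fp_capped.keys == modal_fingerprint([benzene]).keys


# ---------------------------------------------------------------------------
# Geometric invariances
# ---------------------------------------------------------------------------

def _rotate_points(points, matrix, shift):
    out = []
    for p in points:
        pos = matrix @ np.asarray(p.position) + shift
        out.append(PharmacophorePoint(tuple(pos), p.ppp_type, p.source_atoms))
    return out


@pytest.mark.parametrize("axis", ["x", "y", "z"])
def test_rigid_motion_invariance_point_cloud(axis):
    # exact 90-degree rotations are distance-preserving in floating point
    mats = {
        "x": np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float),
        "y": np.array([[0, 0, 1], [0, 1, 0], [-1, 0, 0]], dtype=float),
        "z": np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float),
    }
    pts = gen_point_cloud_molecule(8, box_size=9.0, seed=17)
    moved = _rotate_points(pts, mats[axis], np.array([5.0, -3.0, 2.0]))
    assert enumerate_triplets(pts) == enumerate_triplets(moved)


def test_rigid_motion_invariance_full_molecule(benzene):
    mat = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
    atoms = tuple((s, *tuple(mat @ np.array([x, y, z]) + np.array([1.0, 2.0, -4.0])))
                  for s, x, y, z in benzene.atoms)
    rotated = Conformer("benzene", atoms, benzene.bonds)
    assert modal_fingerprint([rotated]).keys == modal_fingerprint([benzene]).keys


def test_atom_order_invariance(benzene):
    perm = [3, 1, 5, 0, 4, 2]
    inverse = {old: new for new, old in enumerate(perm)}
    atoms = tuple(benzene.atoms[old] for old in perm)
    bonds = tuple((inverse[i], inverse[j], o) for i, j, o in benzene.bonds)
    shuffled = Conformer("benzene", atoms, bonds)
    assert modal_fingerprint([shuffled]).keys == modal_fingerprint([benzene]).keys


# ---------------------------------------------------------------------------
# Binning spec
# ---------------------------------------------------------------------------

def test_binning_half_open_edges():
    spec = BinningSpec()
    assert spec.bin(0.0) == 0
    assert spec.bin(0.999) == 0
    assert spec.bin(1.0) == 1
    assert spec.bin(19.999) == 19
    assert spec.bin(20.0) is None


def test_binning_rejects_bad_edges():
    with pytest.raises(ValueError):
        BinningSpec((0.0, 2.0, 1.0))
    with pytest.raises(ValueError):
        BinningSpec((1.0, 2.0))
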