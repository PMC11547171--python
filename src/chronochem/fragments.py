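"""Fragment decompositions: Bemis–Murcko scaffolds, ring assemblies, side
chains, and RECAP retrosynthetic fragments.

The scaffold/side-chain pair is computed from a single atom partition so that
heavy atoms are conserved exactly: scaffold atoms are ring atoms, the linker
atoms on paths between ring systems, and atoms multiply-bonded to either
(exocyclic =O and the like); everything else forms the side chains, each
carrying one dummy-atom attachment marker.  Ring assemblies merge rings that
share at least one atom, so fused and spiro systems come out as one fragment.
RECAP cleaves the eleven published retrosynthetic bond classes exhaustively
and keeps leaf fragments above a heavy-atom floor (markers never count).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Recap, rdMolDescriptors


@dataclass
class FragmentSet:
    record_id: str
    scaffold: str | None
    ring_assemblies: Counter
    side_chains: Counter
    recap_fragments: Counter


def _scaffold_atom_indices(mol: Chem.Mol) -> set[int]:
    """Ring atoms + inter-ring linkers + exocyclic multiply-bonded neighbours."""
    ri = mol.GetRingInfo()
    ring_atoms = {i for ring in ri.AtomRings() for i in ring}
    if not ring_atoms:
        return set()
    # linkers: iteratively prune non-ring terminal atoms; whatever non-ring
    # atoms survive lie on a path between two rings
    degree = {}
    alive = set(range(mol.GetNumAtoms()))
    for a in mol.GetAtoms():
        degree[a.GetIdx()] = len(a.GetNeighbors())
    frontier = [i for i in alive if degree[i] <= 1 and i not in ring_atoms]
    while frontier:
        nxt = []
        for i in frontier:
            if i not in alive:
                continue
            alive.discard(i)
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in alive:
                    degree[j] -= 1
                    if degree[j] <= 1 and j not in ring_atoms:
                        nxt.append(j)
        frontier = nxt
    core = alive  # ring atoms plus linker atoms
    keep = set(core)
    for i in core:
        atom = mol.GetAtomWithIdx(i)
        for bond in atom.GetBonds():
            other = bond.GetOtherAtom(atom).GetIdx()
            if other not in core and bond.GetBondType() != Chem.BondType.SINGLE:
                keep.add(other)
    return keep


def _submol(mol: Chem.Mol, atom_indices: set[int]) -> Chem.Mol | None:
    rw = Chem.RWMol(mol)
    for idx in sorted(set(range(mol.GetNumAtoms())) - atom_indices, reverse=True):
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def murcko_scaffold(mol: Chem.Mol) -> str | None:
    """Canonical scaffold SMILES, or None for acyclic molecules."""
    keep = _scaffold_atom_indices(mol)
    if not keep:
        return None
    sub = _submol(mol, keep)
    if sub is None:  # pathological sanitization failure: fall back to atom dump
        return None
    return Chem.MolToSmiles(sub)


def ring_assemblies(mol: Chem.Mol) -> Counter:
    """Multiset of canonical assembly SMILES (rings sharing >=1 atom merge)."""
    ri = mol.GetRingInfo()
    rings = [set(r) for r in ri.AtomRings()]
    if not rings:
        return Counter()
    # union-find over rings via shared atoms
    parent = list(range(len(rings)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            if rings[i] & rings[j]:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pi] = pj
    components: dict[int, set[int]] = {}
    for i, ring in enumerate(rings):
        components.setdefault(find(i), set()).update(ring)
    out = Counter()
    for atoms in components.values():
        keep = set(atoms)
        for i in atoms:
            a = mol.GetAtomWithIdx(i)
            for bond in a.GetBonds():
                other = bond.GetOtherAtom(a).GetIdx()
                if other not in atoms and bond.GetBondType() != Chem.BondType.SINGLE:
                    keep.add(other)
        sub = _submol(mol, keep)
        if sub is not None:
            out[Chem.MolToSmiles(sub)] += 1
    return out


def assembly_profile(assembly: Chem.Mol) -> dict[str, int]:
    """Ring, aromatic-ring, spiro-atom and bridgehead-atom counts of one
    ring assembly."""
    ri = assembly.GetRingInfo()
    n_aromatic = 0
    for ring in ri.BondRings():
        if all(assembly.GetBondWithIdx(b).GetIsAromatic() for b in ring):
            n_aromatic += 1
    return {
        "n_rings": ri.NumRings(),
        "n_aromatic_rings": n_aromatic,
        "n_spiro_atoms": rdMolDescriptors.CalcNumSpiroAtoms(assembly),
        "n_bridgehead_atoms": rdMolDescriptors.CalcNumBridgeheadAtoms(assembly),
    }


def side_chains(mol: Chem.Mol) -> Counter:
    """Multiset of side-chain SMILES, one ``*`` attachment marker each.

    Complement of the scaffold atom set; acyclic molecules yield the empty
    multiset (they have no scaffold to hang chains on).
    """
    keep = _scaffold_atom_indices(mol)
    if not keep:
        return Counter()
    rw = Chem.RWMol(mol)
    # mark chain atoms bonded to scaffold atoms, then replace each crossing
    # bond with a bond to a fresh dummy atom
    crossing = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (i in keep) != (j in keep):
            chain_atom = j if i in keep else i
            crossing.append((bond.GetIdx(), chain_atom, bond.GetBondType()))
    for _, chain_atom, btype in crossing:
        dummy = rw.AddAtom(Chem.Atom(0))
        rw.AddBond(chain_atom, dummy, btype)
    for bidx, _, _ in sorted(crossing, key=lambda t: -t[0]):
        b = mol.GetBondWithIdx(bidx)
        rw.RemoveBond(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    for idx in sorted(keep, reverse=True):
        rw.RemoveAtom(idx)
    frag_mol = rw.GetMol()
    try:
        Chem.SanitizeMol(frag_mol)
    except Exception:
        return Counter()
    out = Counter()
    for frag in Chem.GetMolFrags(frag_mol, asMols=True, sanitizeFrags=False):
        out[Chem.MolToSmiles(frag)] += 1
    return out


def _n_heavy_no_marker(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1 and a.GetAtomicNum() != 0)


def _genericize_markers(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return smiles
    for a in mol.GetAtoms():
        if a.GetAtomicNum() == 0:
            a.SetIsotope(0)
            a.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


def recap_fragments(mol: Chem.Mol, min_heavy: int = 4) -> Counter:
    """Leaf fragments of an exhaustive RECAP decomposition, keeping those with
    at least ``min_heavy`` heavy atoms (attachment markers excluded)."""
    tree = Recap.RecapDecompose(mol)
    out = Counter()
    for leaf in tree.GetLeaves().values():
        frag = leaf.mol
        if _n_heavy_no_marker(frag) >= min_heavy:
            out[_genericize_markers(Chem.MolToSmiles(frag))] += 1
    return out


def decompose(mol: Chem.Mol, record_id: str = "", min_heavy: int = 4) -> FragmentSet:
    """All four decompositions of one standardized molecule."""
    return FragmentSet(
        record_id=record_id,
        scaffold=murcko_scaffold(mol),
        ring_assemblies=ring_assemblies(mol),
        side_chains=side_chains(mol),
        recap_fragments=recap_fragments(mol, min_heavy=min_heavy),
    )
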