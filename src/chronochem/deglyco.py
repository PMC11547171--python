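"""Circular sugar (glycoside) detection and removal.

A candidate sugar ring is an isolated, non-aromatic 5- or 6-membered ring with
exactly one ring oxygen and otherwise carbon, whose exocyclic oxygen
substitution is dense enough: (oxygens bonded to ring atoms from outside the
ring) / (ring size) >= ``ratio_threshold`` (default 0.4, the value used for the
reference deglycosylation of natural-product libraries).

Removal deletes the ring together with its purely-exocyclic oxygen
substituents; an oxygen bridging the ring to the rest of the molecule (the
glycosidic oxygen) stays with the aglycone, so salicin yields the salicyl
alcohol skeleton and methyl glucopyranoside yields a methanol fragment.
Removal iterates to fixpoint, each round keeping the largest remaining
fragment, because stripping one sugar can expose another.

Linear (acyclic) sugars are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem


@dataclass(frozen=True)
class DeglycoParams:
    ratio_threshold: float = 0.4
    remove_terminal: bool = True
    remove_nonterminal: bool = True
    ring_sizes: frozenset[int] = frozenset({5, 6})

    def __post_init__(self):
        if not (0 < self.ratio_threshold <= 1):
            raise ValueError("ratio_threshold must be in (0, 1]")
        if not set(self.ring_sizes) <= {4, 5, 6, 7}:
            raise ValueError("ring_sizes must be within {4..7}")


@dataclass
class DeglycosylationResult:
    aglycone: str | None
    n_sugar_rings_removed: int
    sugar_only: bool
    removed_ring_sizes: list[int] = field(default_factory=list)


def detect_circular_sugars(
    mol: Chem.Mol, params: DeglycoParams = DeglycoParams()
) -> list[tuple[int, ...]]:
    """Atom-index tuples of rings satisfying every sugar-ring condition."""
    ri = mol.GetRingInfo()
    candidates: list[tuple[int, ...]] = []
    for ring in ri.AtomRings():
        if len(ring) not in params.ring_sizes:
            continue
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        symbols = [a.GetSymbol() for a in atoms]
        if symbols.count("O") != 1 or any(s not in ("C", "O") for s in symbols):
            continue
        # isolated: no ring atom belongs to any other ring (excludes fused/spiro)
        if any(ri.NumAtomRings(i) > 1 for i in ring):
            continue
        ring_set = set(ring)
        bonds = [
            mol.GetBondBetweenAtoms(ring[i], ring[(i + 1) % len(ring)])
            for i in range(len(ring))
        ]
        if any(b.GetIsAromatic() for b in bonds):
            continue
        n_exo_o = 0
        for a in atoms:
            for nb in a.GetNeighbors():
                if nb.GetIdx() not in ring_set and nb.GetSymbol() == "O":
                    n_exo_o += 1  # once per ring atom the oxygen touches
        if n_exo_o / len(ring) >= params.ratio_threshold:
            candidates.append(tuple(ring))
    return candidates


def _ring_is_terminal(mol: Chem.Mol, ring: tuple[int, ...]) -> bool:
    """Terminal sugar: the ring plus its exocyclic O substituents connect to
    the remainder of the molecule through at most one bond."""
    ring_set = set(ring)
    unit = set(ring)
    for i in ring:
        for nb in mol.GetAtomWithIdx(i).GetNeighbors():
            if nb.GetIdx() not in ring_set and nb.GetSymbol() == "O":
                unit.add(nb.GetIdx())
    out_bonds = 0
    for i in unit:
        for nb in mol.GetAtomWithIdx(i).GetNeighbors():
            if nb.GetIdx() not in unit:
                out_bonds += 1
    return out_bonds <= 1


def _delete_rings(mol: Chem.Mol, rings: list[tuple[int, ...]]) -> Chem.Mol | None:
    """Delete the ring atoms and every exocyclic oxygen whose heavy neighbours
    all lie inside the deleted set; bridging oxygens survive."""
    doomed = set()
    for ring in rings:
        doomed.update(ring)
    for ring in rings:
        for i in ring:
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                if nb.GetIdx() in doomed or nb.GetSymbol() != "O":
                    continue
                if all(h.GetIdx() in doomed for h in nb.GetNeighbors()):
                    doomed.add(nb.GetIdx())
    rw = Chem.RWMol(mol)
    for idx in sorted(doomed, reverse=True):
        rw.RemoveAtom(idx)
    if rw.GetNumHeavyAtoms() == 0:
        return None
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return frags[0]
    return max(
        frags, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f))
    )


def remove_sugars(
    mol: Chem.Mol, params: DeglycoParams = DeglycoParams()
) -> DeglycosylationResult:
    """Iteratively strip circular sugars; classify sugar-only molecules.

    Keeps the single largest non-sugar fragment after each deletion round (a
    non-terminal sugar can disconnect the molecule).  No molecular-weight
    refilter is applied to the aglycone.
    """
    original = Chem.MolToSmiles(mol)
    current = mol
    n_removed = 0
    sizes: list[int] = []
    while True:
        found = detect_circular_sugars(current, params)
        found = [
            r
            for r in found
            if (params.remove_terminal and _ring_is_terminal(current, r))
            or (params.remove_nonterminal and not _ring_is_terminal(current, r))
        ]
        if not found:
            break
        n_removed += len(found)
        sizes.extend(len(r) for r in found)
        nxt = _delete_rings(current, found)
        if nxt is None:
            return DeglycosylationResult(None, n_removed, True, sizes)
        current = _largest_fragment(nxt)
    if n_removed == 0:
        return DeglycosylationResult(original, 0, False, [])
    return DeglycosylationResult(Chem.MolToSmiles(current), n_removed, False, sizes)
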