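"""Structural-alert mining.

Two complementary miners emit candidate structural alerts as
aromaticity-aware SMARTS patterns:

* :func:`mine_graph` — a graph-based depth-first miner in the MoSS/MoFa
  tradition. Fragments grow bond-by-bond from single-atom seeds; a candidate
  is pruned as soon as its occurrence in the focus (DILI-positive) class
  drops below the minimum focus support, which is sound because
  molecule-level support is anti-monotone under extension. Rings are mined
  atomically: when a ring bond enters a fragment the whole ring (closed over
  fused systems) enters with it, so partial rings are never emitted and
  every fragment's aromatic perception matches its parent molecules.

* :func:`mine_fragments` — a recursive bond-breaking miner in the SARpy
  tradition. The fragment pool is every connected piece obtainable by
  cutting any combination of acyclic single bonds (rings stay intact); each
  pool member is validated against the whole dataset and retained by hit
  count, likelihood ratio and precision, after which a reduced rule set is
  extracted greedily.

Support is always the number of molecules matching the fragment's SMARTS
(not the number of embeddings), counted with the same matcher used by the
downstream alert evaluation, so mined supports and evaluated supports can
never disagree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil, floor

from rdkit import Chem


@dataclass(frozen=True)
class StructuralAlert:
    pattern: str  # SMARTS
    source: str  # graph_miner | fragment_miner | external
    focus_support: int
    complement_support: int
    n_bonds: int
    n_atoms: int


def _parse_all(smiles_list, role: str) -> list[Chem.Mol]:
    mols = []
    for s in smiles_list:
        m = Chem.MolFromSmiles(s)
        if m is None:
            raise ValueError(f"unparseable {role} SMILES: {s!r}")
        mols.append(m)
    return mols


def fragment_to_smarts(submol: Chem.Mol) -> str:
    """Canonical aromaticity-aware SMARTS for a molecule subgraph.

    The canonical SMILES of the subgraph is used directly as a SMARTS query:
    aromatic atoms come out lowercase and aliphatic uppercase, so downstream
    matching distinguishes e.g. furan from tetrahydrofuran. Because rings are
    only ever extracted whole, aromatic tokens always sit in complete rings
    and the string is a valid query.
    """
    return Chem.MolToSmiles(submol)


def _submol(mol: Chem.Mol, bond_ids: frozenset[int]) -> Chem.Mol:
    return Chem.PathToSubmol(mol, sorted(bond_ids))


def _ring_bond_sets(mol: Chem.Mol) -> list[frozenset[int]]:
    return [frozenset(r) for r in mol.GetRingInfo().BondRings()]


def _ring_closure(ring_sets: list[frozenset[int]], bonds: frozenset[int]) -> frozenset[int]:
    """Close a bond set over rings: any touched ring is included whole."""
    out = set(bonds)
    changed = True
    while changed:
        changed = False
        for ring in ring_sets:
            if out & ring and not ring <= out:
                out |= ring
                changed = True
    return frozenset(out)


def _seed_smarts(atom: Chem.Atom) -> str:
    sym = atom.GetSymbol()
    sym = sym.lower() if atom.GetIsAromatic() else sym
    charge = atom.GetFormalCharge()
    tag = "" if charge == 0 else f"{'+' if charge > 0 else '-'}{abs(charge) if abs(charge) > 1 else ''}"
    return f"[{sym}{tag}]"


def _match_count(query: Chem.Mol, mols: list[Chem.Mol]) -> int:
    return sum(m.HasSubstructMatch(query) for m in mols)


def _embeddings(query: Chem.Mol, mol: Chem.Mol) -> list[tuple[frozenset[int], frozenset[int]]]:
    """All (atom set, bond set) embeddings of a fragment query in a molecule."""
    out = []
    q_bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in query.GetBonds()]
    for amap in mol.GetSubstructMatches(query, uniquify=True):
        atoms = frozenset(amap)
        bonds = set()
        for qa, qb in q_bonds:
            mb = mol.GetBondBetweenAtoms(amap[qa], amap[qb])
            bonds.add(mb.GetIdx())
        out.append((atoms, frozenset(bonds)))
    return out


def _has_heteroatom(query: Chem.Mol) -> bool:
    return any(a.GetSymbol() != "C" for a in query.GetAtoms())


def mine_graph(
    positive_smiles,
    negative_smiles,
    mfs: float = 0.01,
    mcs: float = 0.0001,
    min_bonds: int = 2,
    max_bonds: int = 15,
) -> list[StructuralAlert]:
    """Depth-first graph mining with focus/complement support thresholds.

    `mfs` is the minimum fraction of DILI-positive molecules a fragment must
    occur in (converted to a count with ceil, so 1% of 200 positives means
    ≥ 2); `mcs` is the maximum allowed fraction of negatives (converted with
    floor, so 0.01% of a few hundred negatives means 0 — precision 1 on the
    mining set). Emitted alerts have 2–15 bonds, at least one non-carbon
    atom, and whole rings only.
    """
    if not 0 < mfs <= 1 or not 0 <= mcs < 1:
        raise ValueError("need 0 < mfs <= 1 and 0 <= mcs < 1")
    pos = _parse_all(positive_smiles, "positive")
    if not pos:
        raise ValueError("positive set must be non-empty")
    neg = _parse_all(negative_smiles, "negative")
    min_focus = ceil(mfs * len(pos))
    max_compl = floor(mcs * len(neg))
    ring_sets = {id(m): _ring_bond_sets(m) for m in pos}

    # seeds: one state per distinct atom type occurring in the focus class
    frontier: dict[str, Chem.Mol] = {}
    for m in pos:
        for a in m.GetAtoms():
            s = _seed_smarts(a)
            if s not in frontier:
                frontier[s] = Chem.MolFromSmarts(s)

    visited: set[str] = set(frontier)
    alerts: dict[str, StructuralAlert] = {}
    while frontier:
        next_frontier: dict[str, Chem.Mol] = {}
        for smarts in sorted(frontier):
            query = frontier[smarts]
            focus = _match_count(query, pos)
            if focus < min_focus:
                continue  # anti-monotone pruning: no extension can recover
            n_bonds = query.GetNumBonds()
            if (
                min_bonds <= n_bonds <= max_bonds
                and _has_heteroatom(query)
                and _match_count(query, neg) <= max_compl
            ):
                alerts[smarts] = StructuralAlert(
                    pattern=smarts,
                    source="graph_miner",
                    focus_support=focus,
                    complement_support=_match_count(query, neg),
                    n_bonds=n_bonds,
                    n_atoms=query.GetNumAtoms(),
                )
            if n_bonds >= max_bonds:
                continue
            for m in pos:
                rings = ring_sets[id(m)]
                for atoms, bonds in _embeddings(query, m):
                    for b in m.GetBonds():
                        bid = b.GetIdx()
                        if bid in bonds:
                            continue
                        if (
                            b.GetBeginAtomIdx() not in atoms
                            and b.GetEndAtomIdx() not in atoms
                        ):
                            continue
                        cand = _ring_closure(rings, bonds | {bid})
                        if len(cand) > max_bonds:
                            continue
                        sub = _submol(m, cand)
                        key = fragment_to_smarts(sub)
                        if key in visited:
                            continue
                        visited.add(key)
                        next_frontier[key] = Chem.MolFromSmarts(key)
        frontier = next_frontier
    return [alerts[k] for k in sorted(alerts)]


# ---------------------------------------------------------------------------
# bond-breaking fragment miner


def _blocks(mol: Chem.Mol) -> tuple[list[set[int]], list[tuple[int, int, int]]]:
    """Partition atoms into rigid blocks connected by breakable bonds.

    Breakable = acyclic single non-aromatic bonds. Returns the blocks (atom
    index sets) and the breakable bonds as (block_a, block_b, bond_idx).
    """
    breakable = [
        b.GetIdx()
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE
        and not b.GetIsAromatic()
        and not b.IsInRing()
    ]
    breakset = set(breakable)
    parent = list(range(mol.GetNumAtoms()))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for b in mol.GetBonds():
        if b.GetIdx() not in breakset:
            i, j = find(b.GetBeginAtomIdx()), find(b.GetEndAtomIdx())
            if i != j:
                parent[i] = j
    roots: dict[int, int] = {}
    blocks: list[set[int]] = []
    for a in range(mol.GetNumAtoms()):
        r = find(a)
        if r not in roots:
            roots[r] = len(blocks)
            blocks.append(set())
        blocks[roots[r]].add(a)
    edges = [
        (roots[find(mol.GetBondWithIdx(b).GetBeginAtomIdx())],
         roots[find(mol.GetBondWithIdx(b).GetEndAtomIdx())],
         b)
        for b in breakable
    ]
    return blocks, edges


def _connected_subsets(n_nodes: int, adjacency: list[set[int]], limit: int | None = None):
    """Enumerate connected node subsets of a graph (tree, for our block graphs).

    Standard rooted enumeration: each subset is generated once, rooted at its
    smallest node.
    """
    results = []
    for root in range(n_nodes):
        stack = [(frozenset([root]), frozenset(
            v for v in adjacency[root] if v > root
        ))]
        while stack:
            subset, frontier = stack.pop()
            results.append(subset)
            if limit is not None and len(results) >= limit:
                return results
            frontier = sorted(frontier)
            for i, v in enumerate(frontier):
                new_frontier = frozenset(
                    u for u in set(frontier[i + 1:]) | (adjacency[v] - subset)
                    if u > root
                ) - {v}
                stack.append((subset | {v}, new_frontier))
    return results


#: Above this many breakable bonds per molecule, the fragment pool explodes
#: combinatorially and the miner falls back to sampling with a warning.
SAMPLING_GUARD_BONDS = 60
SAMPLING_POOL_LIMIT = 20000


def _molecule_fragments(mol: Chem.Mol, min_atoms: int, max_atoms: int) -> set[str]:
    """All fragment SMARTS obtainable from one molecule by bond breaking."""
    blocks, edges = _blocks(mol)
    limit = None
    if len(edges) > SAMPLING_GUARD_BONDS:
        warnings.warn(
            f"molecule has {len(edges)} breakable bonds; sampling fragment pool",
            stacklevel=2,
        )
        limit = SAMPLING_POOL_LIMIT
    adjacency = [set() for _ in blocks]
    for a, b, _ in edges:
        adjacency[a].add(b)
        adjacency[b].add(a)
    out: set[str] = set()
    for subset in _connected_subsets(len(blocks), adjacency, limit=limit):
        atoms = set().union(*(blocks[i] for i in subset))
        if not min_atoms <= len(atoms) <= max_atoms:
            continue
        bond_ids = frozenset(
            b.GetIdx()
            for b in mol.GetBonds()
            if b.GetBeginAtomIdx() in atoms and b.GetEndAtomIdx() in atoms
        )
        if not bond_ids:
            continue
        out.add(fragment_to_smarts(_submol(mol, bond_ids)))
    return out


def fragment_pool(smiles_list, min_atoms: int = 2, max_atoms: int = 15) -> set[str]:
    """Union of all bond-breaking fragments over a molecule list."""
    pool: set[str] = set()
    for m in _parse_all(smiles_list, "input"):
        pool |= _molecule_fragments(m, min_atoms, max_atoms)
    return pool


def likelihood_ratio(tp: int, fp: int, n_pos: int, n_neg: int) -> float:
    """Precision over prior-positive rate; FP is continuity-substituted by 0.5
    when zero so perfectly clean fragments get a finite, large LR."""
    if tp == 0:
        return 0.0
    fp_eff = 0.5 if fp == 0 else fp
    precision = tp / (tp + fp_eff)
    prior = n_pos / (n_pos + n_neg)
    return precision / prior


def mine_fragments(
    positive_smiles,
    negative_smiles,
    min_atoms: int = 2,
    max_atoms: int = 15,
    min_hits: int = 5,
    min_lr: float = 1.0,
    min_precision: float = 0.0,
) -> list[StructuralAlert]:
    """Bond-breaking fragment mining with greedy rule extraction.

    The pool from the positive class is validated against the whole dataset;
    fragments pass if they hit at least `min_hits` positives, have
    likelihood ratio ≥ `min_lr` and precision ≥ `min_precision`. Rules are
    then extracted greedily in (LR, hits) order, dropping any fragment whose
    matched positives are a subset of an already accepted rule's matches.
    """
    pos = _parse_all(positive_smiles, "positive")
    neg = _parse_all(negative_smiles, "negative")
    if not pos:
        raise ValueError("positive set must be non-empty")
    pool: set[str] = set()
    for m in pos:
        pool |= _molecule_fragments(m, min_atoms, max_atoms)

    scored = []
    for smarts in sorted(pool):
        query = Chem.MolFromSmarts(smarts)
        pos_matches = frozenset(
            i for i, m in enumerate(pos) if m.HasSubstructMatch(query)
        )
        tp = len(pos_matches)
        if tp < min_hits:
            continue
        fp = _match_count(query, neg)
        precision = tp / (tp + fp)
        lr = likelihood_ratio(tp, fp, len(pos), len(neg))
        if lr < min_lr or precision < min_precision:
            continue
        scored.append((lr, tp, fp, smarts, query, pos_matches))

    scored.sort(key=lambda t: (-t[0], -t[1], t[3]))
    accepted: list[StructuralAlert] = []
    accepted_matches: list[frozenset[int]] = []
    for lr, tp, fp, smarts, query, pos_matches in scored:
        if any(pos_matches <= prev for prev in accepted_matches):
            continue
        accepted.append(
            StructuralAlert(
                pattern=smarts,
                source="fragment_miner",
                focus_support=tp,
                complement_support=fp,
                n_bonds=query.GetNumBonds(),
                n_atoms=query.GetNumAtoms(),
            )
        )
        accepted_matches.append(pos_matches)
    return accepted
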