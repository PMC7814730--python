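"""Synthetic study-data generation.

Everything the pipeline consumes can be generated here with full seed
reproducibility: labeled SMILES sets in which specified toxicophore
substructures occur with class-dependent prevalence, binary target-prediction
matrices with planted class-shifted columns, geneset collections in GMT form,
and decoy approved-drug catalogs.

Molecules are assembled by joining random scaffold fragments with single
bonds and, for designated carrier compounds, grafting the toxicophore
fragment onto the assembled body. Assembled bodies are rejection-sampled so
that non-carriers never match any planted pattern, and carrier counts are
exact (hypergeometric assignment: round(prevalence*n) carriers chosen without
replacement) so that tests can assert exact occurrence counts; a per-compound
Bernoulli mode is available behind a flag. Emitted SMILES are passed through
the curation standardizer so they are already in standard form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .curation import standardize_structure

#: Default scaffold fragments; chosen to be tautomer-stable, neutral and free
#: of the default toxicophores so decoys never match by accident.
DEFAULT_SCAFFOLDS = (
    "CCO",
    "CCC",
    "c1ccccc1",
    "CC(C)O",
    "CCCl",
    "CC(=O)O",
    "CCS",
    "C1CCCCC1",
    "CCN",
    "c1ccncc1",
    "COC",
    "CC(C)C",
)

#: Default toxicophores: hydrazine and furan, the two headline DILI alerts.
DEFAULT_TOXICOPHORES = (("NN", 0.10, 0.0), ("c1ccco1", 0.10, 0.0))


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative recipe for one synthetic study.

    Defaults encode the study conditions used throughout: 200+200 compounds,
    two toxicophores planted in 10% of positives and no negatives, 100 binary
    target features of which the first 20 carry a +0.4 probability shift in
    the positive class over a 0.3 base rate.
    """

    n_pos: int = 200
    n_neg: int = 200
    toxicophores: tuple[tuple[str, float, float], ...] = DEFAULT_TOXICOPHORES
    scaffold_pool: tuple[str, ...] = DEFAULT_SCAFFOLDS
    n_target_features: int = 100
    planted_features: tuple[tuple[int, float], ...] = tuple(
        (j, 0.4) for j in range(20)
    )
    base_rate: float = 0.3
    genesets_n_random: int = 20
    seed: int = 0

    def __post_init__(self):
        for patt, p_pos, p_neg in self.toxicophores:
            if not (0.0 <= p_neg <= p_pos <= 1.0):
                raise ValueError(
                    f"toxicophore {patt!r}: need 0 <= prevalence_neg <= "
                    f"prevalence_pos <= 1, got {p_neg}, {p_pos}"
                )
        if not self.scaffold_pool:
            raise ValueError("scaffold_pool must be non-empty")
        for j, eff in self.planted_features:
            if not 0 <= j < self.n_target_features:
                raise ValueError(f"planted feature index {j} out of range")
            if not (0.0 <= self.base_rate + eff <= 1.0):
                raise ValueError(
                    f"effect {eff} pushes probability outside [0,1] "
                    f"(base rate {self.base_rate})"
                )

    def rng(self, stream: str) -> np.random.Generator:
        """Named child RNG stream derived from the one global seed."""
        key = tuple(ord(c) for c in stream)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=key)
        )


def _parse_fragment(smiles: str, role: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable {role} fragment: {smiles!r}")
    return mol


def _free_atoms(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0]


def _join(a: Chem.Mol, b: Chem.Mol, rng: np.random.Generator) -> Chem.Mol | None:
    """Join two fragments with a single bond at random H-bearing atoms."""
    fa, fb = _free_atoms(a), _free_atoms(b)
    if not fa or not fb:
        return None
    combo = Chem.RWMol(Chem.CombineMols(a, b))
    ia = int(rng.choice(fa))
    ib = int(rng.choice(fb)) + a.GetNumAtoms()
    combo.AddBond(ia, ib, Chem.BondType.SINGLE)
    mol = combo.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _assemble(
    scaffolds: list[Chem.Mol],
    avoid: list[Chem.Mol],
    rng: np.random.Generator,
    graft: Chem.Mol | None = None,
    max_tries: int = 200,
) -> str:
    """Assemble one molecule body; optionally graft a toxicophore.

    Bodies are rejection-sampled so that the final molecule matches none of
    the `avoid` patterns unless the graft itself introduces one.
    """
    for _ in range(max_tries):
        n_frag = int(rng.integers(1, 4))
        idx = rng.integers(0, len(scaffolds), size=n_frag)
        mol = Chem.Mol(scaffolds[int(idx[0])])
        ok = True
        for i in idx[1:]:
            joined = _join(mol, scaffolds[int(i)], rng)
            if joined is None:
                ok = False
                break
            mol = joined
        if not ok:
            continue
        if graft is not None:
            joined = _join(mol, graft, rng)
            if joined is None:
                continue
            mol = joined
            body_check = None  # carrier: only require parseability
        else:
            body_check = avoid
        smi = standardize_structure(Chem.MolToSmiles(mol))
        final = Chem.MolFromSmiles(smi)
        if final is None:
            continue
        if body_check and any(final.HasSubstructMatch(p) for p in body_check):
            continue
        return smi
    raise RuntimeError("failed to assemble a valid molecule; widen scaffold pool")


def generate_compound_set(spec: SyntheticSpec, exact_counts: bool = True):
    """Generate the labeled compound table.

    Returns a pandas DataFrame with columns compound_id, smiles, source,
    dili_class (vMost for positives, vNo for negatives). Toxicophore t is
    planted in round(prevalence_pos*n_pos) positives and
    round(prevalence_neg*n_neg) negatives (exact counts), or per-compound
    Bernoulli draws when ``exact_counts=False``.
    """
    import pandas as pd

    rng = spec.rng("compounds")
    scaffolds = [_parse_fragment(s, "scaffold") for s in spec.scaffold_pool]
    tox_mols = [
        (_parse_fragment(p, "toxicophore"), Chem.MolFromSmarts(p))
        for p, _, _ in spec.toxicophores
    ]
    avoid = [q for _, q in tox_mols]

    n_total = spec.n_pos + spec.n_neg
    # carriers[t] = boolean carrier flags over all compounds (pos block first)
    carriers = np.zeros((len(spec.toxicophores), n_total), dtype=bool)
    for t, (_, p_pos, p_neg) in enumerate(spec.toxicophores):
        if exact_counts:
            k_pos = int(round(p_pos * spec.n_pos))
            k_neg = int(round(p_neg * spec.n_neg))
            pos_idx = rng.choice(spec.n_pos, size=k_pos, replace=False)
            neg_idx = rng.choice(spec.n_neg, size=k_neg, replace=False)
            carriers[t, pos_idx] = True
            carriers[t, spec.n_pos + neg_idx] = True
        else:
            carriers[t, : spec.n_pos] = rng.random(spec.n_pos) < p_pos
            carriers[t, spec.n_pos :] = rng.random(spec.n_neg) < p_neg

    rows = []
    for i in range(n_total):
        label_pos = i < spec.n_pos
        graft = None
        carried = [t for t in range(len(spec.toxicophores)) if carriers[t, i]]
        mol = None
        if carried:
            # graft all assigned toxicophores sequentially
            body = _assemble(scaffolds, avoid, rng)
            mol = Chem.MolFromSmiles(body)
            for t in carried:
                joined = _join(mol, tox_mols[t][0], rng)
                tries = 0
                while joined is None and tries < 50:
                    body = _assemble(scaffolds, avoid, rng)
                    mol = Chem.MolFromSmiles(body)
                    joined = _join(mol, tox_mols[t][0], rng)
                    tries += 1
                if joined is None:
                    raise RuntimeError("could not graft toxicophore")
                mol = joined
            smi = standardize_structure(Chem.MolToSmiles(mol))
        else:
            smi = _assemble(scaffolds, avoid, rng)
        rows.append(
            {
                "compound_id": f"CPD{i:05d}",
                "smiles": smi,
                "source": "DILIrank",
                "dili_class": "vMost" if label_pos else "vNo",
            }
        )
    return pd.DataFrame(rows)


def generate_feature_matrix(spec: SyntheticSpec, labels: np.ndarray):
    """Generate a binary target-prediction matrix with planted columns.

    Planted feature j has P(1|pos) − P(1|neg) = effect_j (base rate in the
    negative class); non-planted features are label-independent with a
    per-feature base probability drawn from U(0.05, 0.5).
    """
    import pandas as pd

    labels = np.asarray(labels)
    if labels.shape[0] != spec.n_pos + spec.n_neg:
        raise ValueError("labels length must equal n_pos + n_neg")
    rng = spec.rng("features")
    n, m = labels.shape[0], spec.n_target_features
    planted = dict(spec.planted_features)
    p = np.empty((n, m))
    base = rng.uniform(0.05, 0.5, size=m)
    for j in range(m):
        if j in planted:
            p[:, j] = np.where(labels == 1, spec.base_rate + planted[j], spec.base_rate)
        else:
            p[:, j] = base[j]
    x = (rng.random((n, m)) < p).astype(np.int8)
    cols = [f"T{j:04d}" for j in range(m)]
    return pd.DataFrame(x, columns=cols)


@dataclass(frozen=True)
class Geneset:
    name: str
    description: str
    members: tuple[str, ...]


def generate_genesets(spec: SyntheticSpec) -> list[Geneset]:
    """Generate a geneset collection containing one planted set plus decoys.

    The planted set holds exactly the planted feature names (padded with the
    lowest-index non-planted features if fewer than 10); random decoy sets of
    size 10–40 are drawn uniformly from all features.
    """
    rng = spec.rng("genesets")
    names = [f"T{j:04d}" for j in range(spec.n_target_features)]
    planted_idx = sorted(j for j, _ in spec.planted_features)
    members = [names[j] for j in planted_idx]
    if not members:
        raise ValueError("cannot build a planted geneset without planted features")
    pad = (j for j in range(spec.n_target_features) if j not in set(planted_idx))
    while len(members) < 10:
        members.append(names[next(pad)])
    sets = [Geneset("PLANTED_PATHWAY", "planted", tuple(members))]
    max_size = min(40, spec.n_target_features)
    for k in range(spec.genesets_n_random):
        size = int(rng.integers(10, max_size + 1))
        idx = rng.choice(spec.n_target_features, size=size, replace=False)
        sets.append(
            Geneset(
                f"RANDOM_SET_{k:03d}",
                "decoy",
                tuple(names[j] for j in sorted(idx)),
            )
        )
    return sets


def generate_catalog(spec: SyntheticSpec, n_compounds: int = 50):
    """Generate a decoy approved-drug catalog as a SMILES table.

    Roughly one in five catalog entries carries a planted toxicophore, so
    catalog screens have non-trivial hits (mirroring the observation that
    alerts occur in marketed drugs).
    """
    import pandas as pd

    rng = spec.rng("catalog")
    scaffolds = [_parse_fragment(s, "scaffold") for s in spec.scaffold_pool]
    tox = [_parse_fragment(p, "toxicophore") for p, _, _ in spec.toxicophores]
    avoid = [Chem.MolFromSmarts(p) for p, _, _ in spec.toxicophores]
    rows = []
    for i in range(n_compounds):
        if tox and rng.random() < 0.2:
            body = _assemble(scaffolds, avoid, rng)
            mol = Chem.MolFromSmiles(body)
            joined = _join(mol, tox[int(rng.integers(len(tox)))], rng)
            smi = (
                standardize_structure(Chem.MolToSmiles(joined))
                if joined is not None
                else body
            )
        else:
            smi = _assemble(scaffolds, avoid, rng)
        rows.append({"compound_id": f"DRUG{i:04d}", "smiles": smi})
    return pd.DataFrame(rows)


def write_gmt(sets: list[Geneset], path) -> None:
    """Serialize genesets to GMT (tab-separated: name, description, members)."""
    with open(path, "w") as fh:
        for s in sets:
            if not s.members:
                raise ValueError(f"empty geneset: {s.name}")
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def read_gmt(path) -> list[Geneset]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            sets.append(Geneset(parts[0], parts[1], tuple(parts[2:])))
    return sets
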