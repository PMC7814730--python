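"""Featurization: hashed circular fingerprints and external feature matrices.

ECFP4 here means an extended-connectivity fingerprint of diameter 4, i.e.
Morgan radius 2, folded to 2048 bits, binary presence. Continuous descriptor
matrices (e.g. physicochemical descriptors computed externally) are scaled to
zero mean / unit variance with a leakage-safe fit/apply contract: statistics
come from training rows only. Fingerprints and binary target matrices are
never scaled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

FP_BITS = 2048
FP_RADIUS = 2  # diameter 4

_generator = rdFingerprintGenerator.GetMorganGenerator(
    radius=FP_RADIUS, fpSize=FP_BITS
)


def fingerprint(smiles: str) -> np.ndarray:
    """Binary ECFP4 bit vector (length 2048) for a standardized SMILES.

    Canonicalization makes the result invariant to atom input order.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot fingerprint unparseable SMILES: {smiles!r}")
    fp = _generator.GetFingerprint(mol)
    arr = np.zeros(FP_BITS, dtype=np.uint8)
    for b in fp.GetOnBits():
        arr[b] = 1
    return arr


def fingerprint_matrix(smiles_list: Sequence[str], ids: Sequence[str] | None = None):
    """Fingerprint a compound list into a FeatureMatrix of kind 'fingerprint'."""
    x = np.stack([fingerprint(s) for s in smiles_list])
    if ids is None:
        ids = [str(i) for i in range(len(smiles_list))]
    return FeatureMatrix(
        compound_ids=list(ids),
        feature_names=[f"FP{j}" for j in range(FP_BITS)],
        values=x,
        kind="fingerprint",
    )


@dataclass
class FeatureMatrix:
    compound_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    kind: str  # fingerprint | descriptor_continuous | target_binary

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.compound_ids), len(self.feature_names)):
            raise ValueError("values shape inconsistent with ids/feature names")
        if np.isnan(self.values.astype(float)).any():
            raise ValueError("feature matrix contains missing values")
        if self.kind == "target_binary" and not np.isin(self.values, (0, 1)).all():
            raise ValueError("target_binary matrix must contain only 0/1 entries")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "compound_id", self.compound_ids)
        return df


class Scaler:
    """Zero-mean/unit-variance scaler with population (1/n) variance.

    Constant columns are mapped to zero rather than raising. fit() must only
    ever see training rows of a fold; apply() uses the stored training
    statistics unchanged.
    """

    def __init__(self):
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, matrix: FeatureMatrix) -> "Scaler":
        if matrix.kind != "descriptor_continuous":
            raise ValueError(f"scaling only applies to continuous descriptors, got {matrix.kind}")
        x = matrix.values.astype(float)
        self.mean_ = x.mean(axis=0)
        std = x.std(axis=0)  # population convention
        self.scale_ = np.where(std == 0.0, 1.0, std)
        return self

    def apply(self, matrix: FeatureMatrix) -> FeatureMatrix:
        if self.mean_ is None:
            raise RuntimeError("scaler has not been fitted")
        x = (matrix.values.astype(float) - self.mean_) / self.scale_
        return FeatureMatrix(
            matrix.compound_ids, matrix.feature_names, x, matrix.kind
        )


def fit_scaler(train: FeatureMatrix) -> Scaler:
    return Scaler().fit(train)


def apply_scaler(scaler: Scaler, matrix: FeatureMatrix) -> FeatureMatrix:
    return scaler.apply(matrix)


def load_feature_matrix(
    path, ids: Sequence[str], kind: str = "target_binary"
) -> tuple[FeatureMatrix, list[str]]:
    """Load a feature CSV (compound_id column + feature columns), aligned to
    the requested id order.

    Compounds absent from the file are dropped from modeling; the returned
    second element lists them so callers can log the loss (in the source
    study 6 of 923 drugs lacked target predictions).
    """
    df = pd.read_csv(path, dtype={"compound_id": str})
    if "compound_id" not in df.columns:
        raise ValueError("feature CSV must contain a compound_id column")
    if df["compound_id"].duplicated().any():
        dupes = df.loc[df["compound_id"].duplicated(), "compound_id"].tolist()
        raise ValueError(f"duplicate compound ids in feature file: {dupes}")
    df = df.set_index("compound_id")
    present = [i for i in ids if i in df.index]
    missing = [i for i in ids if i not in df.index]
    sub = df.loc[present]
    return (
        FeatureMatrix(present, list(sub.columns), sub.to_numpy(), kind),
        missing,
    )
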