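"""Structural-diversity statistic D(A) over a compound set.

D(A) is the mean pairwise dissimilarity

    D(A) = sum_{i != j} diss(i, j) / (N (N - 1))

over all ordered pairs of the N compounds.  The default dissimilarity is
1 - Tanimoto on hashed linear-path fingerprints (path lengths 1-7, 2048
bits); any user-supplied square dissimilarity matrix is accepted instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemio import Molecule, to_rdkit

FP_BITS = 2048
FP_MIN_PATH = 1
FP_MAX_PATH = 7


def fingerprint(mol: Molecule) -> frozenset[int]:
    """Deterministic hashed linear-path fingerprint as a set of on-bits."""
    rd = to_rdkit(mol)
    bv = Chem.RDKFingerprint(
        rd, minPath=FP_MIN_PATH, maxPath=FP_MAX_PATH, fpSize=FP_BITS,
        branchedPaths=False,
    )
    return frozenset(bv.GetOnBits())


def dissimilarity(a: frozenset[int], b: frozenset[int]) -> float:
    """1 - Tanimoto; two empty sets are identical by convention (0.0)."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return 1.0 - len(a & b) / union


@dataclass(frozen=True)
class DissimilarityMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.ids):
            raise ValueError("dissimilarity matrix must be square over ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(m) != 0.0):
            raise ValueError("dissimilarity diagonal must be zero")
        if m.min() < -1e-12 or m.max() > 1.0 + 1e-12:
            raise ValueError("dissimilarities must lie in [0, 1]")


def pairwise_matrix(mols: Sequence[Molecule]) -> DissimilarityMatrix:
    fps = [fingerprint(m) for m in mols]
    n = len(fps)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = dissimilarity(fps[i], fps[j])
    return DissimilarityMatrix([m.id for m in mols], mat)


def diversity_score(obj) -> float:
    """D(A) of a molecule sequence or a precomputed DissimilarityMatrix."""
    if isinstance(obj, DissimilarityMatrix):
        dm = obj
    else:
        mols = list(obj)
        if len(mols) < 2:
            raise ValueError("diversity needs at least two compounds")
        dm = pairwise_matrix(mols)
    n = len(dm.ids)
    if n < 2:
        raise ValueError("diversity needs at least two compounds")
    return float(dm.matrix.sum() / (n * (n - 1)))


def read_matrix_csv(path) -> DissimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    return DissimilarityMatrix(list(df.index.astype(str)), df.to_numpy(float))


def write_matrix_csv(dm: DissimilarityMatrix, path) -> None:
    pd.DataFrame(dm.matrix, index=dm.ids, columns=dm.ids).to_csv(path)
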