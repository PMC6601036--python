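"""Synthetic fixtures: labeled descriptor datasets and toy molecule libraries.

The proprietary training collections behind the original activity model
(commercial inhibitor and drug-report databases) are not redistributable,
so every pipeline stage is exercised on generated stand-ins:

* :func:`gen_dataset` draws two multivariate-Gaussian classes labeled ±1
  whose means differ by a stated separation (in pooled-sd units) on a
  chosen number of informative features — the simplest structure with a
  closed-form Bayes error against which classifier accuracy can be judged.
* :func:`gen_library` enumerates substituted analogs of one scaffold,
  emulating the scaffold redundancy of real vendor screening libraries
  (low internal diversity relative to a set of unrelated drugs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chemio import Molecule, read_smiles, standardize
from .ml.data import LabeledDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the two-class Gaussian benchmark.

    ``separation`` is the class-mean distance per informative feature in
    pooled-sd units; with identity covariance and one informative feature
    the Bayes error is Phi(-separation/2).
    """

    n_per_class: int = 500
    p: int = 10
    separation: float = 4.0
    covariance: str = "identity"  # "identity" | "equicorrelated"
    rho: float = 0.0
    informative: int = 1
    heavy_tails: bool = False     # Student-t (df=5) scaled to unit variance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("need at least 2 samples per class")
        if not 1 <= self.informative <= self.p:
            raise ValueError("informative count must lie in [1, p]")
        if self.covariance not in ("identity", "equicorrelated"):
            raise ValueError("unknown covariance tag")


def gen_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Draw the two-class benchmark; reproducible by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_per_class, spec.p
    if spec.heavy_tails:
        df = 5
        z = rng.standard_t(df, size=(2 * n, p)) * np.sqrt((df - 2) / df)
    else:
        z = rng.standard_normal((2 * n, p))
    if spec.covariance == "equicorrelated" and spec.rho != 0.0:
        cov = np.full((p, p), spec.rho)
        np.fill_diagonal(cov, 1.0)
        z = z @ np.linalg.cholesky(cov).T
    mean = np.zeros(p)
    mean[: spec.informative] = spec.separation / 2.0
    X = np.vstack([z[:n] + mean, z[n:] - mean])
    y = np.concatenate([np.ones(n, int), -np.ones(n, int)])
    ids = [f"pos{i}" for i in range(n)] + [f"neg{i}" for i in range(n)]
    return LabeledDataset(ids, X, y, [f"f{j}" for j in range(p)])


def bayes_error(spec: SyntheticSpec) -> float:
    """Closed-form Gaussian overlap error for the identity-covariance case."""
    from scipy.stats import norm

    d_eff = spec.separation * np.sqrt(spec.informative)
    return float(norm.cdf(-d_eff / 2.0))


ATTACHMENT = "[*:1]"


def gen_library(
    scaffold: str, substituents: Sequence[str], n: int | None = None
) -> list[Molecule]:
    """Enumerate analogs of a scaffold at its marked attachment point.

    ``scaffold`` is a SMILES containing one ``[*:1]`` dummy; substituents
    are fragment SMILES (a bare fragment like ``F`` gets the matching
    dummy prepended).  Invalid combinations are skipped with a diagnostic;
    duplicates (by canonical SMILES) are removed.  With no substituents
    the bare scaffold (dummy replaced by hydrogen) is returned.
    """
    core = Chem.MolFromSmiles(scaffold)
    if core is None or not any(a.GetAtomicNum() == 0 for a in core.GetAtoms()):
        raise ValueError("scaffold must be valid SMILES with a [*:1] attachment")
    out: list[Molecule] = []
    seen: set[str] = set()

    def add(rd: Chem.Mol, mol_id: str) -> None:
        smi = Chem.MolToSmiles(rd)
        if smi in seen:
            return
        seen.add(smi)
        out.append(standardize(read_smiles(smi, mol_id)))

    if not substituents:
        bare = Chem.ReplaceSubstructs(
            core, Chem.MolFromSmarts("[#0]"), Chem.MolFromSmiles("[H]"),
            replaceAll=True,
        )[0]
        bare = Chem.RemoveHs(bare)
        Chem.SanitizeMol(bare)
        add(bare, "scaffold")
        return out
    for k, sub in enumerate(substituents):
        frag_smi = sub if "*" in sub else ATTACHMENT + sub
        frag = Chem.MolFromSmiles(frag_smi)
        if frag is None:
            logger.warning("substituent %r invalid, skipped", sub)
            continue
        try:
            combined = Chem.molzip(Chem.CombineMols(core, frag))
            Chem.SanitizeMol(combined)
        except Exception as exc:
            logger.warning("cannot attach %r: %s", sub, exc)
            continue
        add(combined, f"analog{k}")
        if n is not None and len(out) >= n:
            break
    return out
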