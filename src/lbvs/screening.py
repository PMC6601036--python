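"""Library screening: score, rank, threshold, and energy-filter hits.

A trained model scores every library molecule with its relative
probability of activity; molecules scoring strictly above the retention
threshold (default 0.7) become ranked hits.  Docking binding energies
produced externally can then be imported from CSV and hits strictly below
the energy cutoff (default -10.0 kcal/mol) retained, lowest energy first.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chemio import Molecule, canonical_smiles, write_sdf
from .descriptors import DEFAULT_REGISTRY, DescriptorError, DescriptorRegistry, compute_all
from .ml.data import LabeledDataset, Scaler

logger = logging.getLogger(__name__)

SCORE_THRESHOLD = 0.7
ENERGY_CUTOFF = -10.0  # kcal/mol

#: Receptor grid-box parameters recorded for users running an external
#: docking program; no docking is performed here.
DOCKING_BOX = {
    "size_x": 16.0, "size_y": 16.0, "size_z": 16.0,
    "center_x": 22.599, "center_y": -2.481, "center_z": 28.0,
}


@dataclass(frozen=True)
class ScreeningHit:
    mol_id: str
    smiles: str
    score: float
    rank: int
    energy: float | None = None


def _score_matrix(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "scores"):  # random forest
        return model.scores(X)
    from .ml.c45 import C45Model, c45_predict
    from .ml.knn import KNNModel, knn_predict
    from .ml.svm import SVMModel, svm_predict

    if isinstance(model, KNNModel):
        preds = knn_predict(model, X)
    elif isinstance(model, C45Model):
        preds = c45_predict(model, X)
    elif isinstance(model, SVMModel):
        preds = svm_predict(model, X)
    else:
        raise TypeError(f"cannot score with model of type {type(model)!r}")
    return np.array([p.score for p in preds])


def screen_library(
    model,
    library: Sequence[Molecule],
    threshold: float = SCORE_THRESHOLD,
    registry: DescriptorRegistry = DEFAULT_REGISTRY,
    scaler: Scaler | None = None,
    impute: np.ndarray | None = None,
) -> tuple[list[ScreeningHit], int]:
    """Score a library and keep molecules with score strictly > threshold.

    Returns the descending-score ranked hit list and the number of
    molecules excluded because their descriptors could not be computed.
    Missing descriptor values are replaced by ``impute`` (per-registry-column
    fill values, e.g. training medians) or 0.  ``scaler`` applies the
    training standardization for distance-based models.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    rows, ids, smiles = [], [], []
    failed = 0
    for mol in library:
        try:
            dv = compute_all(mol, registry)
        except DescriptorError as exc:
            failed += 1
            logger.warning("excluded from screen: %s", exc)
            continue
        vals = dv.values.copy()
        fill = impute if impute is not None else np.zeros(len(registry))
        vals[dv.mask] = np.asarray(fill)[dv.mask]
        rows.append(vals)
        ids.append(mol.id)
        smiles.append(mol.smiles or canonical_smiles(mol))
    if not rows:
        return [], failed
    X = np.asarray(rows)
    if scaler is not None:
        X = (X[:, scaler.kept] - scaler.mean) / scaler.sd
    scores = _score_matrix(model, X)
    order = np.argsort(-scores, kind="stable")
    hits = []
    rank = 0
    for idx in order:
        if scores[idx] > threshold:
            rank += 1
            hits.append(
                ScreeningHit(ids[idx], smiles[idx], float(scores[idx]), rank)
            )
    return hits, failed


def load_energies(path) -> dict[str, float]:
    """Read an id,energy CSV; unparseable rows are logged and skipped.

    A duplicated id keeps the last value (with a warning).
    """
    energies: dict[str, float] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for ln, row in enumerate(reader, 1):
            if not row or row[0].strip().lower() in ("id", "name"):
                continue
            if len(row) < 2:
                logger.warning("energies line %d: too few columns, skipped", ln)
                continue
            mol_id = row[0].strip()
            try:
                e = float(row[1])
            except ValueError:
                logger.warning("energies line %d: non-numeric energy, skipped", ln)
                continue
            if mol_id in energies:
                logger.warning("duplicate energy for %s: last value wins", mol_id)
            energies[mol_id] = e
    return energies


def filter_by_energy(
    hits: Sequence[ScreeningHit],
    energies: Mapping[str, float],
    cutoff: float = ENERGY_CUTOFF,
) -> tuple[list[ScreeningHit], int]:
    """Keep hits with binding energy strictly below the cutoff.

    Retained hits are re-ranked ascending by energy (most negative first:
    the lower the binding energy, the more stable the complex).  Hits with
    no energy entry are excluded and counted in the second return value.
    """
    if not np.isfinite(cutoff):
        raise ValueError("energy cutoff must be finite")
    missing = 0
    kept = []
    for h in hits:
        e = energies.get(h.mol_id)
        if e is None:
            missing += 1
            continue
        if e < cutoff:
            kept.append(replace(h, energy=float(e)))
    kept.sort(key=lambda h: (h.energy, h.mol_id))
    kept = [replace(h, rank=i + 1) for i, h in enumerate(kept)]
    return kept, missing


def write_hits_csv(hits: Iterable[ScreeningHit], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "smiles", "score", "rank", "energy"])
        for h in hits:
            w.writerow([h.mol_id, h.smiles, f"{h.score:.6f}", h.rank,
                        "" if h.energy is None else h.energy])


def write_hits_sdf(
    hits: Sequence[ScreeningHit], library: Sequence[Molecule], path
) -> None:
    by_id = {m.id: m for m in library}
    write_sdf([by_id[h.mol_id] for h in hits if h.mol_id in by_id], path)
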