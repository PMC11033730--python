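"""Label curation: assemble the positive / negative anti-cancer dataset.

Positives are drugs with documented anti-cancer activity.  Negatives are
approved drugs that were never examined in a cancer trial AND are not
chemically similar (Tanimoto above a threshold, default 0.7) to any
cancer-associated drug.  An optional override map stands in for manual
expert validation of the automatic labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .chem import Molecule, fingerprint_library, tanimoto

logger = logging.getLogger(__name__)

DEFAULT_SIMILARITY_THRESHOLD = 0.7


class DuplicateIdError(ValueError):
    pass


@dataclass(frozen=True)
class CatalogueEntry:
    molecule: Molecule
    approved: bool
    in_cancer_trial: bool
    known_anticancer: bool


@dataclass
class LabeledDataset:
    """Curated binary dataset: molecules, 0/1 labels and provenance tags."""

    molecules: list[Molecule]
    labels: dict[str, int]
    provenance: dict[str, str]

    def __post_init__(self) -> None:
        ids = {m.id for m in self.molecules}
        if set(self.labels) != ids:
            raise ValueError("label ids do not match molecule ids")
        pos = {i for i, y in self.labels.items() if y == 1}
        neg = {i for i, y in self.labels.items() if y == 0}
        if pos & neg:  # pragma: no cover - labels map cannot overlap
            raise ValueError("positive and negative id sets overlap")

    @property
    def n_pos(self) -> int:
        return sum(1 for y in self.labels.values() if y == 1)

    @property
    def n_neg(self) -> int:
        return sum(1 for y in self.labels.values() if y == 0)

    def molecule(self, drug_id: str) -> Molecule:
        for m in self.molecules:
            if m.id == drug_id:
                return m
        raise KeyError(drug_id)


def _check_unique_ids(catalogue: Sequence[CatalogueEntry]) -> None:
    seen: dict[str, CatalogueEntry] = {}
    for entry in catalogue:
        prior = seen.get(entry.molecule.id)
        if prior is not None and prior != entry:
            raise DuplicateIdError(
                f"catalogue id {entry.molecule.id!r} appears with conflicting records"
            )
        seen[entry.molecule.id] = entry


def assemble_positives(catalogue: Sequence[CatalogueEntry]) -> set[str]:
    """Ids of all catalogue entries flagged with known anti-cancer activity."""
    if not catalogue:
        raise ValueError("catalogue is empty")
    _check_unique_ids(catalogue)
    return {e.molecule.id for e in catalogue if e.known_anticancer}


def assemble_negatives(
    catalogue: Sequence[CatalogueEntry],
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    *,
    exclude_similar_to_positives: bool = True,
) -> set[str]:
    """Ids of approved drugs that survive the cancer-association filters.

    A drug qualifies as negative when it is approved, not itself
    cancer-associated (neither flagged anti-cancer nor in a cancer trial),
    and its maximal Tanimoto similarity to every cancer-associated drug is
    strictly below ``threshold``.

    ``exclude_similar_to_positives`` controls whether the similarity screen
    compares against trial drugs only or against the union of trial drugs
    and known positives (default: the union, since every positive is
    cancer-associated by definition).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    _check_unique_ids(catalogue)
    excluded_ref = [
        e.molecule
        for e in catalogue
        if e.in_cancer_trial or (exclude_similar_to_positives and e.known_anticancer)
    ]
    ref_fps = fingerprint_library(excluded_ref)
    fps = fingerprint_library(e.molecule for e in catalogue)

    negatives: set[str] = set()
    for entry in catalogue:
        if not entry.approved or entry.known_anticancer or entry.in_cancer_trial:
            continue
        qfp = fps[entry.molecule.id]
        max_sim = max(
            (tanimoto(qfp, ref_fps[m.id]) for m in excluded_ref if m.id != entry.molecule.id),
            default=0.0,
        )
        if max_sim < threshold:
            negatives.add(entry.molecule.id)
    return negatives


def build_dataset(
    catalogue: Sequence[CatalogueEntry],
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    *,
    exclude_similar_to_positives: bool = True,
    override: Optional[Mapping[str, int]] = None,
) -> LabeledDataset:
    """Compose positives and negatives into a labeled dataset.

    ``override`` forces labels for specific ids after automatic curation;
    it is the reproducible stand-in for manual expert validation.  Override
    ids absent from the curated set are ignored with a warning.
    """
    positives = assemble_positives(catalogue)
    negatives = assemble_negatives(
        catalogue, threshold, exclude_similar_to_positives=exclude_similar_to_positives
    )
    if positives & negatives:  # pragma: no cover - construction forbids this
        raise ValueError("internal consistency error: id labeled both 0 and 1")
    if not positives:
        logger.warning("curated dataset contains zero positive drugs")

    by_id = {e.molecule.id: e.molecule for e in catalogue}
    labels: dict[str, int] = {}
    provenance: dict[str, str] = {}
    for i in sorted(positives):
        labels[i] = 1
        provenance[i] = "known_anticancer"
    for i in sorted(negatives):
        labels[i] = 0
        provenance[i] = "approved_no_cancer_association"
    if override:
        for i, forced in override.items():
            if i not in by_id:
                logger.warning("override id %r not in catalogue; ignored", i)
                continue
            labels[i] = int(forced)
            provenance[i] = "manual_override"
    molecules = [by_id[i] for i in sorted(labels)]
    return LabeledDataset(molecules=molecules, labels=labels, provenance=provenance)
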