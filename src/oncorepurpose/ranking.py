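"""Whole-library scoring, ranking and exclusion bookkeeping.

A trained ensemble scores every molecule in a candidate library; entries
are listed by descending score with competition ranks (1 + number of
strictly greater scores, so ties share a rank).  Drugs with documented
anti-cancer activity are flagged as excluded but keep their rank, so the
published rank of an excluded drug remains meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

from .chem import Molecule
from .features import AuxiliaryFeatures
from .models import TrainedEnsemble, predict

logger = logging.getLogger(__name__)

EXCLUSION_REASON = "documented anti-cancer activity"


@dataclass(frozen=True)
class RankedEntry:
    rank: int
    drug_id: str
    score: float
    excluded: bool = False
    exclusion_reason: Optional[str] = None


@dataclass
class RankedList:
    entries: list[RankedEntry]

    def entry(self, drug_id: str) -> RankedEntry:
        for e in self.entries:
            if e.drug_id == drug_id:
                return e
        raise KeyError(drug_id)

    def rank_of(self, drug_id: str) -> int:
        return self.entry(drug_id).rank


def rank_library(
    ensemble: TrainedEnsemble,
    library: Sequence[Molecule],
    features: Optional[Mapping[str, AuxiliaryFeatures]] = None,
) -> RankedList:
    """Score and rank a molecule library with a trained ensemble.

    Entries are ordered by descending score, ties broken by id.  The rank
    of an entry is 1 + the count of strictly greater scores (competition
    ranking), so tied drugs share a rank.
    """
    if not library:
        raise ValueError("library is empty")
    preds = predict(ensemble, library, features)
    ordered = sorted(preds.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    entries = []
    for pos, (drug_id, score) in enumerate(ordered):
        rank = 1 + sum(1 for _, s in ordered if s > score)
        entries.append(RankedEntry(rank=rank, drug_id=drug_id, score=score))
    return RankedList(entries=entries)


def apply_exclusions(ranked: RankedList, known_actives: set[str]) -> RankedList:
    """Flag entries with documented anti-cancer activity; order and ranks
    are unchanged.  Unknown ids in the exclusion set are ignored with a
    warning."""
    listed = {e.drug_id for e in ranked.entries}
    missing = known_actives - listed
    if missing:
        logger.warning("exclusion ids not in ranked list: %s", sorted(missing))
    entries = [
        replace(e, excluded=True, exclusion_reason=EXCLUSION_REASON)
        if e.drug_id in known_actives
        else e
        for e in ranked.entries
    ]
    return RankedList(entries=entries)
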