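"""Readers and writers for the pipeline's plain-text exchange formats.

Molecule tables and catalogues are CSV; feature tables, split plans and
ranked lists are TSV.  Interaction-matrix I/O lives in
:mod:`oncorepurpose.matrices`.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import InvalidMoleculeError, Molecule
from .curation import CatalogueEntry, LabeledDataset
from .evaluation import SplitPlan
from .features import AuxiliaryFeatures, Provenance
from .ranking import RankedList

logger = logging.getLogger(__name__)


def read_molecules(path: str | Path, drop_invalid: bool = True) -> list[Molecule]:
    """Read a molecule table (`id,smiles[,name]`).  Unparseable SMILES are
    dropped with a warning (catalogues contain biologics without usable
    SMILES) unless ``drop_invalid`` is false."""
    df = pd.read_csv(path, dtype=str)
    out = []
    for _, row in df.iterrows():
        try:
            out.append(Molecule(id=row["id"], smiles=row["smiles"],
                                name=row.get("name")))
        except InvalidMoleculeError:
            if not drop_invalid:
                raise
            logger.warning("dropping molecule %r: invalid SMILES %r",
                           row["id"], row["smiles"])
    return out


def write_molecules(mols: Sequence[Molecule], path: str | Path) -> None:
    pd.DataFrame(
        {"id": [m.id for m in mols], "smiles": [m.smiles for m in mols]}
    ).to_csv(path, index=False)


def read_catalogue(path: str | Path) -> list[CatalogueEntry]:
    """Catalogue CSV: `id,smiles,approved,in_cancer_trial,known_anticancer`
    with 0/1 flags."""
    df = pd.read_csv(path, dtype={"id": str, "smiles": str})
    out = []
    for _, row in df.iterrows():
        try:
            mol = Molecule(id=row["id"], smiles=row["smiles"])
        except InvalidMoleculeError:
            logger.warning("dropping catalogue entry %r: invalid SMILES", row["id"])
            continue
        out.append(CatalogueEntry(
            molecule=mol,
            approved=bool(int(row["approved"])),
            in_cancer_trial=bool(int(row["in_cancer_trial"])),
            known_anticancer=bool(int(row["known_anticancer"])),
        ))
    return out


def write_catalogue(entries: Sequence[CatalogueEntry], path: str | Path) -> None:
    pd.DataFrame({
        "id": [e.molecule.id for e in entries],
        "smiles": [e.molecule.smiles for e in entries],
        "approved": [int(e.approved) for e in entries],
        "in_cancer_trial": [int(e.in_cancer_trial) for e in entries],
        "known_anticancer": [int(e.known_anticancer) for e in entries],
    }).to_csv(path, index=False)


def write_dataset(dataset: LabeledDataset, path: str | Path) -> None:
    """Curated dataset CSV: `id,smiles,label,provenance`."""
    rows = [
        (m.id, m.smiles, dataset.labels[m.id], dataset.provenance[m.id])
        for m in dataset.molecules
    ]
    pd.DataFrame(rows, columns=["id", "smiles", "label", "provenance"]).to_csv(
        path, index=False
    )


def read_dataset(path: str | Path) -> LabeledDataset:
    df = pd.read_csv(path, dtype={"id": str, "smiles": str})
    mols = [Molecule(id=r["id"], smiles=r["smiles"]) for _, r in df.iterrows()]
    return LabeledDataset(
        molecules=mols,
        labels={r["id"]: int(r["label"]) for _, r in df.iterrows()},
        provenance={r["id"]: str(r["provenance"]) for _, r in df.iterrows()},
    )


def write_labels(labels: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(sorted(labels.items()), columns=["id", "label"]).to_csv(
        path, index=False
    )


def write_feature_table(
    table: Mapping[str, AuxiliaryFeatures], path: str | Path
) -> None:
    """TSV: id, the numeric feature columns, then the two provenance tags."""
    rows = []
    for drug_id in sorted(table):
        feats = table[drug_id]
        rows.append(
            [drug_id, *feats.vector.tolist(),
             str(feats.dti_provenance), str(feats.ddi_provenance)]
        )
    n_dti = len(next(iter(table.values())).dti_block)
    n_ddi = len(next(iter(table.values())).ddi_block)
    cols = (
        ["id"]
        + [f"dti_{i}" for i in range(n_dti)]
        + [f"ddi_{i}" for i in range(n_ddi)]
        + ["dti_provenance", "ddi_provenance"]
    )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> dict[str, AuxiliaryFeatures]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    dti_cols = [c for c in df.columns if c.startswith("dti_") and c != "dti_provenance"]
    ddi_cols = [c for c in df.columns if c.startswith("ddi_") and c != "ddi_provenance"]

    def parse_prov(text: str) -> Provenance:
        if text.startswith("neighbor("):
            inner = text[len("neighbor(") : -1]
            nid, sim = inner.rsplit(",", 1)
            return Provenance("neighbor", nid, float(sim))
        return Provenance(text)

    out = {}
    for _, row in df.iterrows():
        out[row["id"]] = AuxiliaryFeatures(
            drug_id=row["id"],
            dti_block=row[dti_cols].to_numpy(dtype=float),
            ddi_block=row[ddi_cols].to_numpy(dtype=float),
            dti_provenance=parse_prov(row["dti_provenance"]),
            ddi_provenance=parse_prov(row["ddi_provenance"]),
        )
    return out


def write_split_plan(plan: SplitPlan, path: str | Path) -> None:
    """TSV: `id<TAB>partition<TAB>scaffold`."""
    rows = [
        (i, plan.assignment[i], plan.scaffold_of[i]) for i in sorted(plan.assignment)
    ]
    pd.DataFrame(rows, columns=["id", "partition", "scaffold"]).to_csv(
        path, sep="\t", index=False
    )


def write_ranked_list(ranked: RankedList, path: str | Path) -> None:
    """TSV: `rank<TAB>id<TAB>score<TAB>excluded<TAB>reason`."""
    rows = [
        (e.rank, e.drug_id, e.score, int(e.excluded), e.exclusion_reason or "")
        for e in ranked.entries
    ]
    pd.DataFrame(rows, columns=["rank", "id", "score", "excluded", "reason"]).to_csv(
        path, sep="\t", index=False
    )


def read_override(path: Optional[str | Path]) -> Optional[dict[str, int]]:
    """Optional manual-label override CSV: `id,label`."""
    if path is None:
        return None
    df = pd.read_csv(path, dtype={"id": str})
    return {r["id"]: int(r["label"]) for _, r in df.iterrows()}
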