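"""Dense per-drug features from sparse interaction matrices.

Two compression routes, mirroring the pipeline's feature-engineering stage:

* DTI (drugs x targets, binary) -> PCA to a low-dimensional drug
  representation (default 64 components, mean-centered, unscaled).
* DDI (drugs x drugs, symmetric binary adjacency) -> adjacency matrix
  factorization with propagation (AMFP): logistic matrix factorization with
  per-node biases, followed by one step of neighbor-mean smoothing of the
  embeddings (default 256 dimensions).

Drugs absent from a matrix get features imputed from their chemically most
similar neighbour (Tanimoto >= threshold, default 0.7) or, failing that,
the element-wise average block.  The two blocks are imputed independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .chem import Molecule, SimilarityHit, fingerprint_library, most_similar
from .matrices import InteractionMatrix

logger = logging.getLogger(__name__)

DEFAULT_PCA_DIM = 64
DEFAULT_AMFP_DIM = 256
DEFAULT_IMPUTE_THRESHOLD = 0.7


class DegenerateInputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PCA over the DTI matrix
# ---------------------------------------------------------------------------

@dataclass
class PcaModel:
    """Principal axes of the mean-centered drug x target matrix."""

    mean: np.ndarray                   # (n_targets,)
    components: np.ndarray             # (k, n_targets), orthonormal rows
    explained_variance_ratio: np.ndarray  # (k,), non-increasing

    @property
    def k(self) -> int:
        return self.components.shape[0]


def fit_pca(dti: InteractionMatrix, k: int = DEFAULT_PCA_DIM) -> PcaModel:
    """Fit the top-*k* principal axes of the DTI matrix (drugs as samples).

    Inputs are binary, so no scaling or whitening is applied — only mean
    centering.  The cumulative explained-variance ratio is logged.
    """
    if dti.kind != "DTI":
        raise ValueError("fit_pca expects a DTI matrix")
    n_drugs, n_targets = dti.shape
    if k > min(n_drugs, n_targets):
        raise ValueError(f"k={k} exceeds min(#drugs, #targets)={min(n_drugs, n_targets)}")
    dense = dti.dense()
    if not dense.any():
        raise DegenerateInputError("all-zero DTI matrix")
    pca = PCA(n_components=k, svd_solver="full", whiten=False)
    pca.fit(dense)
    cum = float(np.sum(pca.explained_variance_ratio_))
    logger.info("PCA: %d -> %d dims, cumulative explained variance %.3f",
                n_targets, k, cum)
    return PcaModel(
        mean=pca.mean_,
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def pca_project(model: PcaModel, drug_row: np.ndarray) -> np.ndarray:
    """Project one binary target-profile row onto the principal axes."""
    drug_row = np.asarray(drug_row, dtype=float).ravel()
    if drug_row.shape[0] != model.mean.shape[0]:
        raise ValueError(
            f"row length {drug_row.shape[0]} does not match target space "
            f"{model.mean.shape[0]}"
        )
    return model.components @ (drug_row - model.mean)


# ---------------------------------------------------------------------------
# AMFP over the DDI adjacency
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))




@dataclass
class AmfpModel:
    """Factorized DDI embedding with one-step neighbor-mean propagation.

    ``embeddings`` are the propagated vectors z_i = (1-a) u_i + a mean_j u_j
    over neighbors j; ``raw_embeddings`` are the factorization vectors u_i.
    Reconstruction: P(edge i,j) = sigmoid(z_i . z_j + b_i + b_j + c).
    """

    embeddings: np.ndarray        # (n, d) propagated
    raw_embeddings: np.ndarray    # (n, d)
    bias: np.ndarray              # (n,)
    global_bias: float
    propagation_weight: float
    trained_ids: list[str]
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {t: i for i, t in enumerate(self.trained_ids)}

    @property
    def d(self) -> int:
        return self.embeddings.shape[1]

    def embedding(self, drug_id: str) -> np.ndarray:
        if drug_id not in self._index:
            raise KeyError(drug_id)
        return self.embeddings[self._index[drug_id]]


def fit_amfp(
    ddi: InteractionMatrix,
    d: int = DEFAULT_AMFP_DIM,
    epochs: int = 100,
    learning_rate: float = 0.01,
    negative_ratio: float = 1.0,
    propagation_weight: float = 0.5,
    seed: int = 0,
) -> AmfpModel:
    """Fit logistic matrix factorization with biases on the DDI adjacency.

    Each epoch takes one full-batch Adam step on the logistic reconstruction
    loss over all observed edges plus ``negative_ratio`` freshly sampled
    non-edges per edge.  After optimization the embeddings are smoothed one
    step toward the neighbor mean with weight ``propagation_weight``;
    isolated nodes keep their raw embedding.  Fully seeded.
    """
    if ddi.kind != "DDI":
        raise ValueError("fit_amfp expects a DDI matrix")
    if d < 1:
        raise ValueError("embedding dimension must be >= 1")
    n = len(ddi.row_ids)
    coo = ddi.matrix.tocoo()
    upper = coo.row < coo.col
    pos_i = coo.row[upper].astype(np.int64)
    pos_j = coo.col[upper].astype(np.int64)
    n_edges = pos_i.size
    if n_edges == 0:
        raise DegenerateInputError("DDI graph has no edges")
    if d >= n:
        logger.warning("AMFP over-parameterized: d=%d >= #drugs=%d", d, n)

    rng = np.random.default_rng(seed)
    U = rng.normal(0.0, 0.1, size=(n, d))
    b = np.zeros(n)
    density = 2.0 * n_edges / (n * (n - 1)) if n > 1 else 0.5
    c = float(np.log(density / (1.0 - density)))

    edge_codes = np.sort(coo.row.astype(np.int64) * n + coo.col.astype(np.int64))
    n_neg = max(1, int(round(negative_ratio * n_edges)))

    # Adam state
    mU = np.zeros_like(U); vU = np.zeros_like(U)
    mb = np.zeros_like(b); vb = np.zeros_like(b)
    mc = 0.0; vc = 0.0
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    for epoch in range(1, epochs + 1):
        neg_i = rng.integers(0, n, size=2 * n_neg)
        neg_j = rng.integers(0, n, size=2 * n_neg)
        keep = neg_i != neg_j
        codes = neg_i * n + neg_j
        pos = np.searchsorted(edge_codes, codes)
        pos = np.minimum(pos, edge_codes.size - 1)
        keep &= edge_codes[pos] != codes
        neg_i, neg_j = neg_i[keep][:n_neg], neg_j[keep][:n_neg]

        ii = np.concatenate([pos_i, neg_i])
        jj = np.concatenate([pos_j, neg_j])
        yy = np.concatenate([np.ones(pos_i.size), np.zeros(neg_i.size)])

        logits = np.einsum("ij,ij->i", U[ii], U[jj]) + b[ii] + b[jj] + c
        p = _sigmoid(logits)
        g = (p - yy) / yy.size  # d(mean BCE)/d(logit)

        # d(loss)/dU = A_g @ U with A_g sparse, entries g at (i,j) and (j,i)
        A = sp.coo_matrix(
            (np.concatenate([g, g]),
             (np.concatenate([ii, jj]), np.concatenate([jj, ii]))),
            shape=(n, n),
        ).tocsr()
        gU = A @ U
        gb = np.bincount(ii, weights=g, minlength=n)
        gb += np.bincount(jj, weights=g, minlength=n)
        gc = float(np.sum(g))

        t = epoch
        for param, grad, mom, vel in ((U, gU, mU, vU), (b, gb, mb, vb)):
            mom *= beta1; mom += (1 - beta1) * grad
            vel *= beta2; vel += (1 - beta2) * grad * grad
            mhat = mom / (1 - beta1 ** t)
            vhat = vel / (1 - beta2 ** t)
            param -= learning_rate * mhat / (np.sqrt(vhat) + eps)
        mc = beta1 * mc + (1 - beta1) * gc
        vc = beta2 * vc + (1 - beta2) * gc * gc
        c -= learning_rate * (mc / (1 - beta1 ** t)) / (np.sqrt(vc / (1 - beta2 ** t)) + eps)

    # one-step neighbor-mean propagation
    deg = np.asarray(ddi.matrix.sum(axis=1)).ravel()
    neighbor_mean = ddi.matrix @ U
    with np.errstate(invalid="ignore", divide="ignore"):
        neighbor_mean = np.where(deg[:, None] > 0, neighbor_mean / np.maximum(deg, 1)[:, None], U)
    a = propagation_weight
    Z = np.where(deg[:, None] > 0, (1.0 - a) * U + a * neighbor_mean, U)

    return AmfpModel(
        embeddings=Z,
        raw_embeddings=U,
        bias=b,
        global_bias=float(c),
        propagation_weight=a,
        trained_ids=list(ddi.row_ids),
    )


def amfp_score(model: AmfpModel, i: str, j: str) -> float:
    """Reconstructed interaction probability for drug pair (i, j); symmetric."""
    zi = model.embedding(i)
    zj = model.embedding(j)
    bi = model.bias[model._index[i]]
    bj = model.bias[model._index[j]]
    return float(_sigmoid(np.array(zi @ zj + bi + bj + model.global_bias)))


# ---------------------------------------------------------------------------
# Imputation and the per-drug feature table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Provenance:
    """How one feature block was obtained for one drug."""

    mode: str  # "direct" | "neighbor" | "average"
    neighbor_id: Optional[str] = None
    similarity: Optional[float] = None

    def __str__(self) -> str:
        if self.mode == "neighbor":
            return f"neighbor({self.neighbor_id},{self.similarity:.3f})"
        return self.mode


@dataclass
class AuxiliaryFeatures:
    """Concatenated DTI + DDI feature record for one drug (default 64+256)."""

    drug_id: str
    dti_block: np.ndarray
    ddi_block: np.ndarray
    dti_provenance: Provenance
    ddi_provenance: Provenance

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.dti_block, self.ddi_block])


def _impute_block(
    drug: Molecule,
    block_store: Mapping[str, np.ndarray],
    library: Sequence[Molecule],
    threshold: float,
    fp_cache: Optional[dict] = None,
) -> tuple[np.ndarray, Provenance]:
    if drug.id in block_store:
        return np.asarray(block_store[drug.id], dtype=float), Provenance("direct")
    candidates = [m for m in library if m.id in block_store and m.id != drug.id]
    hit: Optional[SimilarityHit] = most_similar(
        drug, candidates, threshold, precomputed=fp_cache
    )
    if hit is not None:
        return (
            np.asarray(block_store[hit.neighbor_id], dtype=float).copy(),
            Provenance("neighbor", hit.neighbor_id, hit.similarity),
        )
    stacked = np.stack([np.asarray(v, dtype=float) for v in block_store.values()])
    return stacked.mean(axis=0), Provenance("average")


def impute_features(
    drug: Molecule,
    store: Mapping[str, Mapping[str, np.ndarray]],
    library: Sequence[Molecule],
    threshold: float = DEFAULT_IMPUTE_THRESHOLD,
    fp_cache: Optional[dict] = None,
) -> AuxiliaryFeatures:
    """Assemble (and where needed impute) both feature blocks for *drug*.

    ``store`` maps block name ("dti", "ddi") to per-drug vectors for drugs
    possessing that block.  Blocks are filled independently: direct when
    present, else copied from the chemically most similar library drug with
    Tanimoto >= threshold, else the element-wise average over the store.
    """
    for name in ("dti", "ddi"):
        if name not in store or not store[name]:
            raise ValueError(f"feature store has no {name!r} block")
    dti_vec, dti_prov = _impute_block(drug, store["dti"], library, threshold, fp_cache)
    ddi_vec, ddi_prov = _impute_block(drug, store["ddi"], library, threshold, fp_cache)
    return AuxiliaryFeatures(drug.id, dti_vec, ddi_vec, dti_prov, ddi_prov)


def build_feature_table(
    drugs: Sequence[Molecule],
    dti: InteractionMatrix,
    ddi: InteractionMatrix,
    pca: PcaModel,
    amfp: AmfpModel,
    threshold: float = DEFAULT_IMPUTE_THRESHOLD,
) -> dict[str, AuxiliaryFeatures]:
    """One concatenated feature record per input drug.

    DTI rows are PCA-projected; DDI embeddings come from the fitted AMFP
    model.  Drugs missing from a matrix get that block imputed.  Imputation
    statistics are logged per provenance class.
    """
    dti_rows = {r: i for i, r in enumerate(dti.row_ids)}
    dense_dti = dti.dense()
    dti_store = {
        r: pca_project(pca, dense_dti[i]) for r, i in dti_rows.items()
    }
    ddi_store = {t: amfp.embedding(t) for t in amfp.trained_ids}
    store = {"dti": dti_store, "ddi": ddi_store}

    fp_cache = fingerprint_library(drugs)
    table: dict[str, AuxiliaryFeatures] = {}
    counts: dict[str, int] = {}
    for drug in drugs:
        feats = impute_features(drug, store, drugs, threshold, fp_cache)
        table[drug.id] = feats
        for prov in (feats.dti_provenance, feats.ddi_provenance):
            counts[prov.mode] = counts.get(prov.mode, 0) + 1
    logger.info("feature table built for %d drugs; provenance counts: %s",
                len(drugs), counts)
    return table
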