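"""Directed-bond message-passing neural network for molecules, in NumPy.

The architecture follows the D-MPNN family: messages live on directed
bonds, are initialized from the source atom's features concatenated with
the bond's features, and are updated for a fixed number of rounds by
summing the messages on bonds incoming to the source atom (excluding the
reverse bond).  Atom vectors are read out by summing incoming bond
messages, molecule vectors by summing atom vectors, and a feed-forward
head with a sigmoid output produces the classification probability.
Optional per-molecule auxiliary feature vectors are concatenated to the
molecule readout before the head.

Forward and backward passes are written by hand; optimization is Adam on
binary cross-entropy.  All randomness flows from a single integer seed, so
training is reproducible under a fixed thread count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from rdkit import Chem

from .chem import Molecule

# -- featurization ----------------------------------------------------------

_ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P"]  # + other
_ATOM_DIM = len(_ELEMENTS) + 1 + 6 + 4 + 1 + 1 + 5
_BOND_DIM = 4 + 1 + 1


def _one_hot(value: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    v[min(value, size - 1)] = 1.0
    return v


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    sym = atom.GetSymbol()
    elem = np.zeros(len(_ELEMENTS) + 1)
    elem[_ELEMENTS.index(sym) if sym in _ELEMENTS else len(_ELEMENTS)] = 1.0
    charge_map = {-1: 0, 0: 1, 1: 2}
    return np.concatenate([
        elem,
        _one_hot(atom.GetDegree(), 6),
        _one_hot(charge_map.get(atom.GetFormalCharge(), 3), 4),
        [float(atom.GetIsAromatic())],
        [float(atom.IsInRing())],
        _one_hot(atom.GetTotalNumHs(), 5),
    ])


_BOND_TYPES = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}


def _bond_features(bond: Chem.Bond) -> np.ndarray:
    return np.concatenate([
        _one_hot(_BOND_TYPES.get(bond.GetBondType(), 0), 4),
        [float(bond.GetIsConjugated())],
        [float(bond.IsInRing())],
    ])


@dataclass
class MolGraph:
    """Featurized molecular graph with directed bonds."""

    atom_feats: np.ndarray   # (n_atoms, ATOM_DIM)
    bond_feats: np.ndarray   # (n_bonds, ATOM_DIM + BOND_DIM), src-atom || bond
    src: np.ndarray          # (n_bonds,) source atom index
    dst: np.ndarray          # (n_bonds,) target atom index
    rev: np.ndarray          # (n_bonds,) index of the reverse directed bond


def mol_to_graph(mol: Molecule) -> MolGraph:
    rd = mol.to_rdkit()
    atom_feats = np.stack([_atom_features(a) for a in rd.GetAtoms()]) \
        if rd.GetNumAtoms() else np.zeros((0, _ATOM_DIM))
    src, dst, rev, bf = [], [], [], []
    for bond in rd.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        feats = _bond_features(bond)
        k = len(src)
        src.extend((u, v)); dst.extend((v, u))
        rev.extend((k + 1, k))
        bf.append(np.concatenate([atom_feats[u], feats]))
        bf.append(np.concatenate([atom_feats[v], feats]))
    bond_feats = np.stack(bf) if bf else np.zeros((0, _ATOM_DIM + _BOND_DIM))
    return MolGraph(
        atom_feats=atom_feats,
        bond_feats=bond_feats,
        src=np.asarray(src, dtype=np.int64),
        dst=np.asarray(dst, dtype=np.int64),
        rev=np.asarray(rev, dtype=np.int64),
    )


@dataclass
class BatchGraph:
    """Concatenation of several MolGraphs with sparse aggregation operators."""

    atom_feats: np.ndarray
    bond_feats: np.ndarray
    src: np.ndarray
    rev: np.ndarray
    incoming: sp.csr_matrix   # (n_atoms, n_bonds): 1 where dst[e] == atom
    pool: sp.csr_matrix       # (n_mols, n_atoms): molecule membership


def batch_graphs(graphs: Sequence[MolGraph]) -> BatchGraph:
    atom_off = 0
    bond_off = 0
    afs, bfs, srcs, revs = [], [], [], []
    inc_r, inc_c, pool_r, pool_c = [], [], [], []
    for m, g in enumerate(graphs):
        na, nb = g.atom_feats.shape[0], g.bond_feats.shape[0]
        afs.append(g.atom_feats)
        bfs.append(g.bond_feats)
        srcs.append(g.src + atom_off)
        revs.append(g.rev + bond_off)
        inc_r.extend((g.dst + atom_off).tolist())
        inc_c.extend(range(bond_off, bond_off + nb))
        pool_r.extend([m] * na)
        pool_c.extend(range(atom_off, atom_off + na))
        atom_off += na
        bond_off += nb
    n_atoms, n_bonds = atom_off, bond_off
    incoming = sp.csr_matrix(
        (np.ones(len(inc_r)), (inc_r, inc_c)), shape=(n_atoms, n_bonds)
    )
    pool = sp.csr_matrix(
        (np.ones(len(pool_r)), (pool_r, pool_c)), shape=(len(graphs), n_atoms)
    )
    return BatchGraph(
        atom_feats=np.vstack(afs) if afs else np.zeros((0, _ATOM_DIM)),
        bond_feats=np.vstack(bfs) if bfs else np.zeros((0, _ATOM_DIM + _BOND_DIM)),
        src=np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.int64),
        rev=np.concatenate(revs) if revs else np.zeros(0, dtype=np.int64),
        incoming=incoming,
        pool=pool,
    )


# -- network ----------------------------------------------------------------

def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class MPNN:
    """Trainable message-passing classifier.

    Parameters
    ----------
    hidden_dim : width of bond messages, atom vectors and FFN hidden layers.
    message_depth : number of message-update rounds.
    ffn_layers : total linear layers in the head (>= 1); the last is the
        sigmoid output, the preceding ones are ReLU layers of hidden_dim.
    aux_dim : length of the auxiliary feature vector concatenated to the
        molecule readout (0 disables the pathway entirely).
    """

    def __init__(
        self,
        hidden_dim: int = 300,
        message_depth: int = 3,
        ffn_layers: int = 2,
        aux_dim: int = 0,
        seed: int = 0,
    ) -> None:
        self.hidden_dim = hidden_dim
        self.message_depth = message_depth
        self.ffn_layers = ffn_layers
        self.aux_dim = aux_dim
        self.seed = seed
        rng = np.random.default_rng(seed)

        def init(shape):
            fan_in = shape[1]
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        h = hidden_dim
        self.W_i = init((h, _ATOM_DIM + _BOND_DIM))
        self.W_h = init((h, h))
        self.W_o = init((h, _ATOM_DIM + h))
        self.ffn_W: list[np.ndarray] = []
        self.ffn_b: list[np.ndarray] = []
        in_dim = h + aux_dim
        for layer in range(ffn_layers - 1):
            self.ffn_W.append(init((h, in_dim)))
            self.ffn_b.append(np.zeros(h))
            in_dim = h
        self.ffn_W.append(init((1, in_dim)))
        self.ffn_b.append(np.zeros(1))

        self._params = [self.W_i, self.W_h, self.W_o, *self.ffn_W, *self.ffn_b]
        self._adam_m = [np.zeros_like(p) for p in self._params]
        self._adam_v = [np.zeros_like(p) for p in self._params]
        self._adam_t = 0

    # forward --------------------------------------------------------------

    def _forward(self, batch: BatchGraph, aux: Optional[np.ndarray]):
        """Returns probabilities plus the cache needed for backprop."""
        h0_pre = batch.bond_feats @ self.W_i.T
        h0 = _relu(h0_pre)
        hs = [h0]
        pres = [h0_pre]
        h = h0
        for _ in range(self.message_depth):
            atom_sum = batch.incoming @ h
            m = atom_sum[batch.src] - h[batch.rev]
            pre = h0 + m @ self.W_h.T
            h = _relu(pre)
            hs.append(h)
            pres.append(pre)

        atom_in = batch.incoming @ h
        atom_cat = np.hstack([batch.atom_feats, atom_in])
        atom_pre = atom_cat @ self.W_o.T
        atom_h = _relu(atom_pre)
        g = batch.pool @ atom_h

        x = np.hstack([g, aux]) if self.aux_dim else g
        acts = [x]
        ffn_pres = []
        for layer in range(self.ffn_layers - 1):
            pre = acts[-1] @ self.ffn_W[layer].T + self.ffn_b[layer]
            ffn_pres.append(pre)
            acts.append(_relu(pre))
        logits = (acts[-1] @ self.ffn_W[-1].T + self.ffn_b[-1]).ravel()
        probs = _sigmoid(logits)
        cache = (batch, hs, pres, atom_cat, atom_pre, acts, ffn_pres)
        return probs, logits, cache

    def predict_proba(
        self, graphs: Sequence[MolGraph], aux: Optional[np.ndarray] = None
    ) -> np.ndarray:
        batch = batch_graphs(graphs)
        probs, _, _ = self._forward(batch, aux)
        return probs

    # backward -------------------------------------------------------------

    def _backward(self, cache, probs: np.ndarray, labels: np.ndarray):
        batch, hs, pres, atom_cat, atom_pre, acts, ffn_pres = cache
        n = labels.size
        grads = {id(p): np.zeros_like(p) for p in self._params}

        dlogit = (probs - labels) / n  # (n_mols,)

        # FFN head
        grads[id(self.ffn_W[-1])] += dlogit[None, :] @ acts[-1]
        grads[id(self.ffn_b[-1])] += np.array([dlogit.sum()])
        dx = dlogit[:, None] * self.ffn_W[-1]
        for layer in range(self.ffn_layers - 2, -1, -1):
            dpre = dx * (ffn_pres[layer] > 0)
            grads[id(self.ffn_W[layer])] += dpre.T @ acts[layer]
            grads[id(self.ffn_b[layer])] += dpre.sum(axis=0)
            dx = dpre @ self.ffn_W[layer]

        dg = dx[:, : self.hidden_dim]

        # atom readout
        datom_h = batch.pool.T @ dg
        datom_pre = datom_h * (atom_pre > 0)
        grads[id(self.W_o)] += datom_pre.T @ atom_cat
        datom_cat = datom_pre @ self.W_o
        datom_in = datom_cat[:, _ATOM_DIM:]
        dh = batch.incoming.T @ datom_in

        # message-passing rounds, reversed
        dh0_total = np.zeros_like(hs[0])
        for t in range(self.message_depth, 0, -1):
            dpre = dh * (pres[t] > 0)
            dh0_total += dpre
            atom_sum_prev = batch.incoming @ hs[t - 1]
            m_prev = atom_sum_prev[batch.src] - hs[t - 1][batch.rev]
            grads[id(self.W_h)] += dpre.T @ m_prev
            dm = dpre @ self.W_h
            datom_sum = np.zeros((batch.incoming.shape[0], self.hidden_dim))
            np.add.at(datom_sum, batch.src, dm)
            dh = batch.incoming.T @ datom_sum
            dh -= dm[batch.rev]
        dh0_total += dh
        dpre0 = dh0_total * (pres[0] > 0)
        grads[id(self.W_i)] += dpre0.T @ batch.bond_feats

        return [grads[id(p)] for p in self._params]

    # optimization ----------------------------------------------------------

    def train_step(
        self,
        graphs: Sequence[MolGraph],
        labels: np.ndarray,
        aux: Optional[np.ndarray],
        learning_rate: float,
    ) -> float:
        batch = batch_graphs(graphs)
        probs, _, cache = self._forward(batch, aux)
        eps = 1e-12
        loss = -float(np.mean(
            labels * np.log(probs + eps) + (1 - labels) * np.log(1 - probs + eps)
        ))
        grads = self._backward(cache, probs, labels)
        self._adam_t += 1
        b1, b2, aeps = 0.9, 0.999, 1e-8
        t = self._adam_t
        for p, g, m, v in zip(self._params, grads, self._adam_m, self._adam_v):
            m *= b1; m += (1 - b1) * g
            v *= b2; v += (1 - b2) * g * g
            p -= learning_rate * (m / (1 - b1 ** t)) / (np.sqrt(v / (1 - b2 ** t)) + aeps)
        return loss

    def fit(
        self,
        graphs: Sequence[MolGraph],
        labels: np.ndarray,
        aux: Optional[np.ndarray] = None,
        epochs: int = 30,
        learning_rate: float = 1e-3,
        batch_size: int = 50,
        seed: Optional[int] = None,
    ) -> list[float]:
        """Minibatch Adam on binary cross-entropy; returns per-epoch losses."""
        rng = np.random.default_rng(self.seed if seed is None else seed)
        n = len(graphs)
        losses = []
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                batch_aux = aux[idx] if aux is not None else None
                loss = self.train_step(
                    [graphs[i] for i in idx], labels[idx], batch_aux, learning_rate
                )
                epoch_loss += loss * idx.size
            losses.append(epoch_loss / n)
        return losses
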