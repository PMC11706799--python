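"""Phylogenetic likelihood under GTR+Γ: pruning algorithm and the per-edge
machinery used by likelihood-based placement.

The pruning implementation keeps per-category conditional likelihood vectors
with per-site log-scaling (large trees underflow doubles otherwise).  For
placement, every backbone edge gets a precomputed "inside x outside" partial
product at its midpoint, so evaluating a query attachment for any pendant
length costs one 4x4 transition matrix and one weighted sum per site — this
makes an exhaustive all-edges scan cheap at desk scale.

Site likelihoods are averaged over the discrete-gamma categories with equal
weights.  Missing characters ('-') contribute all-ones partials.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np

from .alignment import GAP, MultiGeneAlignment
from .substmodel import GTRModel
from .tree import Node, PhyloTree, number_edges

__all__ = ["tree_loglikelihood", "BackboneEngine"]

_TINY = 1e-300


def _rows_from(aln_or_rows, columns: Optional[np.ndarray] = None) -> Dict[str, np.ndarray]:
    if isinstance(aln_or_rows, MultiGeneAlignment):
        rows = {s: aln_or_rows.row(s) for s in aln_or_rows.species}
    else:
        rows = {s: np.asarray(r, dtype=np.int8) for s, r in aln_or_rows.items()}
    if columns is not None:
        rows = {s: r[columns] for s, r in rows.items()}
    return rows


def _leaf_contrib(P: np.ndarray, states: np.ndarray) -> np.ndarray:
    """Child contribution of a leaf: P(b)[:, :, state], ones where missing."""
    contrib = P[:, :, np.where(states == GAP, 0, states)]  # (k,4,S)
    contrib = contrib.copy()
    contrib[:, :, states == GAP] = 1.0
    return contrib


class _Partials:
    """Down-pass conditional likelihoods with per-(category, site) scaling."""

    def __init__(self, tree: PhyloTree, rows: Mapping[str, np.ndarray],
                 model: GTRModel, multiplier: float):
        self.tree = tree
        self.model = model
        self.multiplier = multiplier
        self.cat_rates = model.gamma_rates()
        self.k = len(self.cat_rates)
        lam, A, B = model.eigensystem()
        self.lam, self.A, self.B = lam, A, B
        widths = {len(r) for r in rows.values()}
        if len(widths) != 1:
            raise ValueError("alignment rows have unequal lengths")
        self.S = widths.pop()
        if self.S == 0:
            raise ValueError("zero-length alignment")
        missing = tree.leaf_set() - set(rows)
        if missing:
            raise ValueError(f"alignment missing rows for {sorted(missing)[:5]}")
        self.rows = rows
        self.down: Dict[Node, np.ndarray] = {}
        self.scale_down: Dict[Node, np.ndarray] = {}
        self._down_pass()

    def pmat(self, t: float) -> np.ndarray:
        """Per-category transition matrices for branch length t; (k,4,4)."""
        ts = t * self.multiplier * self.cat_rates
        E = np.exp(np.multiply.outer(ts, self.lam))
        P = np.einsum("kx,ax,xb->kab", E, self.A, self.B)
        return np.clip(P, 0.0, None)

    def child_contrib(self, child: Node) -> Tuple[np.ndarray, np.ndarray]:
        """(contribution (k,4,S), log-scale (k,S)) of a child toward its parent."""
        P = self.pmat(child.length)
        if child.is_leaf:
            return _leaf_contrib(P, self.rows[child.label]), np.zeros((self.k, self.S))
        contrib = np.einsum("kab,kbS->kaS", P, self.down[child])
        return contrib, self.scale_down[child]

    def _down_pass(self) -> None:
        for node in self.tree.postorder():
            if node.is_leaf:
                continue
            partial = np.ones((self.k, 4, self.S))
            scale = np.zeros((self.k, self.S))
            for child in node.children:
                contrib, s = self.child_contrib(child)
                partial *= contrib
                scale += s
            m = np.maximum(partial.max(axis=1), _TINY)
            partial /= m[:, None, :]
            scale += np.log(m)
            self.down[node] = partial
            self.scale_down[node] = scale

    def loglikelihood(self) -> float:
        pi = self.model.pi
        root = self.tree.root
        if root.is_leaf:
            raise ValueError("tree must have internal structure")
        L = np.einsum("a,kaS->kS", pi, self.down[root])
        logs = np.log(np.maximum(L, _TINY)) + self.scale_down[root]
        site = _logmeanexp(logs, axis=0)
        return float(site.sum())


def _logmeanexp(x: np.ndarray, axis: int) -> np.ndarray:
    m = x.max(axis=axis, keepdims=True)
    out = m.squeeze(axis) + np.log(np.mean(np.exp(x - m), axis=axis))
    return out


def tree_loglikelihood(
    tree: PhyloTree,
    aln,
    model: GTRModel,
    multiplier: float = 1.0,
    columns: Optional[np.ndarray] = None,
) -> float:
    """Log-likelihood of the tree given aligned sequences under GTR+Γ.

    ``aln`` may be a MultiGeneAlignment or a mapping label -> encoded int8
    row; ``columns`` optionally restricts to a column index array.
    """
    rows = _rows_from(aln, columns)
    return _Partials(tree, rows, model, multiplier).loglikelihood()


class BackboneEngine:
    """Precomputed per-edge partials for placing queries on a fixed backbone.

    For edge e (child node c, parent p, length b) the engine stores, at the
    midpoint attachment x = b/2 by default, the per-category, per-site
    product H_e = (P(b-x)^T outside_e) * (P(x) inside_c), rescaled so
    categories share one per-site log offset.  A query with encoded states q
    attached with pendant length t then has site likelihood
    mean_cat sum_state H_e * P_cat(t)[state, q_site], times exp(offset).
    """

    def __init__(
        self,
        backbone: PhyloTree,
        rows: Mapping[str, np.ndarray] | MultiGeneAlignment,
        model: GTRModel,
        multiplier: float = 1.0,
        columns: Optional[np.ndarray] = None,
        distal_fraction: float = 0.5,
    ):
        if any(n.edge_number is None for n in backbone.postorder() if n.parent is not None):
            number_edges(backbone)
        self.tree = backbone
        self.model = model
        self.part = _Partials(backbone, _rows_from(rows, columns), model, multiplier)
        self.k, self.S = self.part.k, self.part.S
        self.height = backbone.height()
        self.pendant_max = max(2.0 * self.height, 1e-3)

        emap = backbone.edge_map()
        self.edge_numbers = sorted(emap)
        self.E = len(self.edge_numbers)
        self.edge_child = [emap[e] for e in self.edge_numbers]
        self.branch_lengths = np.array([n.length for n in self.edge_child])
        self._up_pass()
        self.distal_fraction = distal_fraction
        self.H, self.offset = self._edge_arrays(self.branch_lengths * distal_fraction)

    # -- outside partials --------------------------------------------------

    def _up_pass(self) -> None:
        """eup[v]: partial at parent(v) for everything outside subtree(v),
        including the root prior; with per-(cat,site) log scales."""
        part = self.part
        pi = self.model.pi
        self.eup: Dict[Node, np.ndarray] = {}
        self.scale_up: Dict[Node, np.ndarray] = {}
        ups: Dict[Node, np.ndarray] = {self.tree.root: np.tile(pi[None, :, None], (self.k, 1, self.S))}
        ups_scale: Dict[Node, np.ndarray] = {self.tree.root: np.zeros((self.k, self.S))}
        for node in self.tree.preorder():
            if node.is_leaf:
                continue
            contribs = []
            for child in node.children:
                contribs.append(part.child_contrib(child))
            for i, child in enumerate(node.children):
                e = ups[node].copy()
                s = ups_scale[node].copy()
                for j, (contrib, cscale) in enumerate(contribs):
                    if j == i:
                        continue
                    e *= contrib
                    s += cscale
                m = np.maximum(e.max(axis=1), _TINY)
                e /= m[:, None, :]
                s += np.log(m)
                self.eup[child] = e
                self.scale_up[child] = s
                if not child.is_leaf:
                    P = part.pmat(child.length)
                    ups[child] = np.einsum("kab,kaS->kbS", P, e)
                    ups_scale[child] = s

    def _edge_arrays(self, distals: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """H'[E,k,4,S] with per-(E,S) log offsets, at given per-edge distals."""
        part = self.part
        H = np.empty((self.E, self.k, 4, self.S))
        off = np.empty((self.E, self.k, self.S))
        for idx, child in enumerate(self.edge_child):
            b = self.branch_lengths[idx]
            x = float(distals[idx])
            Pd = part.pmat(x)
            Pu = part.pmat(b - x)
            if child.is_leaf:
                d = _leaf_contrib(Pd, part.rows[child.label])
                ds = np.zeros((self.k, self.S))
            else:
                d = np.einsum("kab,kbS->kaS", Pd, part.down[child])
                ds = part.scale_down[child]
            u = np.einsum("kab,kaS->kbS", Pu, self.eup[child])
            H[idx] = d * u
            off[idx] = ds + self.scale_up[child]
        # uniformize scale across categories per (edge, site)
        omax = off.max(axis=1)
        Hs = H * np.exp(off - omax[:, None, :])[:, :, None, :]
        return Hs, omax

    # -- query evaluation --------------------------------------------------

    def _loglik_at(self, qstates: np.ndarray, pendants: np.ndarray,
                   H: np.ndarray, offset: np.ndarray) -> np.ndarray:
        """Per-edge log-likelihood over the engine's sites for per-edge
        pendant lengths (shape (E,))."""
        part = self.part
        ts = np.multiply.outer(pendants * part.multiplier, part.cat_rates)  # (E,k)
        Ee = np.exp(ts[..., None] * part.lam)  # (E,k,4)
        P = np.einsum("ekx,ax,xb->ekab", Ee, part.A, part.B)
        np.clip(P, 0.0, None, out=P)
        W = P[:, :, :, np.where(qstates == GAP, 0, qstates)]  # (E,k,4,S)
        if (qstates == GAP).any():
            W[:, :, :, qstates == GAP] = 1.0
        val = np.einsum("ekaS,ekaS->ekS", H, W)
        site = np.log(np.maximum(val.mean(axis=1), _TINY)) + offset
        return site.sum(axis=1)

    def scan(
        self,
        qstates: np.ndarray,
        pendant_tol: float = 1e-6,
        optimize_distal: bool = False,
    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Optimal pendant length per edge by golden-section search.

        Returns (loglik[E], pendant[E], distal[E]).
        """
        qstates = np.asarray(qstates, dtype=np.int8)
        if len(qstates) != self.S:
            raise ValueError("query row width differs from engine sites")
        H, offset = self.H, self.offset
        distal = self.branch_lengths * self.distal_fraction
        ll, t = self._golden_pendant(qstates, H, offset, pendant_tol)
        if optimize_distal:
            for _ in range(3):
                distal, ll = self._golden_distal(qstates, t, distal, pendant_tol)
                H2, off2 = self._edge_arrays(distal)
                ll, t = self._golden_pendant(qstates, H2, off2, pendant_tol)
        return ll, t, distal

    def _golden_pendant(self, qstates, H, offset, tol) -> Tuple[np.ndarray, np.ndarray]:
        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        a = np.zeros(self.E)
        b = np.full(self.E, self.pendant_max)
        x1 = b - invphi * (b - a)
        x2 = a + invphi * (b - a)
        f1 = self._loglik_at(qstates, x1, H, offset)
        f2 = self._loglik_at(qstates, x2, H, offset)
        for _ in range(200):
            if (b - a).max() <= tol:
                break
            low = f1 < f2  # maximum lies in [x1, b]
            a = np.where(low, x1, a)
            b = np.where(low, b, x2)
            x1n = np.where(low, x2, b - invphi * (b - a))
            x2n = np.where(low, a + invphi * (b - a), x1)
            f1n = np.where(low, f2, np.nan)
            f2n = np.where(low, np.nan, f1)
            # evaluate the fresh points only (one per edge)
            fresh = np.where(low, x2n, x1n)
            ffresh = self._loglik_at(qstates, fresh, H, offset)
            f1 = np.where(low, f1n, ffresh)
            f2 = np.where(low, ffresh, f2n)
            x1, x2 = x1n, x2n
        t = 0.5 * (a + b)
        ll = self._loglik_at(qstates, t, H, offset)
        return ll, t

    def _golden_distal(self, qstates, t, distal, tol):
        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        a = np.zeros(self.E)
        b = self.branch_lengths.copy()

        def f(x):
            Hx, offx = self._edge_arrays(x)
            return self._loglik_at(qstates, t, Hx, offx)

        x1 = b - invphi * (b - a)
        x2 = a + invphi * (b - a)
        f1, f2 = f(x1), f(x2)
        for _ in range(60):
            if (b - a).max() <= tol:
                break
            low = f1 < f2
            a = np.where(low, x1, a)
            b = np.where(low, b, x2)
            x1n = np.where(low, x2, b - invphi * (b - a))
            x2n = np.where(low, a + invphi * (b - a), x1)
            fresh = np.where(low, x2n, x1n)
            ffresh = f(fresh)
            f1old = f1
            f1 = np.where(low, f2, ffresh)
            f2 = np.where(low, ffresh, f1old)
            x1, x2 = x1n, x2n
        x = 0.5 * (a + b)
        return x, f(x)
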