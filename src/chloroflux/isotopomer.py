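"""Brute-force positional-isotopomer simulation.

Integrates the full 2**n isotopomer state of every internal metabolite.  This
scales exponentially in carbon number and exists as the exhaustive reference
implementation against which the EMU engine is verified; the preset networks
are small enough (<= 7 carbons per metabolite) for it to run in seconds.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .network import AtomNetwork

__all__ = ["IsotopomerSimulator"]


def _input_tensor(n: int, a: float) -> np.ndarray:
    """Joint isotopomer distribution of n independent atoms labelled with prob a."""
    t = np.array([1.0 - a, a])
    out = np.array([1.0])
    for _ in range(n):
        out = np.multiply.outer(out, t)
    return out.reshape((2,) * n) if n else out


class IsotopomerSimulator:
    """Exhaustive isotopomer ODE model of an :class:`AtomNetwork`."""

    def __init__(self, net: AtomNetwork):
        self.net = net
        counts = net.carbon_counts
        self.mets = list(net.pools)
        self.n = {m: counts[m] for m in self.mets}
        self.offsets = {}
        off = 0
        for m in self.mets:
            self.offsets[m] = off
            off += 2 ** self.n[m]
        self.dim = off
        self.inputs = {m: _input_tensor(counts[m], a) for m, a in net.inputs.items()}
        # Precompute per producing reaction instance: target met, flux value,
        # and the recipe to assemble the source tensor.
        self.terms = []
        for rxn in net.reactions:
            v = net.fluxes[rxn.name]
            for pj, (pmet, patoms) in enumerate(rxn.products):
                if pmet not in net.pools:
                    continue
                origin = rxn.atom_origin(pj)  # product pos -> (sub idx, sub pos)
                by_sub: dict = {}
                for ppos, (si, spos) in enumerate(origin):
                    by_sub.setdefault(si, []).append((ppos, spos))
                groups = []  # (sub met, used sub positions, product positions)
                for si in sorted(by_sub):
                    smet = rxn.substrates[si][0]
                    ppos_list = [p for p, _ in by_sub[si]]
                    spos_list = [s for _, s in by_sub[si]]
                    groups.append((smet, spos_list, ppos_list))
                # axis permutation: the outer product carries axes group by
                # group, each group already in product-position order (see
                # _marginal); transpose to the product's atom order
                outer_order = [p for (_, _, ppos) in groups for p in ppos]
                perm = [outer_order.index(k) for k in range(len(patoms))]
                self.terms.append((pmet, v, groups, perm))

    def _marginal(self, tensor: np.ndarray, met: str, keep_positions) -> np.ndarray:
        nm = tensor.ndim
        drop = tuple(ax for ax in range(nm) if ax not in keep_positions)
        marg = tensor.sum(axis=drop) if drop else tensor
        # remaining axes are in ascending position order; reorder to keep_positions
        kept_sorted = sorted(keep_positions)
        perm = [kept_sorted.index(p) for p in keep_positions]
        return np.transpose(marg, perm) if marg.ndim > 1 else marg

    def _rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        dx = np.zeros_like(x)
        tensors = {}
        for m in self.mets:
            o = self.offsets[m]
            tensors[m] = x[o:o + 2 ** self.n[m]].reshape((2,) * self.n[m])
        tensors.update(self.inputs)
        for pmet, v, groups, perm in self.terms:
            src = None
            for smet, spos, _ in groups:
                marg = self._marginal(tensors[smet], smet, spos)
                src = marg if src is None else np.multiply.outer(src, marg)
            src = np.transpose(src, perm)
            o = self.offsets[pmet]
            size = 2 ** self.n[pmet]
            coef = v / self.net.pools[pmet]
            dx[o:o + size] += coef * (src.ravel() - x[o:o + size])
        return dx

    def simulate(self, times, rtol: float = 1e-8, atol: float = 1e-10) -> dict:
        """Return {metabolite: array (n_times, n_carbons + 1)} of true MIDs.

        Dilution is applied at measurement: each metabolite's simulated MID is
        mixed with the unlabelled MID according to its dilution fraction.
        """
        times = np.asarray(times, dtype=float)
        if np.any(times < 0) or np.any(np.diff(times) <= 0):
            raise ValueError("times must be non-negative and strictly ascending")
        x0 = np.zeros(self.dim)
        for m in self.mets:
            x0[self.offsets[m]] = 1.0  # fully unlabelled pattern
        t_span = (0.0, float(times[-1]) if times[-1] > 0 else 1.0)
        sol = solve_ivp(self._rhs, t_span, x0, t_eval=times, method="LSODA",
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"isotopomer integration failed: {sol.message}")
        out = {}
        for m in self.mets:
            n = self.n[m]
            o = self.offsets[m]
            weights = np.array([bin(i).count("1") for i in range(2 ** n)])
            mids = np.zeros((times.size, n + 1))
            block = sol.y[o:o + 2 ** n, :].T  # (T, states)
            for i in range(n + 1):
                mids[:, i] = block[:, weights == i].sum(axis=1)
            d = self.net.dilutions.get(m, 0.0)
            if d:
                unl = np.zeros(n + 1)
                unl[0] = 1.0
                mids = (1.0 - d) * mids + d * unl
            out[m] = mids
        return out
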