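"""Brute-force positional-isotopomer simulator.

Tracks the full 2**n isotopomer distribution of every balanced metabolite
(bit i set = carbon i is 13C) by direct ODE integration.  Exponential in
carbon count, so only usable on toy networks — it exists as an independent
cross-check of the EMU simulator, which must agree with it exactly on any
network where both are feasible.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.integrate import solve_ivp

from .mid import MIDVector, LabelTimeCourse
from .network import FluxState, NetworkModel, Reaction
from .simulate import PoolSizes, _binomial, NATURAL_13C

__all__ = ["simulate_isotopomers"]


def _source_dist(n: int, enrichment: float | None) -> np.ndarray:
    """Isotopomer distribution with independent per-carbon labeling."""
    p = 0.0 if enrichment is None else enrichment
    d = np.zeros(2**n)
    for iso in range(2**n):
        nlab = bin(iso).count("1")
        d[iso] = p**nlab * (1 - p) ** (n - nlab)
    return d


def simulate_isotopomers(
    net: NetworkModel,
    fluxes: FluxState,
    pools: PoolSizes,
    times_min,
    input_enrichment: float = 0.99,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> dict[str, LabelTimeCourse]:
    """Full isotopomer simulation; returns MID time courses per balanced
    metabolite (initial state fully unlabeled)."""
    times_min = np.asarray(times_min, dtype=float)
    times_h = times_min / 60.0
    mets = net.balanced_metabolites()
    ncarb = {m: net.metabolites[m].n_carbons for m in mets}
    offset = {}
    n = 0
    for m in mets:
        offset[m] = n
        n += 2 ** ncarb[m]

    # direction list: (flux, substrate instances, product instances, atom map)
    dirs: list[tuple[float, Reaction]] = []
    for r in net.reactions:
        vf = fluxes.forward(r)
        vb = fluxes.backward(r)
        if vf > 0:
            dirs.append((vf, r))
        if vb > 0:
            dirs.append((vb, r.reversed()))

    def met_dist(y, m, const_cache={}):
        if net.metabolites[m].balanced:
            return y[offset[m] : offset[m] + 2 ** ncarb[m]]
        if m not in const_cache:
            enr = (
                input_enrichment
                if net.metabolites[m].label == "feed"
                else 0.0
            )
            const_cache[m] = _source_dist(net.metabolites[m].n_carbons, enr)
        return const_cache[m]

    def rhs(t, y):
        dy = np.zeros_like(y)
        for v, d in dirs:
            sub_dists = [met_dist(y, s) for s in d.substrates]
            # joint substrate isotopomers, independence across pools
            for combo in product(*[range(x.size) for x in sub_dists]):
                p_joint = 1.0
                for x, i in zip(sub_dists, combo):
                    p_joint *= x[i]
                if p_joint == 0.0:
                    continue
                # deliver each product instance
                for pi, pname in enumerate(d.products):
                    if not net.metabolites[pname].balanced:
                        continue
                    iso = 0
                    for a in range(len(d.atom_map.products[pi])):
                        si, sj = d.atom_map.product_atom_origin(pi, a)
                        if (combo[si] >> sj) & 1:
                            iso |= 1 << a
                    dy[offset[pname] + iso] += v * p_joint
            # consumption
            for sname in d.substrates:
                if net.metabolites[sname].balanced:
                    dy[offset[sname] : offset[sname] + 2 ** ncarb[sname]] -= (
                        v * met_dist(y, sname)
                    )
        for m in mets:
            dy[offset[m] : offset[m] + 2 ** ncarb[m]] /= pools[m]
        return dy

    y0 = np.zeros(n)
    for m in mets:
        y0[offset[m]] = 1.0
    sol = solve_ivp(
        rhs, (0.0, times_h[-1]), y0, method="BDF", t_eval=times_h, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise RuntimeError(sol.message)
    Y = np.clip(sol.y, 0.0, None)
    if times_h[0] == 0.0:
        Y[:, 0] = y0

    out = {}
    for m in mets:
        nc = ncarb[m]
        mids = []
        for col in Y[offset[m] : offset[m] + 2**nc, :].T:
            mid = np.zeros(nc + 1)
            for iso, p in enumerate(col):
                mid[bin(iso).count("1")] += p
            mid /= mid.sum()
            mids.append(MIDVector(m, mid))
        out[m] = LabelTimeCourse(m, times_min, mids)
    return out
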