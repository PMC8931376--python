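"""Elementary metabolite unit (EMU) decomposition.

An EMU is a subset of one metabolite's carbon atoms whose mass-isotopologue
distribution evolves autonomously under the network's atom transitions.
Decomposing backwards from the observed metabolites yields the minimal set
of EMUs needed to simulate their MIDs, organised in size blocks where a
size-k block depends only on blocks of size <= k (equality only through
same-size single-piece transfers).
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import NetworkModel, Reaction, NetworkError

__all__ = ["EMU", "EMUTerm", "EMUSystem", "emu_decompose"]


@dataclass(frozen=True, order=True)
class EMU:
    metabolite: str
    atoms: frozenset[int]

    @property
    def size(self) -> int:
        return len(self.atoms)

    def __repr__(self):
        pos = ",".join(str(i + 1) for i in sorted(self.atoms))
        return f"{self.metabolite}[{pos}]"


@dataclass(frozen=True)
class EMUTerm:
    """One production term of an EMU: flux of a reaction direction carrying
    label from ``pieces`` (convolved when more than one)."""

    rxn_id: str
    forward: bool
    pieces: tuple[EMU, ...]  # pieces on source metabolites included


def _sort_key(e: EMU):
    return (e.size, e.metabolite, tuple(sorted(e.atoms)))


@dataclass
class EMUSystem:
    network: NetworkModel
    emus: list[EMU]  # balanced-metabolite EMUs, size-ordered
    terms: dict[EMU, list[EMUTerm]]
    observed: list[tuple[str, EMU]]  # (observable name, full EMU)

    @property
    def sizes(self) -> list[int]:
        return sorted({e.size for e in self.emus})

    def block(self, size: int) -> list[EMU]:
        return [e for e in self.emus if e.size == size]

    def check_closure(self) -> None:
        known = set(self.emus)
        for e, terms in self.terms.items():
            for t in terms:
                for p in t.pieces:
                    if self.network.metabolites[p.metabolite].balanced and p not in known:
                        raise NetworkError(f"EMU system not closed at {p}")


def _producing_directions(net: NetworkModel, met: str) -> list[tuple[Reaction, bool]]:
    out = []
    for r in net.reactions:
        if met in r.products:
            out.append((r, True))
        if r.reversible and met in r.substrates:
            out.append((r, False))
    return out


def _terms_for(net: NetworkModel, emu: EMU) -> list[EMUTerm]:
    met = emu.metabolite
    terms = []
    for rxn, fwd in _producing_directions(net, met):
        d = rxn if fwd else rxn.reversed()
        for pi, pname in enumerate(d.products):
            if pname != met:
                continue
            pieces: dict[int, set[int]] = {}
            for a in emu.atoms:
                si, sj = d.atom_map.product_atom_origin(pi, a)
                pieces.setdefault(si, set()).add(sj)
            plist = tuple(
                EMU(d.substrates[si], frozenset(idx))
                for si, idx in sorted(pieces.items())
            )
            terms.append(EMUTerm(rxn.id, fwd, plist))
    return terms


def emu_decompose(
    net: NetworkModel,
    observed: list[str | tuple[str, str, tuple[int, ...]]],
) -> EMUSystem:
    """Minimal EMU system generating the observed MIDs.

    ``observed`` entries are metabolite ids (full-molecule observation) or
    ``(name, metabolite, atom_positions)`` tuples using 1-based positions,
    which supports moiety observables such as the glucosyl half of sucrose.
    """
    obs: list[tuple[str, EMU]] = []
    for item in observed:
        if isinstance(item, str):
            if item not in net.metabolites:
                raise NetworkError(f"observed metabolite {item} not in network")
            n = net.metabolites[item].n_carbons
            obs.append((item, EMU(item, frozenset(range(n)))))
        else:
            name, met, pos = item
            if met not in net.metabolites:
                raise NetworkError(f"observed metabolite {met} not in network")
            n = net.metabolites[met].n_carbons
            atoms = frozenset(p - 1 for p in pos)
            if not atoms or max(atoms) >= n or min(atoms) < 0:
                raise NetworkError(f"bad atom positions for {name}")
            obs.append((name, EMU(met, atoms)))
    for r in net.reactions:
        if not r.atom_map.substrates and r.substrates:
            raise NetworkError(f"{r.id}: missing atom map")

    terms: dict[EMU, list[EMUTerm]] = {}
    stack = [e for _, e in obs if net.metabolites[e.metabolite].balanced]
    while stack:
        e = stack.pop()
        if e in terms:
            continue
        tl = _terms_for(net, e)
        if not tl:
            raise NetworkError(f"no producing reaction for {e}")
        terms[e] = tl
        for t in tl:
            for p in t.pieces:
                if net.metabolites[p.metabolite].balanced and p not in terms:
                    stack.append(p)
    emus = sorted(terms, key=_sort_key)
    sys = EMUSystem(net, emus, terms, obs)
    sys.check_closure()
    return sys
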