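"""Compartmentalized atom-mapped reaction network of photosynthetic carbon
metabolism.

The network couples the Calvin-Benson cycle (CBC) in the chloroplast
stroma (``.p``) to cytosolic sucrose synthesis (``.c``), a lumped
photorespiratory salvage path through the mitochondrion (``.m``), vacuolar
sugar pools (``.v``), a cytosolic glucose-6-phosphate (G6P) shunt through
the oxidative pentose phosphate pathway, and a set of hypothesis variants
that admit unlabeled carbon at different points.  Reactions carry per-carbon
atom transitions written as letter strings ("abcde + f -> fba + cde"), the
substrate of all isotope-labeling simulation downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomMap",
    "Reaction",
    "Metabolite",
    "NetworkModel",
    "FluxState",
    "NetworkError",
    "parse_network",
    "canonical_network_text",
    "canonical_network",
    "full_canonical_network",
    "make_variant",
    "VARIANT_IDS",
    "check_steady_state",
    "carbon_accounting",
    "photorespiration_return_fraction",
    "reference_fluxes",
    "reference_pools",
]

COMPARTMENTS = {".c", ".p", ".m", ".v"}


class NetworkError(ValueError):
    """Raised for malformed network documents or inconsistent models."""


@dataclass(frozen=True)
class AtomMap:
    """Per-reaction carbon transition map.

    ``substrates``/``products`` hold one letter string per metabolite
    instance; each letter names one carbon and must appear exactly once on
    each side of the reaction (atom conservation).
    """

    substrates: tuple[str, ...]
    products: tuple[str, ...]

    def __post_init__(self):
        sub = "".join(self.substrates)
        prod = "".join(self.products)
        if len(set(sub)) != len(sub) or len(set(prod)) != len(prod):
            raise NetworkError(f"repeated atom letter in map {sub} -> {prod}")
        if set(sub) != set(prod):
            raise NetworkError(
                f"atom letters differ between sides: {sub!r} vs {prod!r}"
            )

    def product_atom_origin(self, prod_idx: int, atom_idx: int) -> tuple[int, int]:
        """(substrate instance, substrate atom index) feeding a product atom."""
        letter = self.products[prod_idx][atom_idx]
        for si, s in enumerate(self.substrates):
            j = s.find(letter)
            if j >= 0:
                return si, j
        raise KeyError(letter)

    def reversed(self) -> "AtomMap":
        return AtomMap(self.products, self.substrates)


@dataclass(frozen=True)
class Reaction:
    """One reaction with atom transitions.

    Multi-copy stoichiometry is written as repeated instances
    (``GLY.m + GLY.m -> SER.m + CO2i``) so each instance owns its letters.
    """

    id: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    atom_map: AtomMap
    reversible: bool
    group: str = "base"

    def __post_init__(self):
        if len(self.substrates) != len(self.atom_map.substrates) or len(
            self.products
        ) != len(self.atom_map.products):
            raise NetworkError(f"{self.id}: atom map arity mismatch")

    def carbon_count(self, met: str, side: str = "substrate") -> int:
        names, maps = (
            (self.substrates, self.atom_map.substrates)
            if side == "substrate"
            else (self.products, self.atom_map.products)
        )
        return sum(len(m) for n, m in zip(names, maps) if n == met)

    def stoich(self, met: str) -> int:
        """Net stoichiometric coefficient (products minus substrates)."""
        return self.products.count(met) - self.substrates.count(met)

    def reversed(self) -> "Reaction":
        return Reaction(
            self.id + "_rev",
            self.products,
            self.substrates,
            self.atom_map.reversed(),
            False,
            self.group,
        )


@dataclass(frozen=True)
class Metabolite:
    id: str
    n_carbons: int
    compartment: str | None
    role: str = "balanced"  # balanced | source | sink
    label: str = "unlabeled"  # for sources: "feed" or "unlabeled"

    @property
    def balanced(self) -> bool:
        return self.role == "balanced"


@dataclass
class NetworkModel:
    """A validated reaction network with atom maps and species roles."""

    reactions: list[Reaction]
    metabolites: dict[str, Metabolite]

    def __post_init__(self):
        self._by_id = {r.id: r for r in self.reactions}
        if len(self._by_id) != len(self.reactions):
            raise NetworkError("duplicate reaction ids")

    def reaction(self, rid: str) -> Reaction:
        return self._by_id[rid]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def compartments(self) -> set[str]:
        return {
            m.compartment for m in self.metabolites.values() if m.compartment
        }

    def balanced_metabolites(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if m.balanced]

    def producers(self, met: str) -> list[tuple[Reaction, bool]]:
        """(reaction, is_forward_direction) pairs producing ``met``."""
        out = []
        for r in self.reactions:
            if met in r.products:
                out.append((r, True))
            if r.reversible and met in r.substrates:
                out.append((r, False))
        return out

    def validate(self) -> None:
        for r in self.reactions:
            for met, m in zip(
                r.substrates + r.products,
                r.atom_map.substrates + r.atom_map.products,
            ):
                if met not in self.metabolites:
                    raise NetworkError(f"{r.id}: unknown metabolite {met}")
                if self.metabolites[met].n_carbons != len(m):
                    raise NetworkError(
                        f"{r.id}: carbon count of {met} inconsistent "
                        f"({len(m)} vs {self.metabolites[met].n_carbons})"
                    )
        for met in self.balanced_metabolites():
            has_prod = any(met in r.products for r in self.reactions) or any(
                r.reversible and met in r.substrates for r in self.reactions
            )
            has_cons = any(met in r.substrates for r in self.reactions) or any(
                r.reversible and met in r.products for r in self.reactions
            )
            if not (has_prod and has_cons):
                raise NetworkError(
                    f"balanced metabolite {met} lacks a producer or consumer"
                )
        self._check_reachability()

    def _check_reachability(self) -> None:
        import networkx as nx

        g = nx.DiGraph()
        for r in self.reactions:
            for s in r.substrates:
                for p in r.products:
                    g.add_edge(s, p)
                    if r.reversible:
                        g.add_edge(p, s)
        feeds = [
            m.id
            for m in self.metabolites.values()
            if m.role == "source"
        ]
        reachable: set[str] = set()
        import networkx as nx

        for f in feeds:
            if f in g:
                reachable |= nx.descendants(g, f) | {f}
        unreachable = set(self.balanced_metabolites()) - reachable
        if unreachable:
            raise NetworkError(
                f"balanced metabolites unreachable from sources: {sorted(unreachable)}"
            )

    def subset(self, groups: set[str]) -> "NetworkModel":
        rxns = [r for r in self.reactions if r.group in groups]
        used = set()
        for r in rxns:
            used.update(r.substrates)
            used.update(r.products)
        mets = {k: v for k, v in self.metabolites.items() if k in used}
        model = NetworkModel(rxns, mets)
        model.validate()
        return model


# ---------------------------------------------------------------------------
# DSL parsing
# ---------------------------------------------------------------------------

_RXN_RE = re.compile(
    r"^(?P<id>[\w.]+)\s*:\s*(?P<eq>.+?)\s*,\s*(?P<map>.+?)\s*;\s*"
    r"(?P<rev>reversible|irreversible)\s*$"
)


def _split_side(text: str) -> list[str]:
    return [t.strip() for t in text.split("+")]


def parse_network(text: str) -> NetworkModel:
    """Parse a network DSL document.

    Grammar, one statement per line (``#`` comments allowed)::

        @group <name>
        source <metabolite> [feed|unlabeled]
        sink <metabolite>
        <id>: S1 [+ S2] -> P1 [+ P2] , map1 [+ map2] -> map3 [+ map4] ; reversible|irreversible

    Carbon counts are inferred from the atom maps and cross-checked across
    reactions.  Atom-unbalanced reactions are rejected.
    """
    reactions: list[Reaction] = []
    roles: dict[str, tuple[str, str]] = {}
    carbon: dict[str, int] = {}
    group = "base"
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("@group"):
            group = line.split(None, 1)[1].strip()
            continue
        if line.startswith("source ") or line.startswith("sink "):
            parts = line.split()
            role = parts[0]
            met = parts[1]
            label = parts[2] if len(parts) > 2 else "unlabeled"
            roles[met] = (role, label)
            continue
        m = _RXN_RE.match(line)
        if m is None:
            raise NetworkError(f"line {lineno}: syntax error in {line!r}")
        eq, amap = m.group("eq"), m.group("map")
        if "->" not in eq or "->" not in amap:
            raise NetworkError(f"line {lineno}: missing '->'")
        subs_t, prods_t = eq.split("->")
        msubs_t, mprods_t = amap.split("->")
        subs = tuple(_split_side(subs_t))
        prods = tuple(_split_side(prods_t))
        msubs = tuple(_split_side(msubs_t))
        mprods = tuple(_split_side(mprods_t))
        if len(subs) != len(msubs) or len(prods) != len(mprods):
            raise NetworkError(
                f"line {lineno}: reaction {m.group('id')} atom map arity mismatch"
            )
        nsub = sum(len(s) for s in msubs)
        nprod = sum(len(s) for s in mprods)
        if nsub != nprod:
            raise NetworkError(
                f"line {lineno}: reaction {m.group('id')} atom count mismatch "
                f"({nsub} substrate vs {nprod} product carbons)"
            )
        try:
            atom_map = AtomMap(msubs, mprods)
        except NetworkError as e:
            raise NetworkError(f"line {lineno}: {e}") from None
        for met, letters in zip(subs + prods, msubs + mprods):
            if met in carbon and carbon[met] != len(letters):
                raise NetworkError(
                    f"line {lineno}: {met} carbon count conflicts "
                    f"({len(letters)} vs {carbon[met]})"
                )
            carbon[met] = len(letters)
        reactions.append(
            Reaction(
                m.group("id"),
                subs,
                prods,
                atom_map,
                m.group("rev") == "reversible",
                group,
            )
        )
    if not reactions:
        raise NetworkError("empty network document")
    mets: dict[str, Metabolite] = {}
    for met, n in carbon.items():
        comp = None
        for c in COMPARTMENTS:
            if met.endswith(c):
                comp = c
        role, label = roles.get(met, ("balanced", "unlabeled"))
        role = {"source": "source", "sink": "sink"}.get(role, "balanced")
        mets[met] = Metabolite(met, n, comp, role, label)
    for met in roles:
        if met not in mets:
            raise NetworkError(f"declared species {met} never used in a reaction")
    model = NetworkModel(reactions, mets)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Canonical network fixture
# ---------------------------------------------------------------------------

CANONICAL_NETWORK_TEXT = """\
# Photosynthetic carbon metabolism, compartments .p (stroma), .c (cytosol),
# .m (mitochondrion), .v (vacuole).  One intracellular CO2 pool (CO2i) is
# fed from the atmosphere (CO2ext) and receives photorespired/shunt CO2.
source CO2ext feed
source GLCu unlabeled
source CO2u unlabeled
source TPu unlabeled
source STARCHu unlabeled
sink STARCH
sink SUCX
sink TRIOSEX
sink CO2X

@group base
rubisco_c: RUBP.p + CO2i -> PGA.p + PGA.p , abcde + f -> fba + cde ; irreversible
rubisco_o: RUBP.p -> 2PG.p + PGA.p , abcde -> ba + cde ; irreversible
pga_red: PGA.p -> GAP.p , abc -> abc ; reversible
tpi_p: GAP.p -> DHAP.p , abc -> abc ; reversible
fba_p: DHAP.p + GAP.p -> FBP.p , cba + def -> cbadef ; reversible
fbpase_p: FBP.p -> F6P.p , abcdef -> abcdef ; irreversible
tk1_p: F6P.p + GAP.p -> E4P.p + XU5P.p , abcdef + ghi -> cdef + abghi ; reversible
sba_p: E4P.p + DHAP.p -> SBP.p , defg + cba -> cbadefg ; reversible
sbpase_p: SBP.p -> S7P.p , abcdefg -> abcdefg ; irreversible
tk2_p: S7P.p + GAP.p -> R5P.p + XU5P.p , abcdefg + hij -> cdefg + abhij ; reversible
rpi_p: R5P.p -> RU5P.p , abcde -> abcde ; reversible
rpe_p: XU5P.p -> RU5P.p , abcde -> abcde ; reversible
prk_p: RU5P.p -> RUBP.p , abcde -> abcde ; irreversible
pgi_p: F6P.p -> G6P.p , abcdef -> abcdef ; reversible
adpgs_p: G6P.p -> ADPG.p , abcdef -> abcdef ; irreversible
starch_synth: ADPG.p -> STARCH , abcdef -> abcdef ; irreversible
tpt: DHAP.p -> DHAP.c , abc -> abc ; reversible
xpt: XU5P.c -> XU5P.p , abcde -> abcde ; irreversible
pr_glycolate: 2PG.p -> GLY.m , ab -> ab ; irreversible
gdc: GLY.m + GLY.m -> SER.m + CO2i , ab + cd -> cdb + a ; irreversible
ser_hpr: SER.m -> GA.c , abc -> abc ; irreversible
gck: GA.c -> PGA.p , abc -> abc ; irreversible
tpi_c: DHAP.c -> GAP.c , abc -> abc ; reversible
fba_c: DHAP.c + GAP.c -> FBP.c , cba + def -> cbadef ; reversible
fbpase_c: FBP.c -> F6P.c , abcdef -> abcdef ; irreversible
pgi_c: F6P.c -> G6P.c , abcdef -> abcdef ; reversible
ugp_c: G6P.c -> UDPG.c , abcdef -> abcdef ; irreversible
sps_c: UDPG.c + F6P.c -> SUC.c , abcdef + ghijkl -> abcdefghijkl ; irreversible
suc_export: SUC.c -> SUCX , abcdefghijkl -> abcdefghijkl ; irreversible
shunt_c: G6P.c -> RU5P.c + CO2i , abcdef -> bcdef + a ; irreversible
rpe_c: RU5P.c -> XU5P.c , abcde -> abcde ; reversible
triose_efflux: DHAP.c -> TRIOSEX , abc -> abc ; irreversible
co2_feed: CO2ext -> CO2i , a -> a ; irreversible
co2_efflux: CO2i -> CO2X , a -> a ; irreversible

@group recycling
inv_c: SUC.c -> GLC.c + FRC.c , abcdefghijkl -> abcdef + ghijkl ; irreversible
hxk_c: GLC.c -> G6P.c , abcdef -> abcdef ; irreversible
frk_c: FRC.c -> F6P.c , abcdef -> abcdef ; irreversible
suc_vt: SUC.c -> SUC.v , abcdefghijkl -> abcdefghijkl ; reversible
inv_v: SUC.v -> GLC.v + FRC.v , abcdefghijkl -> abcdef + ghijkl ; irreversible
glc_vt: GLC.v -> GLC.c , abcdef -> abcdef ; irreversible
frc_vt: FRC.v -> FRC.c , abcdef -> abcdef ; irreversible

@group entry
glc_entry_c: GLCu -> G6P.c , abcdef -> abcdef ; irreversible
glc_entry_p: GLCu -> G6P.p , abcdef -> abcdef ; irreversible
co2_entry: CO2u -> CO2i , a -> a ; irreversible
tp_entry_p: TPu -> DHAP.p , abc -> abc ; irreversible
starch_turnover: STARCHu -> G6P.p , abcdef -> abcdef ; irreversible

@group starch_variant
oligo_syn: ADPG.p -> OLIGO.p , abcdef -> abcdef ; irreversible
oligo_to_starch: OLIGO.p -> STARCH , abcdef -> abcdef ; irreversible
oligo_turnover: OLIGO.p -> G6P.p , abcdef -> abcdef ; irreversible
"""


def canonical_network_text() -> str:
    """The canonical network DSL document (all groups)."""
    return CANONICAL_NETWORK_TEXT


def full_canonical_network() -> NetworkModel:
    """Parse the complete canonical document: base + recycling + entry +
    starch-turnover reactions, with group tags retained."""
    return parse_network(CANONICAL_NETWORK_TEXT)


def canonical_network() -> NetworkModel:
    """The base (V0) network: CBC, photorespiration, sucrose/starch
    synthesis and the cytosolic G6P shunt — no recycling, no entry fluxes."""
    return full_canonical_network().subset({"base"})


#: hypothesis variants for where unlabeled carbon enters the system
VARIANT_IDS = (
    "V0",
    "V1",
    "V2",
    "V3",
    "V4",
    "V5",
    "starch_whole",
    "starch_intermediate",
)

#: reactions each variant adds on top of the base network
VARIANT_EXTRA: dict[str, tuple[str, ...]] = {
    "V0": (),
    "V1": ("glc_entry_c",),
    "V2": ("glc_entry_p",),
    "V3": ("co2_entry",),
    "V4": ("tp_entry_p",),
    "V5": (
        "inv_c",
        "hxk_c",
        "frk_c",
        "suc_vt",
        "inv_v",
        "glc_vt",
        "frc_vt",
    ),
    "starch_whole": ("starch_turnover",),
    "starch_intermediate": ("oligo_syn", "oligo_to_starch", "oligo_turnover"),
}

#: the free entry-flux parameter of each variant (None for V0)
VARIANT_ENTRY: dict[str, str | None] = {
    "V0": None,
    "V1": "glc_entry_c",
    "V2": "glc_entry_p",
    "V3": "co2_entry",
    "V4": "tp_entry_p",
    "V5": "hxk_c",  # glucose entry = hexokinase fed by free-sugar pools
    "starch_whole": "starch_turnover",
    "starch_intermediate": "oligo_turnover",
}


def make_variant(net: NetworkModel, variant_id: str) -> NetworkModel:
    """Base network plus the variant's unlabeled-entry / recycling reactions.

    ``V0`` returns a network with the identical reaction set.  ``V5`` (the
    final model) activates sucrose recycling, hexokinase/fructokinase and
    tonoplast sugar transport in addition to the glucose entry flux.
    """
    if variant_id not in VARIANT_EXTRA:
        raise NetworkError(
            f"unknown variant {variant_id!r}; known: {sorted(VARIANT_EXTRA)}"
        )
    full = full_canonical_network()
    rxns = list(net.reactions)
    have = {r.id for r in rxns}
    if variant_id == "starch_intermediate":
        rxns = [r for r in rxns if r.id != "starch_synth"]
        have.discard("starch_synth")
    for rid in VARIANT_EXTRA[variant_id]:
        if rid not in have:
            rxns.append(full.reaction(rid))
    mets = dict(net.metabolites)
    for r in rxns:
        for met in r.substrates + r.products:
            if met not in mets:
                mets[met] = full.metabolites[met]
    model = NetworkModel(rxns, mets)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Flux states and steady state
# ---------------------------------------------------------------------------


@dataclass
class FluxState:
    """Net and exchange fluxes, in umol per g fresh weight per hour.

    For a reversible reaction with net flux v and exchange flux e >= 0 the
    forward/backward rates are ``v_f = max(v, 0) + e`` and
    ``v_b = e - min(v, 0)``.  Irreversible reactions must have ``v >= 0``
    and zero exchange.
    """

    net: dict[str, float]
    exch: dict[str, float] = field(default_factory=dict)

    def forward(self, r: Reaction) -> float:
        v = self.net.get(r.id, 0.0)
        e = self.exch.get(r.id, 0.0)
        return max(v, 0.0) + e

    def backward(self, r: Reaction) -> float:
        v = self.net.get(r.id, 0.0)
        e = self.exch.get(r.id, 0.0)
        return e - min(v, 0.0)

    def validate(self, net_model: NetworkModel) -> None:
        for r in net_model.reactions:
            v = self.net.get(r.id, 0.0)
            e = self.exch.get(r.id, 0.0)
            if e < 0:
                raise ValueError(f"{r.id}: exchange flux must be >= 0")
            if not r.reversible:
                if v < -1e-9:
                    raise ValueError(f"{r.id}: irreversible with net {v}")
                if e != 0.0:
                    raise ValueError(f"{r.id}: irreversible with exchange {e}")


def check_steady_state(
    net: NetworkModel, fluxes: FluxState, tol: float = 1e-6
) -> dict[str, dict[str, float]]:
    """Per-metabolite net production report.

    Returns ``{metabolite: {"imbalance": x, "throughput": y, "ok": bool}}``
    for every balanced metabolite; ``ok`` is False where the imbalance
    exceeds ``tol`` relative to the metabolite's throughput (absolute where
    throughput vanishes).
    """
    report = {}
    for met in net.balanced_metabolites():
        prod = cons = 0.0
        for r in net.reactions:
            v = fluxes.net.get(r.id, 0.0)
            s = r.stoich(met)
            flow = s * v
            if flow > 0:
                prod += flow
            else:
                cons -= flow
        imb = prod - cons
        thr = max(prod, cons)
        ok = abs(imb) <= tol * max(thr, 1.0)
        report[met] = {"imbalance": imb, "throughput": thr, "ok": ok}
    return report


# ---------------------------------------------------------------------------
# Carbon accounting (flux-map arithmetic)
# ---------------------------------------------------------------------------


def carbon_accounting(
    fluxes: FluxState | None = None,
    *,
    carboxylation: float | None = None,
    glycerate_return: float | None = None,
    pentose_return: float | None = None,
    photoresp_co2: float | None = None,
    shunt_co2: float | None = None,
    shunt_glucose: float | None = None,
) -> dict[str, float]:
    """Carbon and ATP bookkeeping over a steady-state flux map.

    Either pass a :class:`FluxState` over the canonical network (the
    relevant rates are read off the named reactions) or give the six scalar
    rates directly.  Returned carbons are ``3 x glycerate return`` from
    photorespiration and ``5 x pentose import`` from the cytosolic G6P
    shunt; net assimilation is carboxylation minus the two CO2 releases;
    the ATP cost per net CO2 is ``3 + 3 x shunt glucose flux / net
    assimilation`` (three ATP per glucose cycled through the shunt).
    Percentages are reported at full precision under ``*_pct`` and rounded
    to integers under ``*_pct_rounded``.
    """
    if fluxes is not None:
        carboxylation = fluxes.net.get("rubisco_c", 0.0)
        glycerate_return = fluxes.net.get("gck", 0.0)
        pentose_return = fluxes.net.get("xpt", 0.0)
        photoresp_co2 = fluxes.net.get("gdc", 0.0)
        shunt_co2 = fluxes.net.get("shunt_c", 0.0)
        shunt_glucose = fluxes.net.get("shunt_c", 0.0)
    vals = [
        carboxylation,
        glycerate_return,
        pentose_return,
        photoresp_co2,
        shunt_co2,
        shunt_glucose,
    ]
    if any(v is None for v in vals):
        raise ValueError("incomplete accounting inputs")
    net = carboxylation - photoresp_co2 - shunt_co2
    if net <= 0:
        raise ValueError(f"net assimilation must be positive, got {net}")
    pr_carbons = 3.0 * glycerate_return
    shunt_carbons = 5.0 * pentose_return
    photoresp_pct = 100.0 * photoresp_co2 / net
    shunt_pct = 100.0 * shunt_co2 / net
    atp = 3.0 + 3.0 * shunt_glucose / net
    return {
        "carboxylation": float(carboxylation),
        "net_assimilation": float(net),
        "photorespiration_return_carbons": pr_carbons,
        "shunt_return_carbons": shunt_carbons,
        "extra_carbons": pr_carbons + shunt_carbons,
        "photoresp_co2_pct": photoresp_pct,
        "shunt_co2_pct": shunt_pct,
        "photoresp_co2_pct_rounded": round(photoresp_pct),
        "shunt_co2_pct_rounded": round(shunt_pct),
        "atp_per_net_co2": atp,
    }


# ---------------------------------------------------------------------------
# Photorespiratory atom trace
# ---------------------------------------------------------------------------


def photorespiration_return_fraction(
    net: NetworkModel,
    start: str = "2PG.p",
    target: str = "PGA.p",
    terminal: set[str] | None = None,
) -> float:
    """Fraction of carbon leaving as 2-phosphoglycolate that returns to the
    CBC entry metabolite.

    Assigns a unit steady-state flux of ``start`` production, balances the
    downstream salvage subnetwork, and counts the carbons delivered to
    ``target`` per carbon leaving as ``start``.  Released CO2 (any
    metabolite whose id starts with "CO2", or the ``terminal`` set) is
    treated as lost.  The value is invariant to how finely the
    glycine/serine steps are lumped.
    """
    if start not in net.metabolites:
        raise NetworkError(f"photorespiratory start {start} absent")
    if terminal is None:
        terminal = {m for m in net.metabolites if m.startswith("CO2")}
    # forward-reachable salvage subnetwork from start, stopping at target
    sub: list[Reaction] = []
    frontier = {start}
    seen_mets = {start}
    while frontier:
        nxt = set()
        for r in net.reactions:
            if r in sub:
                continue
            if any(s in frontier for s in r.substrates):
                sub.append(r)
                for p in r.products:
                    m = net.metabolites[p]
                    if (
                        p != target
                        and p not in terminal
                        and m.balanced
                        and p not in seen_mets
                    ):
                        nxt.add(p)
                        seen_mets.add(p)
        frontier = nxt
    sub = [r for r in sub if r.id != "rubisco_o"]
    seen_mets -= terminal
    if not any(target in r.products for r in sub):
        raise NetworkError(f"no salvage path from {start} to {target}")
    # balance intermediates (everything reachable except start itself)
    inter = sorted(seen_mets - {start})
    A = np.zeros((len(inter) + 1, len(sub)))
    b = np.zeros(len(inter) + 1)
    for j, r in enumerate(sub):
        for i, met in enumerate(inter):
            A[i, j] = r.stoich(met)
        A[len(inter), j] = r.stoich(start)
    b[len(inter)] = -1.0  # unit exogenous production of start
    if np.linalg.matrix_rank(A) < len(sub):
        raise NetworkError(
            "salvage subnetwork underdetermined: branch fluxes not fixed "
            "by stoichiometry"
        )
    v, res, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.linalg.norm(A @ v - b) > 1e-8:
        raise NetworkError("salvage subnetwork cannot reach steady state")
    n_start = net.metabolites[start].n_carbons
    returned = 0.0
    for j, r in enumerate(sub):
        c = r.carbon_count(target, "product")
        if c:
            returned += v[j] * c
    return float(returned / n_start)


# ---------------------------------------------------------------------------
# Reference flux map (balanced by construction)
# ---------------------------------------------------------------------------

#: default exchange fluxes of the reversible reactions, umol/gFW/h
DEFAULT_EXCHANGES = {
    "pga_red": 20.0,
    "tpi_p": 50.0,
    "fba_p": 10.0,
    "tk1_p": 10.0,
    "sba_p": 5.0,
    "tk2_p": 10.0,
    "rpi_p": 20.0,
    "rpe_p": 20.0,
    "pgi_p": 10.0,
    "tpt": 10.0,
    "tpi_c": 5.0,
    "fba_c": 2.0,
    "pgi_c": 5.0,
    "rpe_c": 2.0,
    "suc_vt": 0.5,
}


def reference_fluxes(
    variant: str = "V0",
    *,
    carboxylation: float = 172.0,
    oxygenation: float = 50.0,
    shunt: float = 7.0,
    starch: float = 10.0,
    sucrose_export: float = 6.0,
    invertase_c: float = 1.6,
    vacuole_cycle: float = 0.3,
    co2_efflux: float = 15.0,
    glc_entry: float = 0.0,
    glc_entry_p: float = 0.0,
    co2_entry: float = 0.0,
    tp_entry: float = 0.0,
    starch_turn: float = 0.0,
    exchanges: dict[str, float] | None = None,
) -> FluxState:
    """Construct a steady-state flux map from physiological free fluxes.

    The free fluxes are the knobs a leaf physiologist would set:
    carboxylation v_c, oxygenation v_o, the G6P-shunt rate, starch and
    sucrose synthesis, the sucrose-recycling and vacuolar-cycling rates,
    and the variant entry fluxes.  All dependent fluxes follow from carbon
    and metabolite balances; the cytosolic triose efflux (lumped TCA /
    amino-acid drain) closes the overall carbon balance.  Fluxes of
    reactions absent from a variant are zero.

    This parameterization spans the steady-state null space reachable under
    the fitting defaults, so every returned state balances every metabolite
    exactly.
    """
    if variant not in VARIANT_EXTRA:
        raise NetworkError(f"unknown variant {variant!r}")
    recycling = variant == "V5"
    ic = invertase_c if recycling else 0.0
    w = vacuole_cycle if recycling else 0.0
    e1 = glc_entry if variant == "V1" else 0.0
    e2 = glc_entry_p if variant == "V2" else 0.0
    e3 = co2_entry if variant == "V3" else 0.0
    e4 = tp_entry if variant == "V4" else 0.0
    est = starch_turn if variant in ("starch_whole", "starch_intermediate") else 0.0

    vc, vo, sh = carboxylation, oxygenation, shunt
    a, X = starch, sucrose_export
    gr = vo / 2.0  # glycerate return = photorespired CO2 release
    hxk = frk = ic + w
    sps = X + ic + w
    ugp = sps
    pgi_c = ugp + sh - hxk - e1
    fba_c = sps + pgi_c - frk
    tpi_c = fba_c
    # starch_intermediate recycles its own (labeled) carbon; no external entry
    ext_hexose = e1 + e2 + (est if variant == "starch_whole" else 0.0)
    efflux = (vc - gr - sh + 6.0 * ext_hexose + 3.0 * e4 - 6.0 * a - 12.0 * X) / 3.0
    if efflux < -1e-9:
        raise ValueError(
            "carbon balance infeasible: sinks exceed net fixation "
            f"(triose efflux would be {efflux:.3f})"
        )
    tpt = tpi_c + fba_c + max(efflux, 0.0)
    prk = vc + vo
    t1 = (vc + vo - sh) / 3.0
    adpgs = a + est if variant == "starch_intermediate" else a
    pgi_p = a if variant == "starch_intermediate" else a - e2 - est
    fba_p = t1 + pgi_p
    pga_red = 2.0 * vc + vo + gr
    tpi_p = pga_red - fba_p - 2.0 * t1
    feed = vc + co2_efflux - gr - sh - e3
    if feed < 0:
        raise ValueError("CO2 feed flux would be negative; raise co2_efflux")

    net = {
        "rubisco_c": vc,
        "rubisco_o": vo,
        "pga_red": pga_red,
        "tpi_p": tpi_p,
        "fba_p": fba_p,
        "fbpase_p": fba_p,
        "tk1_p": t1,
        "sba_p": t1,
        "sbpase_p": t1,
        "tk2_p": t1,
        "rpi_p": t1,
        "rpe_p": 2.0 * t1 + sh,
        "prk_p": prk,
        "pgi_p": pgi_p,
        "adpgs_p": adpgs,
        "starch_synth": a,
        "tpt": tpt,
        "xpt": sh,
        "pr_glycolate": vo,
        "gdc": vo / 2.0,
        "ser_hpr": gr,
        "gck": gr,
        "tpi_c": tpi_c,
        "fba_c": fba_c,
        "fbpase_c": fba_c,
        "pgi_c": pgi_c,
        "ugp_c": ugp,
        "sps_c": sps,
        "suc_export": X,
        "shunt_c": sh,
        "rpe_c": sh,
        "triose_efflux": max(efflux, 0.0),
        "co2_feed": feed,
        "co2_efflux": co2_efflux,
    }
    if recycling:
        net.update(
            {
                "inv_c": ic,
                "hxk_c": hxk,
                "frk_c": frk,
                "suc_vt": w,
                "inv_v": w,
                "glc_vt": w,
                "frc_vt": w,
            }
        )
    if variant == "V1":
        net["glc_entry_c"] = e1
    if variant == "V2":
        net["glc_entry_p"] = e2
    if variant == "V3":
        net["co2_entry"] = e3
    if variant == "V4":
        net["tp_entry_p"] = e4
    if variant == "starch_whole":
        net["starch_turnover"] = est
    if variant == "starch_intermediate":
        net.pop("starch_synth")
        net["oligo_syn"] = a + est
        net["oligo_to_starch"] = a
        net["oligo_turnover"] = est
    exch = dict(DEFAULT_EXCHANGES)
    if not recycling:
        exch.pop("suc_vt", None)
    if exchanges is not None:
        exch.update(exchanges)
    return FluxState(net=net, exch=exch)


#: pool sizes, umol per g fresh weight; three turnover scales by design:
#: CBC intermediates (seconds), cytosolic hexose-P/sucrose (minutes to ~1 h),
#: vacuolar sugars (many hours)
DEFAULT_POOLS = {
    "RUBP.p": 0.4,
    "PGA.p": 1.2,
    "GAP.p": 0.05,
    "DHAP.p": 0.15,
    "FBP.p": 0.2,
    "F6P.p": 0.3,
    "G6P.p": 0.5,
    "E4P.p": 0.02,
    "XU5P.p": 0.05,
    "S7P.p": 0.2,
    "SBP.p": 0.1,
    "R5P.p": 0.03,
    "RU5P.p": 0.03,
    "ADPG.p": 0.02,
    "2PG.p": 0.1,
    "GLY.m": 2.0,
    "SER.m": 3.0,
    "GA.c": 0.05,
    "CO2i": 0.02,
    "DHAP.c": 0.03,
    "GAP.c": 0.01,
    "FBP.c": 0.02,
    "F6P.c": 1.5,
    "G6P.c": 3.5,
    "UDPG.c": 1.0,
    "SUC.c": 8.0,
    "GLC.c": 0.5,
    "FRC.c": 0.5,
    "RU5P.c": 0.05,
    "XU5P.c": 0.05,
    "SUC.v": 20.0,
    "GLC.v": 3.0,
    "FRC.v": 2.5,
    "OLIGO.p": 0.5,
}


def reference_pools(net: NetworkModel) -> dict[str, float]:
    """Default pool sizes restricted to the metabolites of ``net``."""
    return {
        m: DEFAULT_POOLS[m]
        for m in net.balanced_metabolites()
        if m in DEFAULT_POOLS
    }
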