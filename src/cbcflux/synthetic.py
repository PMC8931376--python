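"""Ground-truth-known synthetic labeling experiments.

Each scenario pins a hypothesis variant, a balanced flux map and pool
sizes, and emulates the study design: a 12CO2 -> 13CO2 switch at t=0,
sampling at 14 time points over 0-120 min, MID measurement of ~20 central
metabolites with per-channel Gaussian noise, and gas-exchange/export
scalars.  The defaults realise the three-timescale mechanism the package
exists to analyse: sub-minute Calvin-Benson cycle turnover, cytosolic
hexose-phosphate/sucrose recycling over tens of minutes, and vacuolar
sugar pools turning over on the timescale of hours, coupled to the cycle
through the cytosolic G6P shunt.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fluxfit import (
    DEFAULT_OBSERVABLES,
    MeasurementSet,
    OBSERVABLE_POOLS,
    PAPER_TIMES_MIN,
    scalar_predictions,
)
from .mid import LabelTimeCourse, MIDVector
from .network import (
    FluxState,
    NetworkModel,
    canonical_network,
    check_steady_state,
    make_variant,
    reference_fluxes,
    reference_pools,
)
from .simulate import CompiledLabelingModel, PoolSizes
from .emu import emu_decompose

__all__ = [
    "Scenario",
    "scenario",
    "generate_dataset",
    "aggregate_replicates",
    "SCENARIO_NAMES",
    "CBC_AGGREGATE",
]

#: the seven CBC intermediates aggregated in the washout analysis
CBC_AGGREGATE = ("DHAP", "E4P", "FBP", "GAP", "PGA", "RUBP", "S7P")

SCENARIO_NAMES = (
    "base_no_reentry",
    "glucose_reentry",
    "starch_turnover",
    "inactive_pools",
    "final_v5",
)

#: default scalar-measurement SDs (umol/gFW/h except the ratio)
SCALAR_SDS = {
    "net_assimilation": 3.0,
    "sucrose_export": 0.5,
    "triose_export": 0.5,
    "vo_vc": 0.02,
}


@dataclass
class Scenario:
    """A fully specified synthetic labeling experiment."""

    name: str
    variant: str
    fluxes: FluxState
    pools: PoolSizes
    times_min: np.ndarray = field(
        default_factory=lambda: np.array(PAPER_TIMES_MIN, dtype=float)
    )
    noise_sd: float = 0.01  # absolute SD per MID channel
    input_enrichment: float = 0.99
    observables: tuple[str, ...] = DEFAULT_OBSERVABLES
    network: NetworkModel | None = None

    def __post_init__(self):
        if self.network is None:
            self.network = make_variant(canonical_network(), self.variant)
        report = check_steady_state(self.network, self.fluxes, tol=1e-8)
        bad = [k for k, v in report.items() if not v["ok"]]
        if bad:
            raise ValueError(f"scenario truth violates steady state at {bad}")

    def truth(self) -> dict:
        return {
            "name": self.name,
            "variant": self.variant,
            "net_fluxes": dict(self.fluxes.net),
            "exchange_fluxes": dict(self.fluxes.exch),
            "pools": dict(self.pools.sizes),
            "f_inactive": dict(self.pools.f_inactive),
            "input_enrichment": self.input_enrichment,
            "noise_sd": self.noise_sd,
            "scalars": scalar_predictions(self.fluxes),
        }


def scenario(name: str, **overrides) -> Scenario:
    """Construct a named scenario.

    ``final_v5`` is the headline truth: carboxylation 172, photorespired
    CO2 release 25, shunt CO2 release 7, and glucose entry into cytosolic
    hexose phosphate (hexokinase flux) 1.9 umol/gFW/h, with vacuolar
    sucrose/glucose/fructose pools turning over on the hours timescale so
    the free sugars are only ~10-50% labeled by 60 min.  Overrides:
    ``fluxes=dict(...)`` forwards to the flux builder, ``pools=dict(...)``
    updates pool sizes, ``f_inactive=dict(...)`` sets inactive fractions,
    and any :class:`Scenario` field (``times_min``, ``noise_sd``, ...)
    can be replaced.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; known: {SCENARIO_NAMES}")
    flux_kw = dict(overrides.pop("fluxes", {}))
    pool_upd = dict(overrides.pop("pools", {}))
    f_in = dict(overrides.pop("f_inactive", {}))

    if name == "base_no_reentry":
        variant = "V0"
    elif name == "glucose_reentry":
        variant = "V1"
        flux_kw.setdefault("glc_entry", 1.9)
    elif name == "starch_turnover":
        variant = "starch_whole"
        flux_kw.setdefault("starch_turn", 0.5)
    elif name == "inactive_pools":
        variant = "V0"
        f_in.setdefault("GLY", 0.3)
        f_in.setdefault("SER", 0.3)
    else:  # final_v5: invertase 1.6 + vacuolar efflux 0.3 -> hexokinase 1.9
        variant = "V5"

    fluxes = reference_fluxes(variant, **flux_kw)
    net = make_variant(canonical_network(), variant)
    pools = reference_pools(net)
    pools.update(pool_upd)
    sc = Scenario(
        name=name,
        variant=variant,
        fluxes=fluxes,
        pools=PoolSizes(pools, f_in),
        network=net,
    )
    if overrides:
        sc = replace(sc, **overrides)
    return sc


def _apply_noise(mix: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Additive truncated-Gaussian channel noise with renormalization."""
    noisy = np.clip(mix + rng.normal(0.0, sd, mix.shape), 0.0, None)
    return noisy / noisy.sum(axis=1, keepdims=True)


def _simulate_observables(sc: Scenario) -> dict[str, np.ndarray]:
    """Noise-free mixed (compartment-weighted) MIDs per observable."""
    observed = []
    members = []
    for name in sc.observables:
        mem = [
            (met, atoms)
            for met, atoms in OBSERVABLE_POOLS[name]
            if met in sc.network.metabolites
        ]
        if not mem:
            continue
        members.append((name, mem))
        for met, atoms in mem:
            if atoms is None:
                atoms = tuple(range(1, sc.network.metabolites[met].n_carbons + 1))
            observed.append((f"{name}::{met}", met, atoms))
    sim = CompiledLabelingModel(emu_decompose(sc.network, observed)).simulate(
        sc.fluxes,
        sc.pools,
        sc.times_min,
        input_enrichment=sc.input_enrichment,
    )
    mixed = {}
    for name, mem in members:
        num = None
        wtot = 0.0
        for met, _ in mem:
            w = sc.pools[met]
            arr = sim[f"{name}::{met}"].as_array()
            num = w * arr if num is None else num + w * arr
            wtot += w
        mix = num / wtot
        f = sc.pools.f_inactive.get(name, 0.0)
        if f:
            init = np.zeros(mix.shape[1])
            init[0] = 1.0
            mix = (1 - f) * mix + f * init
        mixed[name] = mix
    return mixed


def generate_dataset(
    sc: Scenario, seed: int | None = None
) -> tuple[MeasurementSet, MeasurementSet, dict]:
    """Simulate a scenario and return (noisy, noise-free, truth).

    MID noise is additive Gaussian per channel (SD ``sc.noise_sd``),
    clipped at zero and renormalized to the simplex; the recorded SDs are
    the nominal ones.  Scalar measurements are the truth values with
    Gaussian noise at the stated SDs (exact when ``noise_sd`` is zero).
    Byte-identical output for equal seeds.
    """
    rng = np.random.default_rng(seed)
    mixed = _simulate_observables(sc)
    clean_mids: dict[str, LabelTimeCourse] = {}
    noisy_mids: dict[str, LabelTimeCourse] = {}
    for name, mix in mixed.items():
        sds = np.full(mix.shape, max(sc.noise_sd, 1e-4))
        clean_mids[name] = LabelTimeCourse(
            name, sc.times_min, [MIDVector(name, r) for r in mix], sds=sds.copy()
        )
        noisy = _apply_noise(mix, sc.noise_sd, rng) if sc.noise_sd > 0 else mix
        noisy_mids[name] = LabelTimeCourse(
            name, sc.times_min, [MIDVector(name, r) for r in noisy], sds=sds
        )

    truth_scalars = scalar_predictions(sc.fluxes)
    scalars_clean = {k: (truth_scalars[k], sd) for k, sd in SCALAR_SDS.items()}
    scalars_noisy = {
        k: (v + (rng.normal(0.0, sd) if sc.noise_sd > 0 else 0.0), sd)
        for k, (v, sd) in scalars_clean.items()
    }
    return (
        MeasurementSet(noisy_mids, scalars_noisy),
        MeasurementSet(clean_mids, scalars_clean),
        sc.truth(),
    )


def aggregate_replicates(
    sc: Scenario,
    metabolites: tuple[str, ...] = CBC_AGGREGATE,
    n_replicates: int = 6,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled replicate-level %12C washout dataset of the CBC aggregate.

    Emulates the aggregated-intermediates design: each biological
    replicate contributes one pool-weighted aggregate %12C series, with
    channel-level measurement noise applied to every metabolite's MID
    before aggregation.  Returns flat ``(times_min, percent_12c)`` arrays
    of length ``n_times * n_replicates``, time-sorted.
    """
    rng = np.random.default_rng(seed)
    mixed = _simulate_observables(sc)
    missing = [m for m in metabolites if m not in mixed]
    if missing:
        raise KeyError(f"aggregate metabolites not observed: {missing}")
    weights = np.array(
        [
            sum(sc.pools[met] for met, _ in OBSERVABLE_POOLS[m] if met in sc.network.metabolites)
            * (mixed[m].shape[1] - 1)
            for m in metabolites
        ]
    )
    weights = weights / weights.sum()
    ts, us = [], []
    for _ in range(n_replicates):
        per_met = []
        for m in metabolites:
            # %12C is a linear functional of the channels; noise is added
            # without clipping (corrected MS intensities may dip below
            # zero) so the derived series is unbiased Gaussian
            arr = mixed[m] + rng.normal(0.0, sc.noise_sd, mixed[m].shape)
            n = arr.shape[1] - 1
            i = np.arange(n + 1)
            per_met.append(100.0 * (arr * (n - i)).sum(axis=1) / n)
        ts.append(np.asarray(sc.times_min, float))
        us.append(weights @ np.array(per_met))
    t = np.concatenate(ts)
    u = np.clip(np.concatenate(us), 0.0, 100.0)
    order = np.argsort(t, kind="stable")
    return t[order], u[order]
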