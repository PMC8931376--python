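"""Fitting fluxes and pool sizes to MID time courses (INST-MFA).

The forward model is the EMU labeling simulation over a hypothesis-variant
network; the parameters are physiological free fluxes (carboxylation,
oxygenation, shunt rate, export and recycling rates, unlabeled-entry
fluxes), selected pool sizes and inactive fractions.  Metabolic steady
state is enforced by construction: every candidate parameter vector is
expanded to a fully balanced flux map through the free-flux
parameterization of :func:`cbcflux.network.reference_fluxes`, so no
penalty terms are needed.  Measurements enter a weighted least-squares
objective; soft constraints (vo/vc ratio, net assimilation, export rates)
are appended as pseudo-measurements with their own SDs.

Mass-spectrometric measurements cannot resolve compartments, so observed
species are pool-size-weighted mixtures of their compartmental pools
(e.g. F6P = F6P.p + F6P.c); the mixing weights move with fitted pool
sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import chi2

from .emu import emu_decompose
from .mid import LabelTimeCourse
from .network import (
    FluxState,
    NetworkModel,
    VARIANT_ENTRY,
    canonical_network,
    make_variant,
    reference_fluxes,
    reference_pools,
)
from .simulate import CompiledLabelingModel, PoolSizes

__all__ = [
    "profile_interval",
    "MeasurementSet",
    "LabelingFluxModel",
    "FluxFitResults",
    "VariantComparison",
    "weighted_ssr",
    "fit_variant",
    "compare_variants",
    "scalar_predictions",
    "KNOB_BOUNDS",
    "ENTRY_KNOBS",
    "OBSERVABLE_POOLS",
    "PAPER_TIMES_MIN",
]

#: the study's sampling grid, minutes
PAPER_TIMES_MIN = (0, 0.5, 1, 2, 2.5, 3, 5, 7, 10, 15, 30, 60, 90, 120)

#: optimizer boxes for the physiological free fluxes, umol/gFW/h
KNOB_BOUNDS: dict[str, tuple[float, float]] = {
    "carboxylation": (50.0, 400.0),
    "oxygenation": (0.0, 150.0),
    "shunt": (0.0, 30.0),
    "starch": (0.0, 40.0),
    "sucrose_export": (0.0, 30.0),
    "invertase_c": (0.0, 10.0),
    "vacuole_cycle": (0.0, 10.0),
    "co2_efflux": (1.0, 100.0),
    "glc_entry": (0.0, 20.0),
    "glc_entry_p": (0.0, 20.0),
    "co2_entry": (0.0, 60.0),
    "tp_entry": (0.0, 30.0),
    "starch_turn": (0.0, 20.0),
}

#: free entry-flux knobs per hypothesis variant; V5's glucose entry is the
#: hexokinase flux fed by sucrose recycling plus vacuolar sugar efflux
ENTRY_KNOBS: dict[str, tuple[str, ...]] = {
    "V0": (),
    "V1": ("glc_entry",),
    "V2": ("glc_entry_p",),
    "V3": ("co2_entry",),
    "V4": ("tp_entry",),
    "V5": ("invertase_c", "vacuole_cycle"),
    "starch_whole": ("starch_turn",),
    "starch_intermediate": ("starch_turn",),
}

#: observed species -> compartmental member pools (atom range optional);
#: sucrose is observed as its glucosyl/fructosyl moieties
OBSERVABLE_POOLS: dict[str, list[tuple[str, tuple[int, ...] | None]]] = {
    "RUBP": [("RUBP.p", None)],
    "PGA": [("PGA.p", None)],
    "GAP": [("GAP.p", None), ("GAP.c", None)],
    "DHAP": [("DHAP.p", None), ("DHAP.c", None)],
    "FBP": [("FBP.p", None), ("FBP.c", None)],
    "E4P": [("E4P.p", None)],
    "S7P": [("S7P.p", None)],
    "SBP": [("SBP.p", None)],
    "R5P": [("R5P.p", None)],
    "RU5P": [("RU5P.p", None), ("RU5P.c", None)],
    "XU5P": [("XU5P.p", None), ("XU5P.c", None)],
    "F6P": [("F6P.p", None), ("F6P.c", None)],
    "G6P": [("G6P.p", None), ("G6P.c", None)],
    "ADPG": [("ADPG.p", None)],
    "UDPG": [("UDPG.c", None)],
    "2PG": [("2PG.p", None)],
    "GLY": [("GLY.m", None)],
    "SER": [("SER.m", None)],
    "SUC_glc": [("SUC.c", tuple(range(1, 7))), ("SUC.v", tuple(range(1, 7)))],
    "SUC_frc": [("SUC.c", tuple(range(7, 13))), ("SUC.v", tuple(range(7, 13)))],
    "GLC": [("GLC.c", None), ("GLC.v", None)],
    "FRC": [("FRC.c", None), ("FRC.v", None)],
}

DEFAULT_OBSERVABLES = tuple(OBSERVABLE_POOLS)


def scalar_predictions(fluxes: FluxState) -> dict[str, float]:
    """Gas-exchange / export quantities implied by a flux map."""
    n = fluxes.net
    return {
        "net_assimilation": (
            n.get("rubisco_c", 0.0)
            - n.get("gdc", 0.0)
            - n.get("shunt_c", 0.0)
            - n.get("co2_entry", 0.0)
        ),
        "sucrose_export": n.get("suc_export", 0.0),
        "triose_export": n.get("triose_efflux", 0.0),
        "shunt_co2": n.get("shunt_c", 0.0),
        "vo_vc": n.get("rubisco_o", 0.0) / max(n.get("rubisco_c", 1.0), 1e-12),
    }


@dataclass
class MeasurementSet:
    """MID time courses plus scalar flux measurements and soft constraints.

    ``mids[name]`` is a :class:`LabelTimeCourse` whose ``sds`` attribute
    holds the per-channel SDs (required for fitting); ``scalars[name]`` are
    ``(value, sd)`` pairs for quantities of :func:`scalar_predictions`
    (the vo/vc ratio constraint lives here as ``"vo_vc"``).
    """

    mids: dict[str, LabelTimeCourse]
    scalars: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        for name, tc in self.mids.items():
            if tc.sds is None:
                raise ValueError(f"measurement {name} lacks channel SDs")
            if np.any(tc.sds <= 0):
                raise ValueError(f"measurement {name} has non-positive SDs")
        for name, (_, sd) in self.scalars.items():
            if sd <= 0:
                raise ValueError(f"scalar {name} has non-positive SD")

    @property
    def n_residuals(self) -> int:
        return sum(tc.as_array().size for tc in self.mids.values()) + len(
            self.scalars
        )

    def restricted(self, names) -> "MeasurementSet":
        return MeasurementSet(
            {k: v for k, v in self.mids.items() if k in names}, dict(self.scalars)
        )


def weighted_ssr(
    sim: dict[str, np.ndarray],
    meas: MeasurementSet,
    sim_scalars: dict[str, float] | None = None,
) -> float:
    """Sum over all MID channels, times and scalar measurements of
    ((sim - meas)/SD)^2."""
    total = 0.0
    for name, tc in meas.mids.items():
        if name not in sim:
            raise KeyError(f"no prediction for measured species {name}")
        total += float(np.sum(((sim[name] - tc.as_array()) / tc.sds) ** 2))
    for name, (val, sd) in meas.scalars.items():
        if sim_scalars is None or name not in sim_scalars:
            raise KeyError(f"no prediction for scalar measurement {name}")
        total += ((sim_scalars[name] - val) / sd) ** 2
    return total


class LabelingFluxModel:
    """INST-MFA model: fluxes + pools of a hypothesis variant vs MID data.

    Parameters
    ----------
    measurements : MeasurementSet
    variant : str
        Hypothesis variant id ("V0".."V5", "starch_whole",
        "starch_intermediate").
    free : sequence of str
        Free parameters: flux knobs of
        :func:`cbcflux.network.reference_fluxes` (see ``KNOB_BOUNDS``),
        ``"pool:<met>"`` for a pool size (log10-parameterized), or
        ``"fin:<observable>"`` for an inactive fraction.
    fixed : dict
        Overrides for non-free knobs.
    pools : dict
        Pool-size overrides (defaults from ``reference_pools``).
    input_enrichment : float
        13C fraction of the CO2 feed after the switch.
    """

    _POOL_BOUNDS = (-3.0, 2.0)  # log10 umol/gFW
    _FIN_BOUNDS = (0.0, 0.8)

    def __init__(
        self,
        measurements: MeasurementSet,
        variant: str = "V5",
        free: tuple[str, ...] | None = None,
        fixed: dict | None = None,
        pools: dict | None = None,
        f_inactive: dict | None = None,
        input_enrichment: float = 0.99,
        rtol: float = 1e-6,
        atol: float = 1e-8,
        base_network: NetworkModel | None = None,
    ):
        self.meas = measurements
        self.variant = variant
        base = base_network if base_network is not None else canonical_network()
        self.network = make_variant(base, variant)
        self.fixed = dict(fixed or {})
        self.pool_base = reference_pools(self.network)
        if pools:
            self.pool_base.update(pools)
        self.f_inactive = dict(f_inactive or {})
        self.input_enrichment = input_enrichment
        self.rtol, self.atol = rtol, atol
        if free is None:
            free = ENTRY_KNOBS[variant]
        self.free = tuple(free)
        for p in self.free:
            if not (
                p in KNOB_BOUNDS or p.startswith("pool:") or p.startswith("fin:")
            ):
                raise ValueError(f"unknown free parameter {p}")

        # channels measurable in this variant (>=1 member pool present)
        self._members: dict[str, list[tuple[str, tuple[int, ...] | None]]] = {}
        dropped = []
        for name in measurements.mids:
            if name not in OBSERVABLE_POOLS:
                raise KeyError(f"unknown observable {name}")
            mem = [
                (met, atoms)
                for met, atoms in OBSERVABLE_POOLS[name]
                if met in self.network.metabolites
            ]
            if mem:
                self._members[name] = mem
            else:
                dropped.append(name)
        if dropped:
            warnings.warn(
                f"variant {variant}: observables without any model pool "
                f"dropped: {dropped}"
            )
        if not self._members:
            raise ValueError("no measurable observables for this variant")
        self.dof = (
            sum(measurements.mids[n].as_array().size for n in self._members)
            + len(measurements.scalars)
            - len(self.free)
        )
        if self.dof <= 0:
            raise ValueError("over-parameterized fit: dof <= 0")

        observed = []
        for name, mem in self._members.items():
            for met, atoms in mem:
                if atoms is None:
                    atoms = tuple(
                        range(1, self.network.metabolites[met].n_carbons + 1)
                    )
                observed.append((f"{name}::{met}", met, atoms))
        self._sim = CompiledLabelingModel(emu_decompose(self.network, observed))
        self._times = next(iter(measurements.mids.values())).times
        for name in self._members:
            if not np.array_equal(measurements.mids[name].times, self._times):
                raise ValueError("all measured time courses must share the grid")

    # ------------------------------------------------------------------
    def _bounds(self):
        lo, hi = [], []
        for p in self.free:
            if p in KNOB_BOUNDS:
                b = KNOB_BOUNDS[p]
            elif p.startswith("pool:"):
                b = self._POOL_BOUNDS
            else:
                b = self._FIN_BOUNDS
            lo.append(b[0])
            hi.append(b[1])
        return np.array(lo), np.array(hi)

    def _expand(self, x: np.ndarray):
        """Parameter vector -> (FluxState, PoolSizes)."""
        knobs = dict(self.fixed)
        pools = dict(self.pool_base)
        f_in = dict(self.f_inactive)
        for p, v in zip(self.free, x):
            if p in KNOB_BOUNDS:
                knobs[p] = float(v)
            elif p.startswith("pool:"):
                pools[p[5:]] = float(10.0**v)
            else:
                f_in[p[4:]] = float(v)
        fluxes = reference_fluxes(self.variant, **knobs)
        return fluxes, PoolSizes(pools, f_in)

    def simulate(self, x: np.ndarray) -> tuple[dict[str, np.ndarray], dict[str, float]]:
        """Mixture MIDs per observable and scalar predictions at ``x``."""
        fluxes, pools = self._expand(x)
        raw = self._sim.simulate(
            fluxes,
            pools,
            self._times,
            input_enrichment=self.input_enrichment,
            rtol=self.rtol,
            atol=self.atol,
        )
        mixed = {}
        for name, mem in self._members.items():
            num = None
            wtot = 0.0
            for met, _ in mem:
                w = pools[met]
                arr = raw[f"{name}::{met}"].as_array()
                num = w * arr if num is None else num + w * arr
                wtot += w
            mix = num / wtot
            f = pools.f_inactive.get(name, 0.0)
            if f:
                init = np.zeros(mix.shape[1])
                init[0] = 1.0
                mix = (1.0 - f) * mix + f * init
            mixed[name] = mix
        return mixed, scalar_predictions(fluxes)

    def residuals(self, x: np.ndarray) -> np.ndarray:
        try:
            mixed, scal = self.simulate(x)
        except (ValueError, RuntimeError):
            return np.full(self.dof + len(self.free), 1e3)
        out = []
        for name in self._members:
            tc = self.meas.mids[name]
            out.append(((mixed[name] - tc.as_array()) / tc.sds).ravel())
        for name, (val, sd) in self.meas.scalars.items():
            out.append(np.array([(scal[name] - val) / sd]))
        return np.concatenate(out)

    def default_start(self) -> np.ndarray:
        x0 = []
        defaults = {
            "carboxylation": 172.0,
            "oxygenation": 50.0,
            "shunt": 7.0,
            "starch": 10.0,
            "sucrose_export": 6.0,
            "invertase_c": 1.6,
            "vacuole_cycle": 0.3,
            "co2_efflux": 15.0,
        }
        for p in self.free:
            if p in KNOB_BOUNDS:
                lo, hi = KNOB_BOUNDS[p]
                x0.append(np.clip(defaults.get(p, (lo + hi) / 10.0), lo, hi))
            elif p.startswith("pool:"):
                x0.append(np.log10(self.pool_base.get(p[5:], 0.5)))
            else:
                x0.append(0.1)
        return np.array(x0)

    def fit(
        self,
        n_starts: int = 20,
        seed: int | None = None,
        xtol: float = 1e-10,
        ftol: float = 1e-10,
        diff_step: float = 1e-4,
    ) -> "FluxFitResults":
        """Multistart bound-constrained weighted least squares."""
        rng = np.random.default_rng(seed)
        lo, hi = self._bounds()
        if not self.free:  # nothing to optimize: evaluate at the defaults
            x = np.empty(0)
            ssr = float(np.sum(self.residuals(x) ** 2))
            fluxes, pools = self._expand(x)
            return FluxFitResults(
                self, x, {}, fluxes, pools, ssr, 0, 0, -1, seed
            )
        starts = [self.default_start()]
        while len(starts) < n_starts:
            starts.append(rng.uniform(lo, hi))
        best = None
        best_idx = -1
        n_ok = 0
        for i, x0 in enumerate(starts):
            try:
                sol = least_squares(
                    self.residuals,
                    np.clip(x0, lo, hi),
                    bounds=(lo, hi),
                    method="trf",
                    xtol=xtol,
                    ftol=ftol,
                    diff_step=diff_step,
                )
            except Exception:
                continue
            n_ok += 1
            ssr = float(np.sum(sol.fun**2))
            if best is None or ssr < best[0]:
                best = (ssr, sol.x)
                best_idx = i
        if best is None:
            raise RuntimeError("no multistart converged")
        ssr, x = best
        fluxes, pools = self._expand(x)
        return FluxFitResults(
            model=self,
            x=x,
            params=dict(zip(self.free, x)),
            fluxes=fluxes,
            pools=pools,
            ssr=ssr,
            n_starts=len(starts),
            n_converged=n_ok,
            best_start=best_idx,
            seed=seed,
        )


@dataclass
class FluxFitResults:
    """Best-fit flux map, pools and diagnostics of a labeling flux fit."""

    model: LabelingFluxModel
    x: np.ndarray
    params: dict[str, float]
    fluxes: FluxState
    pools: PoolSizes
    ssr: float
    n_starts: int
    n_converged: int
    best_start: int
    seed: int | None

    @property
    def dof(self) -> int:
        return self.model.dof

    def entry_flux(self) -> float:
        """The variant's fitted unlabeled-carbon entry flux.

        For V5 this is the glucose entry into cytosolic hexose phosphate,
        i.e. the hexokinase flux (invertase + vacuolar glucose efflux).
        """
        v = self.model.variant
        rid = VARIANT_ENTRY[v]
        if rid is None:
            return 0.0
        return self.fluxes.net.get(rid, 0.0)

    def ssr_by_observable(self) -> pd.Series:
        mixed, scal = self.model.simulate(self.x)
        rows = {}
        for name in self.model._members:
            tc = self.model.meas.mids[name]
            rows[name] = float(
                np.sum(((mixed[name] - tc.as_array()) / tc.sds) ** 2)
            )
        for name, (val, sd) in self.model.meas.scalars.items():
            rows[f"scalar:{name}"] = float(((scal[name] - val) / sd) ** 2)
        return pd.Series(rows).sort_values(ascending=False)

    def summary(self) -> str:
        lines = [
            f"Labeling flux fit, variant {self.model.variant}",
            f"  weighted SSR {self.ssr:.6g} on {self.dof} dof "
            f"({self.n_converged}/{self.n_starts} starts converged, "
            f"best #{self.best_start})",
            "  free parameters:",
        ]
        for p, v in self.params.items():
            if p.startswith("pool:"):
                lines.append(f"    {p:>16} = {10**v:10.4f} umol/gFW")
            else:
                lines.append(f"    {p:>16} = {v:10.4f}")
        if self.model.variant != "V0":
            lines.append(f"  entry flux = {self.entry_flux():.4f} umol/gFW/h")
        acc = scalar_predictions(self.fluxes)
        lines.append(
            f"  net assimilation {acc['net_assimilation']:.2f}, "
            f"vo/vc {acc['vo_vc']:.3f}"
        )
        return "\n".join(lines)

    # -- confidence intervals -------------------------------------------
    def profile_ci(
        self,
        param: str,
        level: float = 0.95,
        step_frac: float = 0.04,
        max_steps: int = 40,
    ) -> dict:
        """Parameter-continuation (profile likelihood) confidence interval.

        Walks the parameter in both directions, re-optimizing the others,
        until the SSR profile crosses ``SSR_min + chi2_1(level)``; the
        bound is found by linear interpolation in SSR.  A direction that
        hits its box bound first is flagged one-sided.
        """
        if param not in self.params:
            raise KeyError(f"{param} is not a free parameter of this fit")
        idx = self.model.free.index(param)
        lo, hi = self.model._bounds()
        thresh = self.ssr + chi2.ppf(level, 1)
        out = {"param": param, "level": level, "ssr_min": self.ssr, "trace": []}

        def refit_at(val):
            x0 = self.x.copy()
            x0[idx] = val
            if len(self.model.free) == 1:
                r = self.model.residuals(x0)
                return float(np.sum(r**2)), x0
            free_idx = [i for i in range(len(x0)) if i != idx]

            def resid(sub):
                xx = x0.copy()
                xx[free_idx] = sub
                return self.model.residuals(xx)

            sol = least_squares(
                resid,
                x0[free_idx],
                bounds=(lo[free_idx], hi[free_idx]),
                method="trf",
                xtol=1e-8,
                ftol=1e-8,
                diff_step=1e-4,
            )
            xx = x0.copy()
            xx[free_idx] = sol.x
            return float(np.sum(sol.fun**2)), xx

        walk = profile_interval(
            lambda v: refit_at(v)[0],
            self.x[idx],
            self.ssr,
            lo[idx],
            hi[idx],
            level=level,
            step_frac=step_frac,
            max_steps=max_steps,
        )
        out.update(walk)
        return out

    def monte_carlo_ci(
        self,
        n_draws: int = 50,
        level: float = 0.95,
        seed: int | None = None,
    ) -> dict:
        """Parametric Monte Carlo intervals: resimulate measurements with
        Gaussian noise at the stated SDs around the best-fit predictions,
        refit each draw (warm-started), percentile intervals."""
        rng = np.random.default_rng(seed)
        mixed, scal = self.model.simulate(self.x)
        lo, hi = self.model._bounds()
        draws = []
        n_fail = 0
        for _ in range(n_draws):
            mids = {}
            for name in self.model._members:
                tc = self.model.meas.mids[name]
                noisy = mixed[name] + rng.normal(0.0, tc.sds)
                noisy = np.clip(noisy, 0.0, None)
                noisy /= noisy.sum(axis=1, keepdims=True)
                mids[name] = LabelTimeCourse(
                    name,
                    tc.times,
                    [type(tc.mids[0])(name, row) for row in noisy],
                    sds=tc.sds,
                )
            scalars = {
                k: (scal[k] + rng.normal(0.0, sd), sd)
                for k, (v, sd) in self.model.meas.scalars.items()
            }
            m = LabelingFluxModel(
                MeasurementSet(mids, scalars),
                self.model.variant,
                self.model.free,
                self.model.fixed,
                dict(self.model.pool_base),
                dict(self.model.f_inactive),
                self.model.input_enrichment,
            )
            try:
                sol = least_squares(
                    m.residuals,
                    self.x.copy(),
                    bounds=(lo, hi),
                    method="trf",
                    xtol=1e-8,
                    ftol=1e-8,
                    diff_step=1e-4,
                )
                draws.append(sol.x)
            except Exception:
                n_fail += 1
        if n_fail > 0.1 * n_draws:
            raise RuntimeError(f"{n_fail}/{n_draws} Monte Carlo refits failed")
        draws = np.array(draws)
        a = (1 - level) / 2
        return {
            "level": level,
            "params": dict(
                zip(
                    self.model.free,
                    zip(
                        np.quantile(draws, a, axis=0),
                        np.quantile(draws, 1 - a, axis=0),
                    ),
                )
            ),
            "draws": draws,
            "n_failed": n_fail,
        }




def profile_interval(
    ssr_at,
    x_hat: float,
    ssr_min: float,
    lo: float,
    hi: float,
    level: float = 0.95,
    step_frac: float = 0.04,
    max_steps: int = 40,
) -> dict:
    """Directional profile-likelihood walk shared by all models.

    ``ssr_at(v)`` returns the profiled SSR with the parameter pinned at v
    (nuisance parameters re-optimized by the caller).  Walks outward from
    ``x_hat`` until SSR crosses ``ssr_min + chi2_1(level)``, locating the
    bound by linear interpolation in SSR; a direction that reaches its box
    limit while still below the threshold is flagged one-sided.
    """
    thresh = ssr_min + chi2.ppf(level, 1)
    step0 = max(abs(x_hat) * step_frac, 0.02)
    out = {"trace": []}
    for direction, key in ((1.0, "upper"), (-1.0, "lower")):
        prev_v, prev_ssr = x_hat, ssr_min
        bound = None
        one_sided = False
        v = x_hat
        step = step0
        for _ in range(max_steps):
            v = v + direction * step
            clipped = v > hi or v < lo
            v = float(np.clip(v, lo, hi))
            ssr_v = float(ssr_at(v))
            out["trace"].append((v, ssr_v))
            if ssr_v >= thresh:
                from scipy.optimize import brentq

                if abs(v - prev_v) > 1e-12 and ssr_v > thresh:
                    bound = float(
                        brentq(
                            lambda z: ssr_at(z) - thresh,
                            min(prev_v, v),
                            max(prev_v, v),
                            xtol=1e-4 * max(abs(v - prev_v), 1e-6),
                            maxiter=50,
                        )
                    )
                else:
                    bound = float(v)
                break
            if clipped:
                bound = v
                one_sided = True
                break
            # grow the step while the profile rises slowly (flat surface)
            if ssr_v - ssr_min < 0.5 * (thresh - ssr_min):
                step *= 1.6
            prev_v, prev_ssr = v, ssr_v
        if bound is None:
            bound = float(v)
            one_sided = True
        out[key] = bound
        out[f"{key}_one_sided"] = one_sided
    return out


def fit_variant(
    measurements: MeasurementSet,
    variant: str,
    free: tuple[str, ...] | None = None,
    n_starts: int = 20,
    seed: int | None = None,
    **kw,
) -> FluxFitResults:
    """Build and fit a :class:`LabelingFluxModel` in one call."""
    return LabelingFluxModel(measurements, variant, free, **kw).fit(
        n_starts=n_starts, seed=seed
    )


@dataclass
class VariantComparison:
    """SSR ranking of unlabeled-entry hypothesis variants on one dataset."""

    table: pd.DataFrame
    fits: dict[str, FluxFitResults]
    common_observables: tuple[str, ...]

    def summary(self) -> str:
        return (
            "Variant comparison (common-channel weighted SSR)\n"
            + str(self.table)
        )


def compare_variants(
    measurements: MeasurementSet,
    variants=("V0", "V1", "V2", "V3", "V4", "V5"),
    seed: int | None = None,
    n_starts: int = 4,
    free_map: dict[str, tuple[str, ...]] | None = None,
) -> VariantComparison:
    """Fit each variant (its entry flux free) and rank by SSR.

    SSRs are compared on the channels measurable in every variant, so the
    ranking is not an artifact of variants observing different species.
    Per-variant failures are reported as failed rows.  The per-observable
    SSR breakdown of each fit is available from the stored results.
    """
    rng = np.random.default_rng(seed)
    base = canonical_network()
    common = set(measurements.mids)
    for v in variants:
        net = make_variant(base, v)
        common &= {
            name
            for name in measurements.mids
            if any(met in net.metabolites for met, _ in OBSERVABLE_POOLS[name])
        }
    common = tuple(sorted(common))
    common_meas = measurements.restricted(common)

    rows = []
    fits: dict[str, FluxFitResults] = {}
    for v in variants:
        free = (free_map or {}).get(v, ENTRY_KNOBS[v])
        try:
            fit = fit_variant(
                measurements,
                v,
                free=free,
                n_starts=n_starts,
                seed=int(rng.integers(2**31)),
            )
            # common-channel SSR at this variant's optimum
            m_common = LabelingFluxModel(common_meas, v, free)
            ssr_common = float(np.sum(m_common.residuals(fit.x) ** 2))
            fits[v] = fit
            rows.append(
                {
                    "variant": v,
                    "ssr_common": ssr_common,
                    "ssr_full": fit.ssr,
                    "entry_flux": fit.entry_flux(),
                    "n_free": len(fit.params),
                    "failed": False,
                }
            )
        except Exception as e:  # failures become rows, not crashes
            warnings.warn(f"variant {v} failed: {e}")
            rows.append(
                {
                    "variant": v,
                    "ssr_common": np.nan,
                    "ssr_full": np.nan,
                    "entry_flux": np.nan,
                    "n_free": len(free),
                    "failed": True,
                }
            )
    table = pd.DataFrame(rows).set_index("variant")
    base_ssr = table.loc[variants[0], "ssr_common"] if variants else np.nan
    table["delta_ssr"] = table["ssr_common"] - base_ssr
    table = table.sort_values("ssr_common")
    return VariantComparison(table, fits, common)
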