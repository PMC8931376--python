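"""Polyexponential decay models for %12C washout curves.

A first-order compartment network with M pools produces %12C curves that
are M-term polyexponentials, so the number of resolvable kinetic
components in a labeling time course can be read off by fitting the nested
family

    u(t) = sum_{i=1..K} A_i exp(-k_i t) (+ C)

and selecting K by extra-sum-of-squares F tests (Holm-corrected), AIC,
BIC, and leave-one-out cross-validation.  A constant term C represents a
metabolically inactive (never-labeling) pool.  Fitting is done in the
linear %12C domain; semilog curve stripping supplies one deterministic
multistart initialization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

__all__ = [
    "ExponentialDecayModel",
    "ExponentialDecayResults",
    "SelectionReport",
    "fit_exp_model",
    "curve_strip",
    "extra_ss_test",
    "holm_adjust",
    "information_criteria",
    "cross_validate",
    "select_model",
    "DEFAULT_ROSTER",
]

#: nested roster: models 1-7 of the selection ladder, as (n_terms, constant)
DEFAULT_ROSTER: tuple[tuple[int, bool], ...] = (
    (1, False),
    (1, True),
    (2, False),
    (2, True),
    (3, False),
    (3, True),
    (4, False),
)

_RATE_LO, _RATE_HI = 1e-3, 1e3  # 1/h, optimizer box
_START_RATE_LO, _START_RATE_HI = 1e-2, 1e2  # random-start range


def _unpack(params: np.ndarray, k_terms: int, constant: bool):
    A = params[:k_terms]
    k = params[k_terms : 2 * k_terms]
    C = params[-1] if constant else 0.0
    return A, k, C


def _predict(params: np.ndarray, t_h: np.ndarray, k_terms: int, constant: bool):
    A, k, C = _unpack(params, k_terms, constant)
    return np.exp(-np.outer(t_h, k)) @ A + C


class ExponentialDecayModel:
    """K-term exponential decay (optionally plus constant) for a %12C series.

    Parameters
    ----------
    times_min : array
        Sampling times in minutes (rates are reported in 1/h).
    percent_12c : array
        %12C remaining at each time, in [0, 100].
    n_terms : int
        Number of exponential components K, 1..4.
    constant : bool
        Include a constant term C >= 0 (inactive-pool analogue).
    """

    def __init__(self, times_min, percent_12c, n_terms: int = 3, constant: bool = False):
        self.t_min = np.asarray(times_min, dtype=float)
        self.u = np.asarray(percent_12c, dtype=float)
        if self.t_min.shape != self.u.shape or self.t_min.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if not 1 <= n_terms <= 4:
            raise ValueError("n_terms must be in 1..4")
        if np.any(self.u < -1e-9) or np.any(self.u > 100 + 1e-9):
            raise ValueError("%12C values must lie in [0, 100]")
        self.k_terms = n_terms
        self.constant = constant
        self.n_params = 2 * n_terms + int(constant)
        if self.t_min.size < self.n_params + 1:
            raise ValueError(
                f"need at least {self.n_params + 1} observations for this model"
            )
        self.t_h = self.t_min / 60.0

    # -- parameter plumbing -------------------------------------------------
    def _bounds(self):
        lo = np.concatenate(
            [np.zeros(self.k_terms), np.full(self.k_terms, _RATE_LO)]
        )
        hi = np.concatenate(
            [np.full(self.k_terms, 150.0), np.full(self.k_terms, _RATE_HI)]
        )
        if self.constant:
            lo = np.append(lo, 0.0)
            hi = np.append(hi, 100.0)
        return lo, hi

    def _random_start(self, rng: np.random.Generator):
        scale = max(self.u.max(), 1.0)
        amps = rng.dirichlet(np.ones(self.k_terms)) * scale
        rates = 10 ** rng.uniform(
            np.log10(_START_RATE_LO), np.log10(_START_RATE_HI), self.k_terms
        )
        x0 = np.concatenate([amps, rates])
        if self.constant:
            x0 = np.append(x0, rng.uniform(0, scale / 4))
        return x0

    def _strip_start(self):
        try:
            guesses = curve_strip(self.t_min, self.u, self.k_terms)
        except ValueError:
            return None
        A = np.clip([a for a, _ in guesses], 0.0, 150.0)
        k = np.clip([k for _, k in guesses], _RATE_LO, _RATE_HI)
        x0 = np.concatenate([A, k])
        if self.constant:
            x0 = np.append(x0, min(self.u[-1] / 2.0, 99.0))
        return x0

    def predict(self, params, times_min=None):
        t_h = self.t_h if times_min is None else np.asarray(times_min, float) / 60.0
        return _predict(np.asarray(params, float), t_h, self.k_terms, self.constant)

    def _jacobian(self, params):
        A, k, _ = _unpack(params, self.k_terms, self.constant)
        E = np.exp(-np.outer(self.t_h, k))
        J = np.empty((self.t_h.size, self.n_params))
        J[:, : self.k_terms] = E
        J[:, self.k_terms : 2 * self.k_terms] = -A * self.t_h[:, None] * E
        if self.constant:
            J[:, -1] = 1.0
        return J

    def _canonical(self, params: np.ndarray) -> np.ndarray:
        A, k, C = _unpack(params, self.k_terms, self.constant)
        order = np.lexsort((-A, -k))  # descending rate, ties by amplitude
        out = np.concatenate([A[order], k[order]])
        if self.constant:
            out = np.append(out, C)
        return out

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        n_starts: int = 100,
        seed: int | None = None,
        xtol: float = 1e-12,
        ftol: float = 1e-12,
    ) -> "ExponentialDecayResults":
        """Bound-constrained nonlinear least squares from ``n_starts``
        random initializations (plus a curve-stripping start); the
        smallest-SSR fit wins."""
        rng = np.random.default_rng(seed)
        lo, hi = self._bounds()

        def resid(x):
            return self.predict(x) - self.u

        starts = []
        strip = self._strip_start()
        if strip is not None:
            starts.append(np.clip(strip, lo, hi))
        # deterministic spread start: log-spaced rates incl. the slow bound,
        # so a K-term model can always reach the (K-1)+constant boundary fit
        scale = max(self.u.max(), 1.0)
        spread = np.concatenate(
            [
                np.full(self.k_terms, scale / self.k_terms),
                np.logspace(np.log10(_RATE_LO), np.log10(30.0), self.k_terms)[::-1],
            ]
        )
        if self.constant:
            spread = np.append(spread, 1.0)
        starts.append(np.clip(spread, lo, hi))
        while len(starts) < max(n_starts, 1):
            starts.append(np.clip(self._random_start(rng), lo, hi))

        best = None
        best_idx = -1
        n_ok = 0
        for i, x0 in enumerate(starts):
            try:
                sol = least_squares(
                    resid, x0, jac=lambda x: self._jacobian(x),
                    bounds=(lo, hi), method="trf", xtol=xtol, ftol=ftol,
                )
            except Exception:
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            n_ok += 1
            ssr = float(np.sum(sol.fun**2))
            if best is None or ssr < best[0]:
                best = (ssr, sol.x)
                best_idx = i
        if best is None:
            raise RuntimeError("all multistart fits failed")
        ssr, x = best
        return ExponentialDecayResults(
            model=self,
            params=self._canonical(x),
            ssr=ssr,
            n_starts=len(starts),
            n_converged=n_ok,
            best_start=best_idx,
            seed=seed,
        )


@dataclass
class ExponentialDecayResults:
    """Best multistart fit of an :class:`ExponentialDecayModel`."""

    model: ExponentialDecayModel
    params: np.ndarray
    ssr: float
    n_starts: int
    n_converged: int
    best_start: int
    seed: int | None

    @property
    def nobs(self) -> int:
        return self.model.t_min.size

    @property
    def n_params(self) -> int:
        return self.model.n_params

    @property
    def amplitudes(self) -> np.ndarray:
        return self.params[: self.model.k_terms]

    @property
    def rates(self) -> np.ndarray:
        return self.params[self.model.k_terms : 2 * self.model.k_terms]

    @property
    def const(self) -> float:
        return float(self.params[-1]) if self.model.constant else 0.0

    @property
    def residuals(self) -> np.ndarray:
        return self.model.predict(self.params) - self.model.u

    @property
    def aic(self) -> float:
        return information_criteria(self)[0]

    @property
    def bic(self) -> float:
        return information_criteria(self)[1]

    def predict(self, times_min=None) -> np.ndarray:
        return self.model.predict(self.params, times_min)

    def bootstrap_band(
        self,
        n_resamples: int = 1000,
        level: float = 0.95,
        seed: int | None = None,
        times_min=None,
    ) -> dict:
        """Residual-resampling bootstrap CIs for parameters and the fitted
        curve (the time grid is fixed by design, so residuals rather than
        cases are resampled)."""
        rng = np.random.default_rng(seed)
        t_out = self.model.t_min if times_min is None else np.asarray(times_min, float)
        fitted = self.predict()
        # inflate residuals by sqrt(n/(n-p)): fitted residuals understate
        # the error SD, which would shrink bootstrap intervals
        n, p = self.nobs, self.n_params
        res = self.residuals * np.sqrt(n / max(n - p, 1))
        params = []
        curves = []
        n_fail = 0
        m = self.model
        lo, hi = m._bounds()
        x_warm = np.clip(self.params, lo, hi)
        for _ in range(n_resamples):
            u_star = np.clip(fitted + rng.choice(res, size=res.size, replace=True), 0, 100)
            try:
                # residual-bootstrap refits start at the point estimate;
                # the perturbed optimum stays in its basin
                sol = least_squares(
                    lambda x: _predict(x, m.t_h, m.k_terms, m.constant) - u_star,
                    x_warm,
                    jac=lambda x: m._jacobian(x),
                    bounds=(lo, hi),
                    method="trf",
                )
                if not np.all(np.isfinite(sol.x)):
                    raise RuntimeError("non-finite bootstrap fit")
                xc = m._canonical(sol.x)
            except Exception:
                n_fail += 1
                continue
            params.append(xc)
            curves.append(_predict(xc, np.asarray(t_out, float) / 60.0, m.k_terms, m.constant))
        if n_fail > 0.1 * n_resamples:
            raise RuntimeError(f"{n_fail}/{n_resamples} bootstrap refits failed")
        params = np.array(params)
        curves = np.array(curves)
        a = (1 - level) / 2
        return {
            "level": level,
            "times_min": t_out,
            "param_lo": np.quantile(params, a, axis=0),
            "param_hi": np.quantile(params, 1 - a, axis=0),
            "curve_lo": np.quantile(curves, a, axis=0),
            "curve_hi": np.quantile(curves, 1 - a, axis=0),
            "n_resamples": n_resamples,
            "n_failed": n_fail,
        }

    def summary(self) -> str:
        lines = [
            f"Exponential decay fit: K={self.model.k_terms}"
            + (" + constant" if self.model.constant else ""),
            f"  nobs {self.nobs}, params {self.n_params}, SSR {self.ssr:.6g}",
            f"  multistart: {self.n_converged}/{self.n_starts} converged, "
            f"best start #{self.best_start}",
        ]
        for i, (A, k) in enumerate(zip(self.amplitudes, self.rates), 1):
            lines.append(
                f"  A{i} = {A:8.3f} %    k{i} = {k:10.4f} 1/h"
                f"  (t1/2 = {np.log(2) / k * 60:8.2f} min)"
            )
        if self.model.constant:
            lines.append(f"  C  = {self.const:8.3f} %")
        lines.append(f"  AIC {self.aic:.3f}   BIC {self.bic:.3f}")
        return "\n".join(lines)

    def plot(self, ax=None, band: dict | None = None):
        """Data, fit, and optional bootstrap band on a matplotlib axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tg = np.linspace(self.model.t_min.min(), self.model.t_min.max(), 300)
        ax.plot(self.model.t_min, self.model.u, "o", label="data")
        ax.plot(tg, self.predict(tg), "-", label="fit")
        if band is not None:
            ax.fill_between(
                band["times_min"], band["curve_lo"], band["curve_hi"], alpha=0.3
            )
        ax.set_xlabel("time (min)")
        ax.set_ylabel("%12C remaining")
        ax.legend()
        return ax


def fit_exp_model(
    times_min, percent_12c, k_terms: int, constant: bool = False,
    n_starts: int = 100, seed: int | None = None,
) -> ExponentialDecayResults:
    """Functional wrapper around :class:`ExponentialDecayModel`."""
    return ExponentialDecayModel(times_min, percent_12c, k_terms, constant).fit(
        n_starts=n_starts, seed=seed
    )


def curve_strip(times_min, u, phases: int) -> list[tuple[float, float]]:
    """Pharmacokinetic curve stripping: sequential semilog line fits from
    the slowest tail backwards, subtracting each fitted component.

    Returns ``[(A_i, k_i), ...]`` fastest first (canonical order).  Raises
    ``ValueError`` when a residual segment has too few positive points, in
    which case callers fall back to random initialization.
    """
    t_h = np.asarray(times_min, float) / 60.0
    r = np.asarray(u, float).copy()
    if not 1 <= phases <= 4:
        raise ValueError("phases must be 1..4")
    n = t_h.size
    comps: list[tuple[float, float]] = []
    remaining = np.ones(n, dtype=bool)
    for phase in range(phases):
        pos = remaining & (r > 1e-12)
        idx = np.nonzero(pos)[0]
        if idx.size < 2:
            if not comps:
                raise ValueError("curve stripping ran out of positive points")
            # remaining phases have nothing left to explain
            import warnings

            warnings.warn("curve stripping: residual exhausted; padding zeros")
            while len(comps) < phases:
                comps.append((0.0, comps[-1][1] * 10.0))
            break
        if phase < phases - 1:
            seg = idx[-max(2, idx.size // (phases - phase)):]
        else:
            seg = idx
        slope, intercept = np.polyfit(t_h[seg], np.log(r[seg]), 1)
        k = -slope
        A = np.exp(intercept)
        if k <= 0:
            k = _RATE_LO
        comps.append((A, k))
        r = r - A * np.exp(-k * t_h)
        remaining &= t_h < t_h[seg[0]]
    comps.sort(key=lambda c: -c[1])
    return comps


def extra_ss_test(reduced: ExponentialDecayResults, full: ExponentialDecayResults):
    """Extra-sum-of-squares F test between two nested fits on the same data.

    F = ((SSR_r - SSR_f)/(p_f - p_r)) / (SSR_f/(n - p_f)); a negative
    numerator (the larger model fitting worse, possible up to optimizer
    tolerance) clamps to F=0, p=1.
    """
    if reduced.nobs != full.nobs or not np.array_equal(
        reduced.model.t_min, full.model.t_min
    ):
        raise ValueError("fits are not on the same data")
    p_r, p_f, n = reduced.n_params, full.n_params, full.nobs
    if p_f <= p_r:
        raise ValueError("full model must have more parameters than reduced")
    if n <= p_f:
        raise ValueError("not enough observations for the F test")
    num = (reduced.ssr - full.ssr) / (p_f - p_r)
    den = full.ssr / (n - p_f)
    if num <= 0 or den <= 0:
        return 0.0, 1.0
    F = num / den
    p = float(f_dist.sf(F, p_f - p_r, n - p_f))
    return float(F), p


def holm_adjust(pvalues) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment, order preserving."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min((m - rank) * p[idx], 1.0)
        running = max(running, val)
        adj[idx] = running
    return adj


def information_criteria(fit: ExponentialDecayResults) -> tuple[float, float]:
    """Gaussian-likelihood AIC/BIC with q = parameter count + 1 (variance)."""
    n = fit.nobs
    q = fit.n_params + 1
    if n <= q:
        raise ValueError("too few observations for information criteria")
    if fit.ssr <= 0:
        warnings.warn("zero SSR: information criteria are -inf")
        return -np.inf, -np.inf
    ll_term = n * np.log(fit.ssr / n)
    return ll_term + 2 * q, ll_term + q * np.log(n)


def cross_validate(
    times_min, u, k_terms: int, constant: bool = False,
    seed: int | None = None, n_starts: int = 5,
    warm_params: np.ndarray | None = None,
) -> float:
    """Leave-one-out cross-validation score (mean held-out squared error).

    Folds are the unique sampling times, so for unreplicated series this
    is ordinary LOO while for replicated designs each fold holds out one
    time point's replicates together (replicates of the same sample are
    not independent of each other).  Each fold refits the model
    warm-started from the full-data fit plus a few random starts;
    deterministic for a given seed.  Folds whose fit fails are skipped
    with a warning.
    """
    t = np.asarray(times_min, float)
    u = np.asarray(u, float)
    rng = np.random.default_rng(seed)
    if warm_params is None:
        warm_params = (
            ExponentialDecayModel(t, u, k_terms, constant)
            .fit(n_starts=max(n_starts, 10), seed=int(rng.integers(2**31)))
            .params
        )
    errs = []
    skipped = 0
    for ti in np.unique(t):
        mask = t != ti
        try:
            m = ExponentialDecayModel(t[mask], u[mask], k_terms, constant)
            lo, hi = m._bounds()
            sol = least_squares(
                lambda x: m.predict(x) - u[mask],
                np.clip(warm_params, lo, hi),
                jac=lambda x: m._jacobian(x),
                bounds=(lo, hi),
                method="trf",
            )
            best = float(np.sum(sol.fun**2))
            best_x = sol.x
            r = m.fit(n_starts=n_starts, seed=int(rng.integers(2**31)))
            if r.ssr < best:
                best_x = r.params
            pred = m.predict(best_x, t[~mask])
            errs.extend(((pred - u[~mask]) ** 2).tolist())
        except Exception:
            skipped += 1
            warnings.warn(f"CV fold at t={ti} failed; skipped")
    if not errs:
        raise RuntimeError("all CV folds failed")
    return float(np.mean(errs))


@dataclass
class SelectionReport:
    """Model-selection verdict table over the nested roster."""

    roster: tuple[tuple[int, bool], ...]
    fits: dict[tuple[int, bool], ExponentialDecayResults]
    table: pd.DataFrame
    winners: dict[str, tuple[int, bool]]
    consensus: tuple[int, bool]
    consensus_rule: str = (
        "Holm-adjusted extra-SS p < 0.05 vs previous nested model and "
        ">=2 of {AIC, BIC, CV} prefer it; otherwise the extra-SS ladder winner"
    )

    def summary(self) -> str:
        lines = ["Nested polyexponential model selection", str(self.table)]
        for crit, w in self.winners.items():
            lines.append(f"  {crit:>8} prefers: {_model_name(w)}")
        lines.append(f"  consensus: {_model_name(self.consensus)}")
        return "\n".join(lines)


def _model_name(spec: tuple[int, bool]) -> str:
    k, c = spec
    return f"{k}exp" + ("+C" if c else "")


def select_model(
    times_min,
    u,
    roster: tuple[tuple[int, bool], ...] = DEFAULT_ROSTER,
    seed: int | None = None,
    n_starts: int = 100,
    alpha: float = 0.05,
) -> SelectionReport:
    """Fit the nested roster and produce the four-criterion verdict table.

    Models that cannot be fitted on the data (too few observations) are
    dropped with a warning; criteria computed where defined.
    """
    rng = np.random.default_rng(seed)
    fits: dict[tuple[int, bool], ExponentialDecayResults] = {}
    cv: dict[tuple[int, bool], float] = {}
    for spec in roster:
        k, c = spec
        try:
            fit = ExponentialDecayModel(times_min, u, k, c).fit(
                n_starts=n_starts, seed=int(rng.integers(2**31))
            )
        except (ValueError, RuntimeError) as e:
            warnings.warn(f"model {_model_name(spec)} skipped: {e}")
            continue
        fits[spec] = fit
        cv[spec] = cross_validate(
            times_min, u, k, c, seed=int(rng.integers(2**31)),
            warm_params=fit.params,
        )
    specs = [s for s in roster if s in fits]
    raw_p = []
    Fs = []
    for prev, cur in zip(specs, specs[1:]):
        F, p = extra_ss_test(fits[prev], fits[cur])
        Fs.append(F)
        raw_p.append(p)
    adj_p = holm_adjust(raw_p) if raw_p else np.array([])

    rows = []
    for i, s in enumerate(specs):
        fit = fits[s]
        rows.append(
            {
                "model": _model_name(s),
                "K": fit.n_params,
                "SSR": fit.ssr,
                "F_vs_prev": Fs[i - 1] if i else np.nan,
                "p_raw": raw_p[i - 1] if i else np.nan,
                "p_holm": adj_p[i - 1] if i else np.nan,
                "AIC": fit.aic,
                "BIC": fit.bic,
                "CV": cv[s],
            }
        )
    table = pd.DataFrame(rows).set_index("model")

    # extra-SS ladder: climb while the step up is (Holm-)significant
    ladder = 0
    for i in range(1, len(specs)):
        if adj_p[i - 1] < alpha:
            ladder = i
        else:
            break
    winners = {
        "extra_SS": specs[ladder],
        "AIC": min(specs, key=lambda s: fits[s].aic),
        "BIC": min(specs, key=lambda s: fits[s].bic),
        "CV": min(specs, key=lambda s: cv[s]),
    }
    consensus = specs[ladder]
    votes = {
        s: sum(1 for c in ("AIC", "BIC", "CV") if winners[c] == s) for s in specs
    }
    candidates = []
    for i, s in enumerate(specs):
        sig = i == 0 or adj_p[i - 1] < alpha
        if sig and votes[s] >= 2:
            candidates.append(s)
    if candidates:
        consensus = max(candidates, key=lambda s: (votes[s], specs.index(s)))
    return SelectionReport(tuple(specs), fits, table, winners, consensus)
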