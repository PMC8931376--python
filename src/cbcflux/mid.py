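"""Mass isotopologue distributions (MIDs) and labeling time courses.

A MID is the vector of fractions ``m0..mn`` of molecules of an n-carbon
metabolite carrying 0..n heavy (13C) carbons.  It is the universal
measurement currency of 13CO2 labeling experiments: every simulated or
measured quantity in this package reduces to MIDs per metabolite per time,
or to the %12C summaries derived from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MIDVector",
    "LabelTimeCourse",
    "binomial_mid",
    "twelve_c_fraction",
    "aggregate_12c",
]

#: tolerance on the unit-sum (simplex) constraint of a MID
SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class MIDVector:
    """Isotopologue fraction vector of one metabolite.

    Parameters
    ----------
    metabolite : str
        Metabolite identifier (may carry a compartment suffix).
    fractions : ndarray, shape (n+1,)
        Fractions m0..mn; non-negative and summing to one.
    """

    metabolite: str
    fractions: np.ndarray

    def __post_init__(self):
        frac = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", frac)
        if frac.ndim != 1 or frac.size < 2:
            raise ValueError("MID needs at least two channels (m0, m1)")
        if np.any(frac < -SIMPLEX_TOL):
            raise ValueError(
                f"negative isotopologue fraction in {self.metabolite}: {frac.min()}"
            )
        if abs(frac.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"MID of {self.metabolite} does not sum to 1 (sum={frac.sum():.8f})"
            )

    @property
    def n_carbons(self) -> int:
        return self.fractions.size - 1

    def mean_enrichment(self) -> float:
        """Average 13C fraction per carbon, sum_i i*m_i / n."""
        i = np.arange(self.fractions.size)
        return float((i * self.fractions).sum() / self.n_carbons)


def binomial_mid(n: int, p: float, metabolite: str = "binomial") -> MIDVector:
    """MID of an n-carbon metabolite whose carbons are labeled independently
    with probability ``p`` (single-population binomial labeling)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    i = np.arange(n + 1)
    from scipy.stats import binom

    return MIDVector(metabolite, binom.pmf(i, n, p))


def twelve_c_fraction(mid: MIDVector | np.ndarray) -> float:
    """Percentage of carbon atoms that are 12C, ``100 * sum_i m_i (n-i)/n``."""
    frac = mid.fractions if isinstance(mid, MIDVector) else np.asarray(mid, float)
    n = frac.size - 1
    i = np.arange(n + 1)
    return float(100.0 * (frac * (n - i)).sum() / n)


@dataclass
class LabelTimeCourse:
    """MID time course of one metabolite over a labeling experiment.

    ``times`` are in minutes with the pre-switch sample at t=0 first;
    ``mids[j]`` is the MID at ``times[j]``.  ``sds`` optionally carries the
    per-channel measurement SDs, same shape as the stacked fractions.
    """

    metabolite: str
    times: np.ndarray
    mids: list[MIDVector]
    sds: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.mids) != self.times.size:
            raise ValueError("times and mids length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        ns = {m.n_carbons for m in self.mids}
        if len(ns) != 1:
            raise ValueError("all MIDs in a time course must share carbon count")
        if self.sds is not None:
            self.sds = np.asarray(self.sds, dtype=float)
            if self.sds.shape != self.as_array().shape:
                raise ValueError("sds shape mismatch")

    @property
    def n_carbons(self) -> int:
        return self.mids[0].n_carbons

    def as_array(self) -> np.ndarray:
        """Fractions stacked as (n_times, n_carbons+1)."""
        return np.vstack([m.fractions for m in self.mids])

    def twelve_c_series(self) -> np.ndarray:
        return np.array([twelve_c_fraction(m) for m in self.mids])


def aggregate_12c(
    courses: dict[str, LabelTimeCourse],
    metabolites: list[str],
    pool_sizes: dict[str, float] | None = None,
    weighted: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate %12C series over a set of metabolites.

    By default the per-metabolite %12C values are combined as a
    pool-size-weighted mean (weights proportional to each metabolite's
    carbon content, pool size x carbon number); with ``weighted=False`` or
    absent pool sizes an unweighted mean is used.

    Returns ``(times, aggregate %12C per time)``.
    """
    if not metabolites:
        raise ValueError("empty metabolite list")
    missing = [m for m in metabolites if m not in courses]
    if missing:
        raise KeyError(f"metabolites missing from dataset: {missing}")
    ref = courses[metabolites[0]].times
    for m in metabolites[1:]:
        if not np.array_equal(courses[m].times, ref):
            raise ValueError(f"time grid of {m} differs from {metabolites[0]}")
    series = np.vstack([courses[m].twelve_c_series() for m in metabolites])
    if weighted and pool_sizes is not None:
        w = np.array(
            [pool_sizes[m] * courses[m].n_carbons for m in metabolites], dtype=float
        )
    else:
        w = np.ones(len(metabolites))
    w = w / w.sum()
    return ref.copy(), w @ series
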