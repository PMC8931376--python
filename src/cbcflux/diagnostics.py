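"""Isotopologue diagnostics: the M0-over-M1 anomaly.

Under single-population labeling every carbon of a metabolite is 13C with
the same probability p, making the MID binomial; then M1/M0 = n*p/(1-p),
which is large once p is high (e.g. 144 for n=6, p=0.96).  Observing
M0 >> M1 at late times therefore indicates a second, essentially
unlabeled population of intact molecules mixing into the pool — the
signature of intact-carbon reimport rather than slow labeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mid import MIDVector, LabelTimeCourse, binomial_mid, twelve_c_fraction

__all__ = [
    "binomial_mid",
    "m1_m0_stats",
    "m0_share_of_unlabeled",
    "diag_table",
    "DiagRow",
]

#: observed/predicted M1:M0 ratio below this factor flags an M0 excess
DEFAULT_EXCESS_FACTOR = 10.0


def estimate_enrichment(mid: MIDVector, exclude_m0: bool = True) -> float:
    """Per-carbon 13C probability p of the labeled subpopulation.

    With ``exclude_m0`` (default) M0 is treated as a separate unlabeled
    population and p is the mean enrichment of the M>=1 molecules,
    mirroring the two-population reading of the anomaly; otherwise the
    plain mean enrichment over all molecules is used.
    """
    frac = mid.fractions
    n = mid.n_carbons
    i = np.arange(n + 1)
    if exclude_m0:
        rest = frac[1:]
        tot = rest.sum()
        if tot <= 0:
            return 0.0
        return float((i[1:] * rest).sum() / (n * tot))
    return mid.mean_enrichment()


def m1_m0_stats(
    mid: MIDVector,
    p_hat: float | None = None,
    excess_factor: float = DEFAULT_EXCESS_FACTOR,
    exclude_m0: bool = True,
) -> dict:
    """Observed vs binomial-predicted M1/M0 ratio.

    Returns observed ratio m1/m0 (NaN sentinel when m0=0), the predicted
    ratio n*p/(1-p), and an excess flag set when the observed ratio falls
    below predicted/``excess_factor``.
    """
    m0, m1 = float(mid.fractions[0]), float(mid.fractions[1])
    if p_hat is None:
        p_hat = estimate_enrichment(mid, exclude_m0=exclude_m0)
    n = mid.n_carbons
    predicted = np.inf if p_hat >= 1.0 else n * p_hat / (1.0 - p_hat)
    observed = np.nan if m0 <= 0 else m1 / m0
    excess = bool(
        np.isfinite(observed) and predicted > 0 and observed < predicted / excess_factor
    )
    return {
        "observed": observed,
        "predicted": float(predicted),
        "p_hat": float(p_hat),
        "excess": excess,
    }


def m0_share_of_unlabeled(mid: MIDVector) -> float:
    """Fraction of a metabolite's 12C carbon residing in M0 molecules,
    ``m0 * n / sum_i m_i (n - i)``.

    Near 1 when an inactive (fully unlabeled) subpopulation explains all
    missing label; well below 1 when partially labeled molecules carry
    most of the 12C.
    """
    frac = mid.fractions
    n = mid.n_carbons
    i = np.arange(n + 1)
    denom = float((frac * (n - i)).sum())
    if denom <= 0:
        raise ValueError("metabolite carries no 12C")
    return float(frac[0] * n / denom)


@dataclass
class DiagRow:
    metabolite: str
    time_min: float
    m0: float
    m1: float
    m2: float
    ratio_observed: float
    ratio_predicted: float
    m0_share: float
    pool_size: float | None
    excess: bool


def diag_table(
    courses: dict[str, LabelTimeCourse],
    time_min: float,
    pool_sizes: dict[str, float] | None = None,
    strict_time: bool = True,
    excess_factor: float = DEFAULT_EXCESS_FACTOR,
    exclude_m0: bool = True,
) -> pd.DataFrame:
    """One diagnostic row per metabolite at (or nearest to) ``time_min``,
    sorted by M0 excess (predicted/observed ratio), CSV-writable."""
    import warnings

    rows = []
    for name, tc in courses.items():
        times = tc.times
        if time_min in times:
            j = int(np.where(times == time_min)[0][0])
        elif strict_time:
            raise KeyError(f"time {time_min} not sampled for {name}")
        else:
            j = int(np.argmin(np.abs(times - time_min)))
            warnings.warn(
                f"{name}: using nearest time {times[j]} for requested {time_min}"
            )
        mid = tc.mids[j]
        stats = m1_m0_stats(mid, excess_factor=excess_factor, exclude_m0=exclude_m0)
        try:
            share = m0_share_of_unlabeled(mid)
        except ValueError:
            share = np.nan
        rows.append(
            DiagRow(
                metabolite=name,
                time_min=float(tc.times[j]),
                m0=float(mid.fractions[0]),
                m1=float(mid.fractions[1]),
                m2=float(mid.fractions[2]) if mid.n_carbons >= 2 else np.nan,
                ratio_observed=stats["observed"],
                ratio_predicted=stats["predicted"],
                m0_share=share,
                pool_size=(pool_sizes or {}).get(name),
                excess=stats["excess"],
            ).__dict__
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["excess_factor"] = df["ratio_predicted"] / df["ratio_observed"]
    return df.sort_values("excess_factor", ascending=False).reset_index(drop=True)
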