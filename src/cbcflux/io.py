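"""File formats and run configuration.

MID tables travel as wide-format CSV with columns
``metabolite, n_carbons, time_min, M0..Mk, sd_M0..sd_Mk`` (channels beyond
a metabolite's carbon count left empty); numbers round-trip bit-exactly
through ``repr``-precision floats.  Structured results are JSON; run
configuration is YAML with strict key checking.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mid import MIDVector, LabelTimeCourse

__all__ = [
    "write_mid_csv",
    "read_mid_csv",
    "RunConfig",
    "read_config",
    "write_json",
]

#: a MID row whose sum deviates by more than this is rejected outright;
#: smaller deviations are renormalized with a warning
SIMPLEX_REJECT = 1e-3


def write_mid_csv(courses: dict[str, LabelTimeCourse], path) -> None:
    nmax = max(tc.n_carbons for tc in courses.values())
    cols = (
        ["metabolite", "n_carbons", "time_min"]
        + [f"M{i}" for i in range(nmax + 1)]
        + [f"sd_M{i}" for i in range(nmax + 1)]
    )
    rows = []
    for name in sorted(courses):
        tc = courses[name]
        arr = tc.as_array()
        for j, t in enumerate(tc.times):
            row = {"metabolite": name, "n_carbons": tc.n_carbons, "time_min": repr(float(t))}
            for i in range(tc.n_carbons + 1):
                row[f"M{i}"] = repr(float(arr[j, i]))
                if tc.sds is not None:
                    row[f"sd_M{i}"] = repr(float(tc.sds[j, i]))
            rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_mid_csv(path) -> dict[str, LabelTimeCourse]:
    """Read and validate a MID table CSV.

    MIDs off the unit simplex by more than 1e-3 are rejected; smaller
    deviations are renormalized with a warning.  Duplicated
    (metabolite, time) rows and negative fractions are errors.
    """
    import warnings

    df = pd.read_csv(path)
    required = {"metabolite", "n_carbons", "time_min"}
    if not required.issubset(df.columns):
        raise ValueError(f"malformed header: missing {required - set(df.columns)}")
    out: dict[str, LabelTimeCourse] = {}
    for name, sub in df.groupby("metabolite", sort=False):
        n = int(sub["n_carbons"].iloc[0])
        if sub["time_min"].duplicated().any():
            raise ValueError(f"duplicated (metabolite, time) rows for {name}")
        sub = sub.sort_values("time_min")
        mcols = [f"M{i}" for i in range(n + 1)]
        vals = sub[mcols].to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValueError(f"negative fractions for {name}")
        sums = vals.sum(axis=1)
        bad = np.abs(sums - 1.0) > SIMPLEX_REJECT
        if np.any(bad):
            raise ValueError(
                f"{name}: MID rows off the simplex by >{SIMPLEX_REJECT} "
                f"(worst sum {sums[bad][0]:.4f})"
            )
        off = np.abs(sums - 1.0) > 1e-9
        if np.any(off):
            warnings.warn(f"{name}: renormalized {off.sum()} MID rows")
            vals = vals / sums[:, None]
        sdcols = [f"sd_M{i}" for i in range(n + 1)]
        sds = None
        if all(c in sub.columns for c in sdcols):
            sarr = sub[sdcols].to_numpy(dtype=float)
            if not np.all(np.isnan(sarr)):
                sds = sarr
        out[name] = LabelTimeCourse(
            name,
            sub["time_min"].to_numpy(dtype=float),
            [MIDVector(name, r) for r in vals],
            sds=sds,
        )
    if not out:
        raise ValueError("empty MID table")
    return out


@dataclass
class RunConfig:
    """Pipeline run configuration with spec'd defaults."""

    network: str | None = None
    data: str | None = None
    out_dir: str = "."
    seed: int | None = None
    variant: str = "V5"
    scenario: str = "final_v5"
    noise_sd: float = 0.01
    polyexp_starts: int = 100
    flux_starts: int = 20
    bootstrap_resamples: int = 1000
    mc_draws: int = 50
    sim_rtol: float = 1e-8
    sim_atol: float = 1e-10
    log_level: str = "INFO"

    def __post_init__(self):
        for name in ("polyexp_starts", "flux_starts", "bootstrap_resamples", "mc_draws"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.seed is None:
            # a run must be reproducible: draw one and record it everywhere
            self.seed = int(np.random.SeedSequence().entropy % (2**31))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"seed": self.seed, "config_hash": self.config_hash()}


def read_config(path) -> RunConfig:
    """Load a YAML config; unknown keys are rejected by name."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def write_json(obj: dict, path, config: RunConfig | None = None) -> None:
    """Write a JSON artifact, embedding seed + config hash when given."""

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    payload = dict(obj)
    if config is not None:
        payload["_provenance"] = config.provenance()
    Path(path).write_text(json.dumps(payload, indent=2, default=default))
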