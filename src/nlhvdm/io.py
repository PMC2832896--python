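"""Readers/writers for the TSV/JSON formats shared across the CLI commands."""

from __future__ import annotations

import json
import warnings

import numpy as np

from .errors import ParseError
from .model import GeneKinetics, TFActivityProfile

__all__ = [
    "write_activity",
    "read_activity",
    "write_kinetics_json",
    "read_kinetics_json",
]


def write_activity(path, profile: TFActivityProfile, ci_low=None, ci_high=None,
                   meta: dict | None = None) -> None:
    """Two-or-four-column activity TSV: time, mean[, ci_low, ci_high]."""
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={val}\n")
        cols = ["time", "activity"]
        if ci_low is not None and ci_high is not None:
            cols += ["ci_low", "ci_high"]
        fh.write("\t".join(cols) + "\n")
        for i, t in enumerate(profile.knot_times):
            row = [f"{t:g}", f"{profile.knot_values[i]:.8g}"]
            if ci_low is not None and ci_high is not None:
                row += [f"{ci_low[i]:.8g}", f"{ci_high[i]:.8g}"]
            fh.write("\t".join(row) + "\n")


def read_activity(path):
    """Read an activity TSV; returns (profile, ci_low, ci_high) (CIs may be None)."""
    times, vals, lo, hi = [], [], [], []
    header = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if len(header) not in (2, 4):
                    raise ParseError(f"line {lineno}: expected 2 or 4 columns")
                continue
            if len(fields) != len(header):
                raise ParseError(f"line {lineno}: ragged row")
            try:
                nums = [float(x) for x in fields]
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric cell") from None
            times.append(nums[0])
            vals.append(nums[1])
            if len(nums) == 4:
                lo.append(nums[2])
                hi.append(nums[3])
    t = np.asarray(times)
    v = np.asarray(vals)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ParseError("activity times must be strictly increasing (>= 2 rows)")
    if np.any(v < 0) or np.any(v > 1):
        warnings.warn("activity values outside [0, 1]; clipping")
        v = np.clip(v, 0.0, 1.0)
    profile = TFActivityProfile(t, v, baseline_value=float(v[0]) if t[0] <= 0 else 0.0)
    return profile, (np.asarray(lo) if lo else None), (np.asarray(hi) if hi else None)


def _kin_dict(k: GeneKinetics) -> dict:
    return dict(c=k.c, k=k.k, K=k.K, d=k.d, tau=k.tau, delta=k.delta, n=k.n, m=k.m)


def write_kinetics_json(path, kinetics: dict, extra: dict | None = None) -> None:
    """Serialise {probe_id: GeneKinetics} plus any extra metadata."""
    doc = dict(extra or {})
    doc["kinetics"] = {pid: _kin_dict(k) for pid, k in kinetics.items()}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_kinetics_json(path):
    with open(path) as fh:
        doc = json.load(fh)
    kin = {pid: GeneKinetics(**spec) for pid, spec in doc.pop("kinetics").items()}
    return kin, doc
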