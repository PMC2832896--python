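"""Expression time-course container and its TSV representation.

The on-disk format is a probes x arrays matrix with a ``probe_id`` column and
array labels ``t<H>_r<R>`` (time in hours, replicate index), e.g. ``t2_r1``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, MissingProbeError, ParseError

__all__ = ["ExpressionDataset"]

_LABEL_RE = re.compile(r"^t(?P<time>\d+(?:\.\d+)?)_r(?P<rep>\d+)$")


@dataclass
class ExpressionDataset:
    """Probes x time points x replicates expression values.

    ``values`` has shape ``(n_probes, n_times, n_replicates)``; ``times`` are
    hours, strictly increasing.
    """

    probe_ids: list
    times: np.ndarray
    values: np.ndarray
    gene_symbols: list | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise InvalidInputError("values must be a (probe, time, replicate) array")
        if len(self.probe_ids) != self.values.shape[0]:
            raise InvalidInputError("probe_ids length does not match values")
        if self.times.size != self.values.shape[1]:
            raise InvalidInputError("times length does not match values")
        if not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("times must be strictly increasing")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise InvalidInputError("duplicate probe ids")
        if np.any(~np.isfinite(self.values)):
            raise InvalidInputError("values contain non-finite entries")
        if self.gene_symbols is not None and len(self.gene_symbols) != len(self.probe_ids):
            raise InvalidInputError("gene_symbols length does not match probe_ids")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    def index_of(self, probe_id: str) -> int:
        try:
            return self.probe_ids.index(probe_id)
        except ValueError:
            raise MissingProbeError(probe_id) from None

    def get(self, probe_id: str) -> np.ndarray:
        """(time, replicate) values for one probe."""
        return self.values[self.index_of(probe_id)]

    def replicate_mean(self) -> np.ndarray:
        """(probe, time) matrix averaged over replicates."""
        return self.values.mean(axis=2)

    def subset(self, probe_ids: Sequence[str]) -> "ExpressionDataset":
        idx = [self.index_of(p) for p in probe_ids]
        genes = [self.gene_symbols[i] for i in idx] if self.gene_symbols else None
        return ExpressionDataset(list(probe_ids), self.times.copy(), self.values[idx].copy(), genes)

    def single_replicate(self, r: int) -> "ExpressionDataset":
        if not 0 <= r < self.n_replicates:
            raise InvalidInputError(f"replicate index {r} out of range")
        return ExpressionDataset(
            list(self.probe_ids), self.times.copy(), self.values[:, :, r : r + 1].copy(),
            list(self.gene_symbols) if self.gene_symbols else None,
        )

    # -- TSV round trip -----------------------------------------------------

    def column_labels(self) -> list:
        def fmt(t: float) -> str:
            return f"{t:g}"

        return [f"t{fmt(t)}_r{r + 1}" for t in self.times for r in range(self.n_replicates)]

    def to_frame(self) -> pd.DataFrame:
        flat = self.values.reshape(self.n_probes, self.n_times * self.n_replicates)
        return pd.DataFrame(flat, index=pd.Index(self.probe_ids, name="probe_id"),
                            columns=self.column_labels())

    def write_tsv(self, path, meta: dict | None = None) -> None:
        with open(path, "w") as fh:
            for key, val in (meta or {}).items():
                fh.write(f"# {key}={val}\n")
            self.to_frame().to_csv(fh, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "ExpressionDataset":
        header = None
        rows: list[tuple[int, str, list]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if header is None:
                    if fields[0] != "probe_id":
                        raise ParseError(f"line {lineno}: header must start with 'probe_id'")
                    header = fields[1:]
                    continue
                if len(fields) != len(header) + 1:
                    raise ParseError(f"line {lineno}: expected {len(header) + 1} fields, got {len(fields)}")
                rows.append((lineno, fields[0], fields[1:]))
        if header is None:
            raise ParseError("empty expression file")

        parsed = []
        for label in header:
            m = _LABEL_RE.match(label)
            if not m:
                raise ParseError(f"bad array label '{label}' (expected t<hours>_r<replicate>)")
            parsed.append((float(m.group("time")), int(m.group("rep"))))
        times = sorted({t for t, _ in parsed})
        reps = sorted({r for _, r in parsed})
        if len(parsed) != len(times) * len(reps) or len(set(parsed)) != len(parsed):
            raise ParseError("array labels do not form a complete time x replicate grid")
        col_pos = {tr: i for i, tr in enumerate(parsed)}

        probe_ids, seen = [], {}
        values = np.empty((len(rows), len(times), len(reps)))
        for i, (lineno, pid, cells) in enumerate(rows):
            if pid in seen:
                raise ParseError(f"line {lineno}: duplicate probe id '{pid}' (first at line {seen[pid]})")
            seen[pid] = lineno
            probe_ids.append(pid)
            try:
                nums = [float(c) for c in cells]
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-numeric cell ({exc})") from None
            for (t, r), v in zip(parsed, nums):
                values[i, times.index(t), reps.index(r)] = v
        return cls(probe_ids, np.asarray(times), values)
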