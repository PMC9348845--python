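"""Dataset ingestion and unit-interval preprocessing.

Input files are three-column CSVs read positionally: drug concentration,
response effect, group name (one header row).  The beta law cannot handle
responses at or outside the {0, 1} boundaries, so out-of-range values are
truncated into the open interval by one of two schemes:

``sequential`` (default)
    Interior values are untouched.  Offending values are mapped just inside
    the boundary in rank order: the j-th most extreme value at or above 1
    becomes ``1 - j*delta``, the j-th most extreme at or below 0 becomes
    ``j*delta``, with ``delta = min(gap/2, 1/(2n), 1e-3)`` where ``gap`` is
    the distance from the most extreme interior value to that boundary.
    This preserves ordering and never collides with interior values.  It is
    this package's stand-in for a boundary-perturbing sequential truncation
    scheme; only offending values are perturbed.

``conventional``
    The standard compression ``y <- (y*(n-1) + 0.5)/n`` applied to *all*
    values with ``n`` the per-group sample size — simple but coarse for
    small n, which is exactly what motivates the sequential default.

Zero/negative doses cannot enter the log-dose model and are dropped with a
warning.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DoseResponseDataset",
    "read_dataset",
    "truncate_unit_interval",
    "handle_zero_dose",
]

_DELTA_CAP = 1e-3


class DatasetFormatError(ValueError):
    pass


@dataclass
class DoseResponseDataset:
    """Tidy validated dose-response records.

    ``data`` has columns ``dose`` (positive), ``response`` (strictly inside
    (0,1) after preprocessing), ``group`` (non-empty string) and ``flag``
    (``raw``/``truncated``/``rescaled``).  ``log`` collects human-readable
    preprocessing messages.
    """

    data: pd.DataFrame
    log: list = field(default_factory=list)

    def __post_init__(self):
        required = {"dose", "response", "group"}
        if not required.issubset(self.data.columns):
            raise DatasetFormatError(f"missing columns {required - set(self.data.columns)}")
        if "flag" not in self.data.columns:
            self.data = self.data.assign(flag="raw")
        if (self.data["group"].astype(str).str.len() == 0).any():
            raise DatasetFormatError("empty group labels")

    @property
    def groups(self):
        return list(pd.unique(self.data["group"]))

    def group_counts(self):
        return self.data.groupby("group", sort=False).size().to_dict()

    def subset(self, group):
        return DoseResponseDataset(self.data[self.data["group"] == group]
                                   .reset_index(drop=True), list(self.log))

    def arrays(self, group=None):
        df = self.data if group is None else self.data[self.data["group"] == group]
        return df["dose"].to_numpy(float), df["response"].to_numpy(float)

    def to_csv(self, path_or_buf):
        self.data[["dose", "response", "group"]].to_csv(path_or_buf, index=False)

    @property
    def n_obs(self):
        return len(self.data)


def truncate_unit_interval(responses, method="sequential", n=None):
    """Map responses into the open unit interval.

    Returns ``(values, flags)`` where ``flags`` marks changed entries.  ``n``
    defaults to the vector length (callers pass the group size).
    """
    y = np.asarray(responses, dtype=float).copy()
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    n = y.size if n is None else int(n)
    flags = np.zeros(y.size, dtype=bool)
    if n < 1:
        raise ValueError("need n >= 1")

    if method == "conventional":
        out = (y * (n - 1) + 0.5) / n
        return out, np.ones(y.size, dtype=bool)
    if method != "sequential":
        raise ValueError("method must be 'sequential' or 'conventional'")

    lo = y <= 0.0
    hi = y >= 1.0
    interior = ~(lo | hi)
    if lo.any():
        k = int(lo.sum())
        gap = float(np.min(y[interior])) if interior.any() else 1.0
        # gap/(k+1) guarantees even the least extreme offender stays below
        # every interior value
        delta = min(gap / (k + 1.0), 1.0 / (2.0 * n), _DELTA_CAP)
        order = np.argsort(y[lo])  # most extreme (smallest) first
        ranks = np.empty(order.size, dtype=int)
        ranks[order] = np.arange(1, order.size + 1)
        y[lo] = ranks * delta
        flags |= lo
    if hi.any():
        k = int(hi.sum())
        gap = float(1.0 - np.max(y[interior])) if interior.any() else 1.0
        delta = min(gap / (k + 1.0), 1.0 / (2.0 * n), _DELTA_CAP)
        order = np.argsort(-y[hi])  # most extreme (largest) first
        ranks = np.empty(order.size, dtype=int)
        ranks[order] = np.arange(1, order.size + 1)
        y[hi] = 1.0 - ranks * delta
        flags |= hi
    return y, flags


def _truncate_groupwise(df, method, log):
    y = df["response"].to_numpy(float)
    flags = np.zeros(len(df), dtype=bool)
    for g in pd.unique(df["group"]):
        idx = np.flatnonzero((df["group"] == g).to_numpy())
        yg, fg = truncate_unit_interval(y[idx], method=method, n=idx.size)
        y[idx] = yg
        flags[idx] = fg
        n_changed = int(np.count_nonzero(fg & (yg != df["response"].to_numpy(float)[idx])))
        if method == "sequential" and fg.any():
            log.append(f"group {g!r}: {int(fg.sum())} boundary/out-of-range "
                       f"response(s) truncated into (0,1)")
        elif method == "conventional" and n_changed:
            log.append(f"group {g!r}: conventional transform applied (n={idx.size})")
    df = df.copy()
    df["response"] = y
    prev = df["flag"].to_numpy(object)
    prev[flags] = "truncated"
    df["flag"] = prev
    return df


def handle_zero_dose(dataset: DoseResponseDataset) -> DoseResponseDataset:
    """Drop records with dose <= 0 (log dose undefined there).

    Errors if any group is left with fewer than 2 distinct doses.
    """
    df = dataset.data
    bad = df["dose"] <= 0
    log = list(dataset.log)
    if bad.any():
        rows = [f"(dose={r.dose}, group={r.group!r})" for r in df[bad].itertuples()]
        msg = f"dropped {int(bad.sum())} nonpositive-dose record(s): " + ", ".join(rows)
        warnings.warn(msg)
        log.append(msg)
        df = df[~bad].reset_index(drop=True)
    for g, sub in df.groupby("group", sort=False):
        if sub["dose"].nunique() < 2:
            raise DatasetFormatError(
                f"group {g!r} has fewer than 2 distinct positive doses")
    return DoseResponseDataset(df, log)


def read_dataset(path_or_buf, truncation="sequential") -> DoseResponseDataset:
    """Read and validate a positional three-column dose-response CSV.

    Columns are interpreted by position as (dose, response, group) regardless
    of header names.  Responses that look like percentages (majority of
    values above 1.5) are rescaled by 1/100 with a warning.  Out-of-range
    responses are truncated; nonpositive doses dropped.
    """
    try:
        raw = pd.read_csv(path_or_buf)
    except pd.errors.EmptyDataError as exc:
        raise DatasetFormatError("empty input file") from exc
    if raw.shape[1] < 3:
        raise DatasetFormatError(
            f"expected >= 3 columns (dose, response, group); got {raw.shape[1]}")
    if raw.empty:
        raise DatasetFormatError("no data rows")
    df = raw.iloc[:, :3].copy()
    df.columns = ["dose", "response", "group"]

    log: list[str] = []
    for col in ("dose", "response"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any() or parsed.isna().any():
            rows = (np.flatnonzero(parsed.isna().to_numpy()) + 2).tolist()  # header = row 1
            raise DatasetFormatError(
                f"non-numeric or missing {col} value(s) at file row(s) {rows}")
        df[col] = parsed.astype(float)
    df["group"] = df["group"].astype(str)
    df["flag"] = "raw"

    resp = df["response"]
    if (resp > 1.5).mean() > 0.5:
        warnings.warn("responses look like percentages; rescaling by 1/100")
        log.append("responses rescaled by 1/100 (percentage input detected)")
        df["response"] = resp / 100.0
        df["flag"] = "rescaled"

    dataset = DoseResponseDataset(df, log)
    dataset = handle_zero_dose(dataset)
    dataset.data = _truncate_groupwise(dataset.data, truncation, dataset.log)
    return dataset


def read_dataset_from_text(text: str, truncation="sequential") -> DoseResponseDataset:
    """Convenience wrapper reading from an in-memory CSV string."""
    return read_dataset(io.StringIO(text), truncation=truncation)
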