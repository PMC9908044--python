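"""Participant-level data model and I/O for cluster-randomized trials.

A cluster-randomized trial (CRT) randomizes intact groups (hospitals,
schools, villages) to treatment arms, so the arm indicator is constant
within each cluster.  This module holds the validated participant-level
container (:class:`CRTDataset`), its per-cluster summary
(:class:`ClusterSummaryTable`), and CSV round-tripping for datasets and
estimation results.

Cluster identifiers are opaque labels: they are never assumed numeric,
contiguous, or ordered.  Missing or non-finite outcomes are rejected
outright rather than dropped, because silently discarding observations
changes the estimand the analysis targets.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CRTFormatError",
    "CRTValidationError",
    "CRTDataset",
    "ClusterSummaryTable",
    "read_crt_table",
    "summarize_clusters",
    "write_estimates",
    "read_estimates",
    "ESTIMATE_COLUMNS",
]


class CRTFormatError(ValueError):
    """Raised when an input file does not have the expected layout."""


class CRTValidationError(ValueError):
    """Raised when data violate the cluster-randomized design invariants."""


@dataclasses.dataclass(frozen=True)
class CRTDataset:
    """Validated participant-level CRT data.

    Parameters
    ----------
    cluster : ndarray of str
        Cluster label per participant (opaque; order of first appearance
        defines the cluster ordering used everywhere downstream).
    arm : ndarray of int
        Binary arm indicator per participant, 0 = control, 1 = treated;
        constant within cluster by design.
    outcome : ndarray of float
        Participant outcome; finite, no missing values.
    """

    cluster: np.ndarray
    arm: np.ndarray
    outcome: np.ndarray

    def __post_init__(self) -> None:
        cluster = np.asarray(self.cluster, dtype=object)
        arm = np.asarray(self.arm)
        outcome = np.asarray(self.outcome, dtype=float)
        if not (len(cluster) == len(arm) == len(outcome)):
            raise CRTValidationError("cluster, arm and outcome must have equal length")
        if len(cluster) == 0:
            raise CRTValidationError("dataset is empty")
        if not np.all(np.isfinite(outcome)):
            bad = int(np.flatnonzero(~np.isfinite(outcome))[0])
            raise CRTValidationError(f"non-finite outcome at row {bad}")
        arm_vals = set(np.unique(arm).tolist())
        if not arm_vals <= {0, 1}:
            raise CRTValidationError(f"arm must be coded 0/1, got levels {sorted(arm_vals)}")
        arm = arm.astype(np.int64)

        # cluster ordering = order of first appearance
        labels, first_idx, inv = np.unique(cluster, return_index=True, return_inverse=True)
        order = np.argsort(first_idx, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(len(order))
        codes = rank[inv]
        labels = labels[order]

        for g, lab in enumerate(labels):
            arms_g = np.unique(arm[codes == g])
            if len(arms_g) > 1:
                raise CRTValidationError(
                    f"arm varies within cluster {lab!r}: randomization is by cluster"
                )
        cluster_arm = np.array([arm[codes == g][0] for g in range(len(labels))])
        if len(labels) < 2 or not (0 in cluster_arm and 1 in cluster_arm):
            raise CRTValidationError("need at least two clusters with >=1 cluster per arm")

        object.__setattr__(self, "cluster", cluster)
        object.__setattr__(self, "arm", arm)
        object.__setattr__(self, "outcome", outcome)
        object.__setattr__(self, "_labels", labels)
        object.__setattr__(self, "_codes", codes)
        object.__setattr__(self, "_cluster_arm", cluster_arm)

    # -- derived quantities -------------------------------------------------

    @property
    def n_participants(self) -> int:
        return len(self.outcome)

    @property
    def n_clusters(self) -> int:
        return len(self._labels)

    @property
    def cluster_labels(self) -> np.ndarray:
        """Cluster labels in order of first appearance."""
        return self._labels

    @property
    def cluster_codes(self) -> np.ndarray:
        """Integer cluster index (0..G-1) per participant."""
        return self._codes

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self._codes, minlength=self.n_clusters)

    @property
    def cluster_arms(self) -> np.ndarray:
        """Arm indicator per cluster, aligned with :attr:`cluster_labels`."""
        return self._cluster_arm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster_id": self.cluster, "arm": self.arm, "outcome": self.outcome}
        )

    def write_csv(self, path: str | Path) -> None:
        # %.17g guarantees binary64 round-trip through text
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


@dataclasses.dataclass(frozen=True)
class ClusterSummaryTable:
    """One row per cluster: label, size ``n_i``, arm, and mean outcome ``ybar_i``.

    Satisfies the conservation identity
    ``sum(n_i * ybar_i) == sum of all participant outcomes``.
    """

    cluster_id: np.ndarray
    n: np.ndarray
    arm: np.ndarray
    ybar: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster_id": self.cluster_id, "n": self.n, "arm": self.arm, "ybar": self.ybar}
        )


def read_crt_table(
    path: str | Path,
    columns: Sequence[str] = ("cluster_id", "arm", "outcome"),
    arm_mapping: Mapping[object, int] | None = None,
) -> CRTDataset:
    """Read participant-level CRT data from a delimited text file.

    ``columns`` names the (cluster, arm, outcome) columns in that order.
    The arm column may use any two level codes; without an explicit
    ``arm_mapping`` the lexicographically smaller level becomes control (0).
    """
    path = Path(path)
    if not path.exists():
        raise CRTFormatError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if len(columns) != 3:
        raise CRTFormatError("columns must name (cluster, arm, outcome)")
    for col in columns:
        if col not in df.columns:
            raise CRTFormatError(f"missing column {col!r} (found {list(df.columns)})")
    cl_col, arm_col, y_col = columns

    outcome_raw = pd.to_numeric(df[y_col], errors="coerce")
    bad = outcome_raw.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CRTValidationError(f"missing or non-numeric outcome at row {row}")

    arm_raw = df[arm_col]
    levels = pd.unique(arm_raw)
    if len(levels) > 2:
        raise CRTFormatError(f"arm column {arm_col!r} has {len(levels)} levels, expected 2")
    if arm_mapping is not None:
        try:
            arm = arm_raw.map(dict(arm_mapping)).to_numpy()
        except KeyError as exc:  # pragma: no cover - pandas maps to NaN instead
            raise CRTFormatError(f"arm level not in mapping: {exc}") from exc
        if pd.isna(arm).any():
            raise CRTFormatError("arm_mapping does not cover all observed arm levels")
    else:
        lv = sorted(levels, key=str)
        if set(lv) <= {0, 1}:
            arm = arm_raw.to_numpy()
        else:
            arm = arm_raw.map({lv[0]: 0, lv[-1]: 1}).to_numpy()
    return CRTDataset(
        cluster=df[cl_col].astype(str).to_numpy(dtype=object),
        arm=np.asarray(arm, dtype=np.int64),
        outcome=outcome_raw.to_numpy(dtype=float),
    )


def summarize_clusters(data: CRTDataset) -> ClusterSummaryTable:
    """Collapse participant-level data to per-cluster size, arm and mean outcome."""
    g = data.n_clusters
    sizes = data.cluster_sizes
    sums = np.bincount(data.cluster_codes, weights=data.outcome, minlength=g)
    return ClusterSummaryTable(
        cluster_id=data.cluster_labels.copy(),
        n=sizes,
        arm=data.cluster_arms.copy(),
        ybar=sums / sizes,
    )


ESTIMATE_COLUMNS = (
    "estimator",
    "estimand",
    "estimate",
    "se",
    "ci_low",
    "ci_high",
    "df",
    "correction",
)


def write_estimates(results: Sequence, path: str | Path, fmt: str = "csv") -> None:
    """Write a sequence of estimation results to CSV (or JSON).

    Columns: estimator, estimand, estimate, se, ci_low, ci_high, df,
    correction.  ``df`` is empty for normal-approximation intervals.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "estimator": r.estimator,
                "estimand": r.estimand_target,
                "estimate": r.estimate,
                "se": r.se,
                "ci_low": r.ci[0],
                "ci_high": r.ci[1],
                "df": r.df,
                "correction": r.correction,
            }
        )
    df = pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
    path = Path(path)
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=2) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'csv' or 'json')")


def read_estimates(path: str | Path) -> pd.DataFrame:
    """Read back a file written by :func:`write_estimates` (CSV or JSON)."""
    path = Path(path)
    if path.suffix == ".json":
        return pd.DataFrame(json.loads(path.read_text()), columns=ESTIMATE_COLUMNS)
    return pd.read_csv(path)
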