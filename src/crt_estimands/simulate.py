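"""Synthetic cluster-randomized trials with controllable informative cluster size.

Informative cluster size means participant outcomes (type 1) or treatment
effects (type 2) depend on how many participants a cluster enrols.  The
generator takes a set of size strata, each with its own baseline and true
effect, so either type (or neither) can be switched on explicitly.

Gaussian outcomes follow

    y_ij = mu(n_i) + delta(n_i) * arm_i + b_i + e_ij,
    b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_e^2),

and binomial outcomes put the same linear predictor plus the cluster
intercept on the log-odds scale.  The intraclass correlation (ICC) is
rho = sigma_b^2 / (sigma_b^2 + sigma_e^2); either rho or sigma_b may be
given, never both.

Replicate streams come from a counter-based Philox generator keyed by
(base seed, replicate index), so any replicate can be regenerated
bit-identically without replaying the ones before it.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from collections.abc import Sequence

import numpy as np

from .data import CRTDataset

__all__ = [
    "Stratum",
    "GenerativeSpec",
    "sigma_b_from_icc",
    "randomize_clusters",
    "generate_dataset",
    "preset_scenarios",
    "PRESETS",
]


@dataclasses.dataclass(frozen=True)
class Stratum:
    """A group of equally sized clusters sharing baseline and true effect.

    For gaussian outcomes ``baseline``/``effect`` are on the outcome scale;
    for binomial outcomes both are on the log-odds scale.
    """

    count: int
    size: int
    baseline: float
    effect: float

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("stratum count must be >= 1")
        if self.size < 1:
            raise ValueError("cluster size must be >= 1")


@dataclasses.dataclass(frozen=True)
class GenerativeSpec:
    """Complete definition of a simulated CRT scenario."""

    strata: tuple[Stratum, ...]
    family: str = "gaussian"  # gaussian | binomial
    sigma_e: float = 1.0
    icc: float | None = None
    sigma_b: float | None = None
    allocation: str = "stratified"  # stratified | simple
    seed: int = 0

    def __post_init__(self) -> None:
        strata = tuple(
            s if isinstance(s, Stratum) else Stratum(*s) for s in self.strata
        )
        object.__setattr__(self, "strata", strata)
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.allocation not in ("stratified", "simple"):
            raise ValueError(f"unknown allocation {self.allocation!r}")
        if sum(s.count for s in strata) < 2:
            raise ValueError("need at least 2 clusters in total")
        if (self.icc is None) == (self.sigma_b is None):
            raise ValueError("exactly one of icc and sigma_b must be given")
        if self.icc is not None and not (0.0 <= self.icc < 1.0):
            raise ValueError("icc must lie in [0, 1)")
        if self.sigma_b is not None and self.sigma_b < 0:
            raise ValueError("sigma_b must be >= 0")
        if self.sigma_e < 0:
            raise ValueError("sigma_e must be >= 0")

    @property
    def n_clusters(self) -> int:
        return sum(s.count for s in self.strata)

    @property
    def n_participants(self) -> int:
        return sum(s.count * s.size for s in self.strata)

    def resolved_sigma_b(self) -> float:
        """Between-cluster SD, converting from the ICC if that was given."""
        if self.sigma_b is not None:
            return float(self.sigma_b)
        if self.family == "gaussian":
            return sigma_b_from_icc(self.icc, self.sigma_e)
        # binomial latent scale: residual variance of the standard logistic
        return sigma_b_from_icc(self.icc, math.pi / math.sqrt(3.0))

    def with_icc(self, icc: float) -> "GenerativeSpec":
        return dataclasses.replace(self, icc=icc, sigma_b=None)

    def sizes(self) -> np.ndarray:
        """Cluster size per cluster, stratum by stratum."""
        return np.repeat([s.size for s in self.strata], [s.count for s in self.strata])

    def effects(self) -> np.ndarray:
        """True effect per cluster (matching :meth:`sizes`)."""
        return np.repeat([s.effect for s in self.strata], [s.count for s in self.strata])

    def baselines(self) -> np.ndarray:
        return np.repeat([s.baseline for s in self.strata], [s.count for s in self.strata])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["strata"] = [dataclasses.asdict(s) for s in self.strata]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeSpec":
        d = dict(d)
        d["strata"] = tuple(
            Stratum(**s) if isinstance(s, dict) else Stratum(*s) for s in d["strata"]
        )
        return cls(**d)


def sigma_b_from_icc(icc: float, sigma_e: float) -> float:
    """Between-cluster SD giving the requested ICC at residual SD ``sigma_e``.

    Inverts rho = sigma_b^2 / (sigma_b^2 + sigma_e^2):
    sigma_b = sigma_e * sqrt(rho / (1 - rho)).
    """
    if not 0.0 <= icc < 1.0:
        raise ValueError("icc must lie in [0, 1)")
    if sigma_e <= 0:
        raise ValueError("sigma_e must be > 0")
    return float(sigma_e) * math.sqrt(icc / (1.0 - icc))


def _replicate_rng(base_seed: int, replicate: int) -> np.random.Generator:
    # Philox is counter-based: keying on (base_seed, replicate) gives
    # independent streams regardless of execution order.
    return np.random.Generator(np.random.Philox(key=(int(base_seed) << 32) + int(replicate)))


def randomize_clusters(spec: GenerativeSpec, rng: np.random.Generator) -> np.ndarray:
    """Assign arms (0/1) to clusters.

    ``stratified`` splits each size stratum as evenly as possible (the odd
    cluster, if any, goes to a random arm); ``simple`` is complete
    randomization with equal arm totals overall.  A stratified request
    where some stratum has a single cluster falls back to pooled complete
    randomization, since a within-stratum split is impossible.
    """
    counts = [s.count for s in spec.strata]
    if spec.allocation == "stratified" and any(c < 2 for c in counts):
        warnings.warn(
            "stratified allocation needs >=2 clusters per stratum; "
            "falling back to pooled complete randomization",
            stacklevel=2,
        )
    if spec.allocation == "stratified" and all(c >= 2 for c in counts):
        arms = []
        for c in counts:
            half = c // 2
            a = np.array([0] * half + [1] * half + ([int(rng.integers(2))] if c % 2 else []))
            rng.shuffle(a)
            arms.append(a)
        return np.concatenate(arms)
    total = sum(counts)
    half = total // 2
    a = np.array([0] * half + [1] * (total - half))
    rng.shuffle(a)
    return a


def generate_dataset(spec: GenerativeSpec, replicate: int = 0) -> CRTDataset:
    """Draw one synthetic CRT dataset from ``spec``.

    The stream is a pure function of ``(spec.seed, replicate)``; equal
    inputs reproduce the dataset bit-for-bit.
    """
    rng = _replicate_rng(spec.seed, replicate)
    sizes = spec.sizes()
    base = spec.baselines()
    eff = spec.effects()
    arms = randomize_clusters(spec, rng)
    sigma_b = spec.resolved_sigma_b()

    g = len(sizes)
    b = rng.normal(0.0, sigma_b, size=g) if sigma_b > 0 else np.zeros(g)
    eta_cluster = base + eff * arms + b
    eta = np.repeat(eta_cluster, sizes)
    if spec.family == "gaussian":
        y = eta + (rng.normal(0.0, spec.sigma_e, size=len(eta)) if spec.sigma_e > 0 else 0.0)
    else:
        p = 1.0 / (1.0 + np.exp(-eta))
        y = (rng.random(len(eta)) < p).astype(float)

    labels = np.repeat(
        np.array([f"c{i:04d}" for i in range(g)], dtype=object), sizes
    )
    return CRTDataset(cluster=labels, arm=np.repeat(arms, sizes), outcome=np.asarray(y, float))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


PRESETS: dict[str, GenerativeSpec] = {
    # 60 clusters, half of size 10 with true effect 5, half of size 100 with
    # true effect 1; continuous outcome with residual SD 5.  Participant-
    # average truth 450/330 = 1.36, cluster-average truth 3.
    "figure1": GenerativeSpec(
        strata=(Stratum(30, 10, 0.0, 5.0), Stratum(30, 100, 0.0, 1.0)),
        family="gaussian",
        sigma_e=5.0,
        icc=0.1,
    ),
    # Type-1 informative cluster size: event rate 10% in small clusters and
    # 20% in large ones, conditional odds ratio 0.75 in both.
    "type1-binary": GenerativeSpec(
        strata=(
            Stratum(30, 10, _logit(0.10), math.log(0.75)),
            Stratum(30, 100, _logit(0.20), math.log(0.75)),
        ),
        family="binomial",
        sigma_e=0.0,
        sigma_b=0.0,
        icc=None,
    ),
    # Type-2: the effect itself depends on size (OR 0.75 small, 0.50 large).
    "type2-binary": GenerativeSpec(
        strata=(
            Stratum(30, 10, _logit(0.10), math.log(0.75)),
            Stratum(30, 100, _logit(0.10), math.log(0.50)),
        ),
        family="binomial",
        sigma_e=0.0,
        sigma_b=0.0,
        icc=None,
    ),
}


def preset_scenarios(name: str) -> GenerativeSpec:
    """Return a named, fully populated scenario."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
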