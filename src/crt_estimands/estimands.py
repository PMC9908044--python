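"""True participant-average and cluster-average treatment effects.

A cluster-randomized trial can target two distinct estimands:

* the participant-average treatment effect ``Delta_P``, which weights each
  participant equally: ``sum(n_i * delta_i) / sum(n_i)``;
* the cluster-average treatment effect ``Delta_C``, which weights each
  cluster equally: ``sum(delta_i) / k``.

On collapsible scales (difference in means, risk difference, risk ratio)
the two coincide unless the true effect varies with cluster size.  For the
non-collapsible odds ratio they can differ as soon as outcomes *or*
effects vary with size, which :func:`marginal_estimands_binary` quantifies
by integrating a cluster-level random intercept out of the log-odds model
with Gauss-Hermite quadrature.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np

from .simulate import GenerativeSpec

__all__ = [
    "ClusterEffectProfile",
    "EstimandPair",
    "participant_average_effect",
    "cluster_average_effect",
    "marginal_estimands_binary",
    "marginal_probability",
]

_MEASURES = ("difference_in_means", "risk_difference", "risk_ratio", "odds_ratio")


@dataclasses.dataclass(frozen=True)
class ClusterEffectProfile:
    """Cluster sizes ``n_i`` and true effects ``delta_i`` on a collapsible scale."""

    sizes: tuple[int, ...]
    effects: tuple[float, ...]

    def __post_init__(self) -> None:
        sizes = tuple(int(n) for n in self.sizes)
        effects = tuple(float(d) for d in self.effects)
        if len(sizes) != len(effects):
            raise ValueError("sizes and effects must have equal length")
        if len(sizes) == 0:
            raise ValueError("profile is empty")
        if any(n < 1 for n in sizes):
            raise ValueError("cluster sizes must be >= 1")
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "effects", effects)

    @classmethod
    def from_spec(cls, spec: GenerativeSpec) -> "ClusterEffectProfile":
        """Profile implied by a generative scenario (one entry per cluster)."""
        return cls(tuple(spec.sizes().tolist()), tuple(spec.effects().tolist()))


@dataclasses.dataclass(frozen=True)
class EstimandPair:
    """The two estimands on a common summary measure."""

    participant_average: float
    cluster_average: float
    measure: str

    def __post_init__(self) -> None:
        if self.measure not in _MEASURES:
            raise ValueError(f"measure must be one of {_MEASURES}")
        for v in (self.participant_average, self.cluster_average):
            if not np.isfinite(v):
                raise ValueError("estimand values must be finite")
            if self.measure in ("risk_ratio", "odds_ratio") and v <= 0:
                raise ValueError("ratio estimands must be strictly positive")


def participant_average_effect(profile: ClusterEffectProfile) -> float:
    """Size-weighted average of cluster effects: sum(n_i d_i) / sum(n_i)."""
    n = np.asarray(profile.sizes, float)
    d = np.asarray(profile.effects, float)
    return float(np.sum(n * d) / np.sum(n))


def cluster_average_effect(profile: ClusterEffectProfile) -> float:
    """Unweighted average of cluster effects: sum(d_i) / k (sizes ignored)."""
    return float(np.mean(profile.effects))


def _gh_nodes(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    # probabilist convention: nodes/weights for E[f(Z)], Z ~ N(0,1)
    x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    return x, w / np.sqrt(2.0 * np.pi)


def marginal_probability(eta: float, sigma_b: float, n_nodes: int = 64) -> float:
    """Marginal event probability E[expit(eta + b)], b ~ N(0, sigma_b^2).

    Computed by Gauss-Hermite quadrature with ``n_nodes`` nodes
    (probabilist convention), so results are bit-reproducible.
    """
    if sigma_b < 0:
        raise ValueError("sigma_b must be >= 0")
    if sigma_b == 0:
        return float(1.0 / (1.0 + np.exp(-eta)))
    x, w = _gh_nodes(n_nodes)
    p = float(np.sum(w / (1.0 + np.exp(-(eta + sigma_b * x)))))
    if not 0.0 < p < 1.0:
        raise ArithmeticError(f"integrated probability {p} outside (0, 1)")
    return p


def _summary(p1: float, p0: float, measure: str) -> float:
    if measure == "risk_difference":
        return p1 - p0
    if measure == "risk_ratio":
        return p1 / p0
    if measure == "odds_ratio":
        return (p1 / (1 - p1)) / (p0 / (1 - p0))
    raise ValueError(f"measure {measure!r} not defined for binary outcomes")


def marginal_estimands_binary(
    spec: GenerativeSpec,
    measure: str = "odds_ratio",
    n_nodes: int = 64,
    cluster_average_of_log_or: bool = False,
) -> EstimandPair:
    """True marginal estimands for a binomial scenario.

    Per size stratum and arm the conditional log-odds ``baseline + effect *
    arm`` is integrated over the latent cluster intercept to get marginal
    probabilities.  ``Delta_P`` applies ``measure`` to probabilities
    averaged with participant weights (stratum count x size); ``Delta_C``
    uses cluster weights (stratum count).

    By default the cluster-average estimand applies the summary measure to
    equally-cluster-weighted probabilities, exactly parallel to the
    participant-average definition.  ``cluster_average_of_log_or=True``
    instead averages stratum log odds ratios (odds-ratio measure only),
    which is the other defensible convention.
    """
    if spec.family != "binomial":
        raise ValueError("marginal_estimands_binary requires a binomial spec")
    sigma_b = spec.resolved_sigma_b()

    counts = np.array([s.count for s in spec.strata], float)
    sizes = np.array([s.size for s in spec.strata], float)
    p0 = np.array(
        [marginal_probability(s.baseline, sigma_b, n_nodes) for s in spec.strata]
    )
    p1 = np.array(
        [marginal_probability(s.baseline + s.effect, sigma_b, n_nodes) for s in spec.strata]
    )

    w_part = counts * sizes
    p0_part = float(np.sum(w_part * p0) / np.sum(w_part))
    p1_part = float(np.sum(w_part * p1) / np.sum(w_part))
    delta_p = _summary(p1_part, p0_part, measure)

    if cluster_average_of_log_or:
        if measure != "odds_ratio":
            raise ValueError("cluster_average_of_log_or applies to the odds ratio only")
        log_ors = np.log([_summary(a, b, "odds_ratio") for a, b in zip(p1, p0)])
        delta_c = float(np.exp(np.sum(counts * log_ors) / np.sum(counts)))
    else:
        p0_cl = float(np.sum(counts * p0) / np.sum(counts))
        p1_cl = float(np.sum(counts * p1) / np.sum(counts))
        delta_c = _summary(p1_cl, p0_cl, measure)

    return EstimandPair(delta_p, delta_c, measure)
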