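"""Detection and availability probability machinery for point-count surveys.

Point counts record, for every bird, the radial distance class of first
detection and the time interval of first detection.  Two thinning
processes act on the birds actually present:

* **perceptibility** -- an available bird at radial distance ``r`` is
  detected with probability :math:`g(r) = \\exp(-r^2 / 2\\sigma^2)`
  (half-normal detection function with scale ``sigma``);
* **availability** -- a bird gives a detectable cue in removal interval
  ``j`` with geometric probability :math:`\\pi_{a,j} = p_a (1-p_a)^{j-1}`,
  so overall availability over ``J`` intervals is
  :math:`\\phi = 1 - (1-p_a)^J`.

Distances are binned; the multinomial cell probability of detecting a
bird in bin ``b`` combines ``g`` with the triangular radial density
:math:`f(r) = 2 r / B^2` (uniform bird placement in the circle of
truncation radius ``B``), evaluated at the bin midpoint by the
rectangular rule:

.. math:: \\pi_{d,b} = g(r_b) \\, \\frac{2 r_b \\delta_b}{B^2}

The overall probability that an available bird is detected anywhere
inside the truncation radius is :math:`p_d = \\sum_b \\pi_{d,b}`.

Everything here is a closed-form, deterministic function shared by the
simulator and both inference models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistanceBinning",
    "TimeRemovalScheme",
    "DetectionParams",
    "AvailabilityParams",
    "half_normal",
    "distance_cell_probs",
    "closed_form_pd",
    "conditional_distance_cells",
    "removal_cell_probs",
    "per_interval_availability",
    "DEFAULT_BINNING",
    "DEFAULT_REMOVAL",
]


@dataclass(frozen=True)
class DistanceBinning:
    """Radial distance classes out to a truncation radius.

    Parameters
    ----------
    edges : tuple of float
        Strictly increasing bin edges in meters, starting at 0.  The
        default reproduces the survey protocol bins
        0-25, >25-50, >50-100 and >100-150 m.
    """

    edges: tuple = (0.0, 25.0, 50.0, 100.0, 150.0)

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("need at least two bin edges")
        if edges[0] != 0.0:
            raise ValueError("first distance edge must be 0")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("distance edges must be strictly increasing")
        object.__setattr__(self, "edges", tuple(edges))

    @property
    def B(self) -> float:
        """Truncation radius in meters (outermost edge)."""
        return self.edges[-1]

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def midpoints(self) -> np.ndarray:
        e = np.asarray(self.edges)
        return (e[:-1] + e[1:]) / 2.0

    @property
    def widths(self) -> np.ndarray:
        return np.diff(np.asarray(self.edges))


@dataclass(frozen=True)
class TimeRemovalScheme:
    """Removal intervals of a timed count.

    The nominal minute boundaries are labels only: the availability
    model treats the count as ``J`` equal removal periods, which is
    exactly what the overall-availability identity
    ``phi = 1 - (1 - p_a)**J`` assumes.
    """

    J: int = 3
    labels: tuple = ("0-3 min", ">3-5 min", ">5-10 min")

    def __post_init__(self):
        if self.J < 1:
            raise ValueError("need at least one removal interval")
        if self.labels is not None and len(self.labels) != self.J:
            object.__setattr__(self, "labels", tuple(f"interval {j+1}" for j in range(self.J)))


@dataclass(frozen=True)
class DetectionParams:
    """Half-normal detection scale ``sigma`` in meters."""

    sigma: float = 55.0

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class AvailabilityParams:
    """Per-interval availability ``p_a`` and derived overall ``phi``."""

    p_a: float
    J: int = 3
    phi: float = field(init=False)

    def __post_init__(self):
        if not 0 < self.p_a < 1:
            raise ValueError("p_a must lie in (0, 1)")
        if self.J < 1:
            raise ValueError("J must be >= 1")
        object.__setattr__(self, "phi", 1.0 - (1.0 - self.p_a) ** self.J)


DEFAULT_BINNING = DistanceBinning()
DEFAULT_REMOVAL = TimeRemovalScheme()


def half_normal(r, sigma):
    """Half-normal detection function ``g(r) = exp(-r^2 / (2 sigma^2))``.

    Parameters
    ----------
    r : float or array_like
        Radial distance in meters, >= 0.
    sigma : float
        Scale parameter in meters, > 0.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    out = np.exp(-(r ** 2) / (2.0 * sigma ** 2))
    return out if out.ndim else float(out)


def distance_cell_probs(binning: DistanceBinning = DEFAULT_BINNING,
                        params: DetectionParams = DetectionParams()):
    """Multinomial distance-cell probabilities and overall perceptibility.

    Evaluates ``pi_b = g(r_b) * 2 r_b delta_b / B**2`` at bin midpoints
    (rectangular rule) and returns ``(pi, p_d)`` with ``p_d = pi.sum()``.
    """
    r = binning.midpoints
    delta = binning.widths
    B = binning.B
    pi = half_normal(r, params.sigma) * 2.0 * r * delta / B ** 2
    return pi, float(pi.sum())


def closed_form_pd(sigma: float, B: float) -> float:
    """Exact integral of ``g(r) * 2r/B^2`` over [0, B].

    Analytic oracle for the rectangular rule:
    ``(2 sigma^2 / B^2) * (1 - exp(-B^2 / (2 sigma^2)))``.
    """
    if not (sigma > 0 and B > 0):
        raise ValueError("sigma and B must be positive")
    s2 = 2.0 * sigma ** 2
    return float((s2 / B ** 2) * -np.expm1(-(B ** 2) / s2))


def conditional_distance_cells(pi_d) -> np.ndarray:
    """Normalize distance cells to the conditional multinomial
    ``pi_b / p_d`` used in the per-detection likelihood."""
    pi_d = np.asarray(pi_d, dtype=float)
    if np.any(pi_d < 0):
        raise ValueError("cell probabilities must be non-negative")
    total = pi_d.sum()
    if total <= 0:
        raise ValueError("degenerate input: all cells zero")
    return pi_d / total


def removal_cell_probs(p_a: float, scheme: TimeRemovalScheme = DEFAULT_REMOVAL):
    """Geometric removal cells and overall availability.

    Returns ``(pi_a, phi)`` with ``pi_a[j] = p_a (1-p_a)**j`` for
    ``j = 0..J-1`` and ``phi = pi_a.sum() = 1 - (1-p_a)**J``.
    """
    if not 0 < p_a < 1:
        raise ValueError("p_a must lie in (0, 1)")
    j = np.arange(scheme.J)
    pi_a = p_a * (1.0 - p_a) ** j
    phi = 1.0 - (1.0 - p_a) ** scheme.J
    return pi_a, float(phi)


def per_interval_availability(phi: float, J: int) -> float:
    """Invert ``phi = 1 - (1-p_a)**J`` for the per-interval ``p_a``."""
    if not 0 < phi < 1:
        raise ValueError("phi must lie in (0, 1)")
    if J < 1:
        raise ValueError("J must be >= 1")
    return 1.0 - (1.0 - phi) ** (1.0 / J)
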