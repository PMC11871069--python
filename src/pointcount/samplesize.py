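"""Required point-count calculator for target precision.

The survey-effort formula scales a pilot study's effort by the squared
ratio of its observed coefficient of variation (CV) to the target:

.. math:: k = \\frac{q}{CV_t^2} \\cdot \\frac{k_0}{n_0},
          \\qquad q = n_0 \\, CV_{obs}^2,

which simplifies to :math:`k = k_0 (CV_{obs}/CV_t)^2` -- the total
detections :math:`n_0` cancel, entering only through the pilot CV.
Targets of 0.15 (research precision) and 0.25 (management monitoring)
are conventional.  A packaged literature table gives minimum sample
sizes reported for bottomland-hardwood and riparian forest species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["PilotSummary", "SampleSizeResult", "required_points", "encounter_rate",
           "cv_scaling", "xyz_table", "literature_table", "literature_lookup",
           "round_half_up"]

#: Required-point classes of the design surface (from-to, points).
K_CLASSES = ((0, 50), (50, 100), (100, 250), (250, 500), (500, 1000),
             (1000, 2000), (2000, math.inf))


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (matches the
    published paired-column rounding; ceiling over-predicts)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class PilotSummary:
    """Pilot-survey inputs: ``n0`` total detections over ``k0`` points
    with observed density CV ``cv_obs``."""

    n0: int
    k0: int
    cv_obs: float
    density_hat: float | None = None

    def __post_init__(self):
        if self.n0 < 0 or int(self.n0) != self.n0:
            raise ValueError("n0 must be a non-negative integer")
        if self.k0 < 1:
            raise ValueError("k0 must be >= 1")
        if not self.cv_obs > 0:
            raise ValueError("cv_obs must be positive")

    @property
    def q(self) -> float:
        """Variance-rate constant ``n0 * cv_obs**2``."""
        return self.n0 * self.cv_obs ** 2


@dataclass(frozen=True)
class SampleSizeResult:
    cv_target: float
    k: float
    k_rounded: int
    pilot: PilotSummary


def required_points(pilot: PilotSummary, cv_target: float) -> SampleSizeResult:
    """Points needed to achieve ``cv_target``: ``k0 * (cv_obs/cv_target)**2``."""
    if not cv_target > 0:
        raise ValueError("cv_target must be positive")
    if pilot.n0 == 0:
        raise ValueError("encounter rate undefined: pilot recorded no detections")
    k = pilot.q / cv_target ** 2 * pilot.k0 / pilot.n0
    return SampleSizeResult(cv_target, k, round_half_up(k), pilot)


def encounter_rate(pilot: PilotSummary) -> float:
    """Average detections per surveyed point, ``n0 / k0``."""
    return pilot.n0 / pilot.k0


def cv_scaling(k_at_cv1: float, cv1: float, cv2: float) -> float:
    """Re-express a required point count at a different target CV:
    ``k * (cv1/cv2)**2``."""
    if not (k_at_cv1 > 0 and cv1 > 0 and cv2 > 0):
        raise ValueError("all arguments must be positive")
    return k_at_cv1 * (cv1 / cv2) ** 2


def _k_class(k: float) -> str:
    for lo, hi in K_CLASSES:
        if lo <= k < hi:
            return f">{lo}" if math.isinf(hi) else f"{lo}-{hi}"
    raise AssertionError("unreachable")


def xyz_table(pilots, cv_targets=(0.15, 0.25),
              count_bins=(0, 50, 100, 250, 500, 1000, 2000, math.inf),
              cv_bins=(0.0, 0.15, 0.30, 0.45, 0.60, math.inf)) -> pd.DataFrame:
    """Design surface: median required points per (total-count bin x
    observed-CV bin x target CV), with the median also classed into
    the published point-count bins."""
    pilots = list(pilots)
    if not pilots:
        raise ValueError("need at least one pilot summary")
    recs = []
    for p in pilots:
        for cvt in cv_targets:
            k = required_points(p, cvt).k
            recs.append({"n0": p.n0, "cv_obs": p.cv_obs, "cv_target": cvt, "k": k})
    df = pd.DataFrame(recs)
    df["count_bin"] = pd.cut(df["n0"], bins=list(count_bins), right=False)
    df["cv_bin"] = pd.cut(df["cv_obs"], bins=list(cv_bins), right=False)
    out = (df.groupby(["count_bin", "cv_bin", "cv_target"], observed=True)["k"]
             .median().dropna().reset_index(name="median_k"))
    out["k_class"] = out["median_k"].map(_k_class)
    return out


def literature_table() -> pd.DataFrame:
    """The packaged literature benchmark of minimum sample sizes."""
    with resources.files("pointcount").joinpath("data/table4_literature.csv").open() as fh:
        return pd.read_csv(fh)


def literature_lookup(species_name: str) -> dict:
    """Average minimum sample size and range for a species (exact or
    case-insensitive match; unknown names raise with nearest matches)."""
    tab = literature_table()
    hit = tab[tab["species"].str.lower() == species_name.strip().lower()]
    if hit.empty and species_name.strip().lower() == "multispecies":
        hit = tab[tab["species"].str.startswith("Multispecies")]
    if hit.empty:
        import difflib
        near = difflib.get_close_matches(species_name, tab["species"].tolist(), n=3, cutoff=0.3)
        raise KeyError(f"species {species_name!r} not in the literature table; "
                       f"nearest matches: {near}")
    row = hit.iloc[0]
    rng = None
    if pd.notna(row["range_lo"]) and pd.notna(row["range_hi"]):
        rng = (int(row["range_lo"]), int(row["range_hi"]))
    return {"species": row["species"], "average": int(row["avg_min_n"]),
            "range": rng, "references": row["references"]}
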