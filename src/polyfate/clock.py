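"""Temporal model of post-duplication gene shuffling.

Literature observations of the percentage of duplicated genes that have been
structurally lost (pseudogenized/deleted) or functionally diverged (neo-/
subfunctionalized) are plotted against time since the duplication and
summarized with a logarithmic curve,

    shuffled(t) = clamp(a + b * ln t, 0, 100)   [t in million years],

fitted by weighted least squares on interval midpoints (weights 1/half-width
squared, floored at a 1-percent half-width for point observations).  The
fitted curve answers questions such as "when are half the duplicates
shuffled?" via the closed-form inversion t = exp((level - a) / b).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MODES = ("structural", "functional")


@dataclass(frozen=True)
class ShufflingObservation:
    """One literature data point: a taxon's duplicate-shuffling percentage
    band at a divergence-time band (million years)."""

    taxon: str
    time_range: tuple[float, float]
    percent_range: tuple[float, float]
    mode: str

    def __post_init__(self) -> None:
        tl, th = self.time_range
        pl, ph = self.percent_range
        if not 0 < tl <= th:
            raise ValueError("time range must satisfy 0 < low <= high")
        if not 0 < pl <= ph <= 100:
            raise ValueError("percent range must satisfy 0 < low <= high <= 100")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    @property
    def time_mid(self) -> float:
        return 0.5 * (self.time_range[0] + self.time_range[1])

    @property
    def percent_mid(self) -> float:
        return 0.5 * (self.percent_range[0] + self.percent_range[1])


@dataclass(frozen=True)
class ShufflingCurve:
    mode: str  # structural | functional | total
    a: float
    b: float
    fit_residual: float  # RMS in percent points
    t_min: float  # earliest observed midpoint time
    t_max: float

    def predict(self, t: float) -> float:
        """Clamped prediction; see ``extrapolates`` for the range flag."""
        if t <= 0:
            raise ValueError("time must be positive")
        return float(np.clip(self.a + self.b * math.log(t), 0.0, 100.0))

    def extrapolates(self, t: float) -> bool:
        return t < self.t_min or t > self.t_max


def fit_curve(
    observations: Sequence[ShufflingObservation],
    mode: str = "total",
    min_halfwidth: float = 1.0,
) -> ShufflingCurve:
    """Weighted least-squares fit of percent = a + b ln(t) on midpoints.

    ``mode="total"`` pools structural and functional observations into one
    curve.  Requires at least two observations; the fitted slope must be
    positive (shuffling accumulates with time).
    """
    if mode == "total":
        obs = list(observations)
    else:
        obs = [o for o in observations if o.mode == mode]
    if len(obs) < 2:
        raise ValueError(f"need at least two observations for mode {mode!r}, got {len(obs)}")
    x = np.array([math.log(o.time_mid) for o in obs])
    y = np.array([o.percent_mid for o in obs])
    halfwidth = np.array(
        [max(min_halfwidth, 0.5 * (o.percent_range[1] - o.percent_range[0])) for o in obs]
    )
    w = 1.0 / halfwidth**2
    b, a = np.polyfit(x, y, 1, w=np.sqrt(w))
    if b <= 0:
        raise ValueError("fitted slope is non-positive; shuffling must increase with time")
    residual = float(np.sqrt(np.mean((a + b * x - y) ** 2)))
    return ShufflingCurve(
        mode=mode,
        a=float(a),
        b=float(b),
        fit_residual=residual,
        t_min=float(min(o.time_mid for o in obs)),
        t_max=float(max(o.time_mid for o in obs)),
    )


def time_at_level(curve: ShufflingCurve, level: float) -> tuple[float, bool]:
    """Invert the (unclamped) curve: the time at which the fitted shuffling
    percentage reaches ``level``.  Returns (time in MY, extrapolation flag).
    """
    if curve.b <= 0:
        raise ValueError("curve slope must be positive to invert")
    if not 0 < level <= 100:
        raise ValueError("level must lie in (0, 100]")
    t = math.exp((level - curve.a) / curve.b)
    return t, curve.extrapolates(t)


def load_observations(path=None) -> list[ShufflingObservation]:
    """Load shuffling observations from a TSV (taxon, mode, time_low,
    time_high, percent_low, percent_high); defaults to the bundled
    literature compilation."""
    if path is None:
        source = resources.files("polyfate").joinpath("data/shuffling_observations.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    return [
        ShufflingObservation(
            taxon=str(r.taxon),
            time_range=(float(r.time_low), float(r.time_high)),
            percent_range=(float(r.percent_low), float(r.percent_high)),
            mode=str(r.mode),
        )
        for r in df.itertuples(index=False)
    ]


def curve_to_json(curve: ShufflingCurve, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "mode": curve.mode,
                "form": "percent = clamp(a + b*ln(t_MY), 0, 100)",
                "a": curve.a,
                "b": curve.b,
                "fit_residual_percent": curve.fit_residual,
                "t_min": curve.t_min,
                "t_max": curve.t_max,
            },
            fh,
            indent=2,
        )
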