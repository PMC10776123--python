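"""Cumulative mortality curves and inflection detection.

A cohort's weekly death record is turned into cumulative mortality
M(t) = deaths(<=t) / N, plotted on a log10 scale from the first death
onward.  Inflection points of the log-mortality trajectory are located
with the extremum surface estimator (ESE): for each interior point the
signed area between the data polyline and the chord from either end is
computed, and the inflection abscissa is the midpoint of the two surface
extrema.  A recursive-bisection wrapper searches for up to two
inflections, which delimit up to three life-history phases (early life,
exponential Gompertzian aging, late-life mortality plateau).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SurvivalData",
    "MortalitySeries",
    "InflectionEstimate",
    "cumulative_mortality",
    "ese_inflection",
    "find_inflections",
]


@dataclass
class SurvivalData:
    """Per-individual death weeks plus censoring, with cohort size N.

    Censored animals are excluded from the death tally but count toward N
    (standard life-table bookkeeping).
    """

    death_weeks: np.ndarray
    censor_weeks: np.ndarray = field(default_factory=lambda: np.empty(0))
    N: int = 0

    def __post_init__(self) -> None:
        self.death_weeks = np.sort(np.asarray(self.death_weeks, float))
        self.censor_weeks = np.sort(np.asarray(self.censor_weeks, float))
        if (self.death_weeks < 0).any() or (self.censor_weeks < 0).any():
            raise ValueError("negative weeks in survival data")
        n_total = len(self.death_weeks) + len(self.censor_weeks)
        if self.N == 0:
            self.N = n_total
        if self.N < n_total:
            raise ValueError(f"N={self.N} smaller than number of animals {n_total}")
        if self.N == 0:
            raise ValueError("empty survival data")

    @classmethod
    def from_death_weeks(cls, death_weeks, censor_weeks=(), N: int = 0) -> "SurvivalData":
        return cls(np.asarray(death_weeks, float), np.asarray(censor_weeks, float), N)

    @classmethod
    def from_alive_counts(cls, weeks, alive) -> "SurvivalData":
        """Expand a (week, number alive) census into per-individual death weeks."""
        weeks = np.asarray(weeks, float)
        alive = np.asarray(alive, float)
        if len(weeks) == 0:
            raise ValueError("empty alive-count table")
        if (weeks < 0).any():
            raise ValueError("negative weeks in alive-count table")
        order = np.argsort(weeks)
        weeks, alive = weeks[order], alive[order]
        inc = np.diff(alive) > 0
        if inc.any():
            w = weeks[1:][inc][0]
            raise ValueError(f"alive count increases at week {w:g}")
        N = int(alive[0])
        deaths = -np.diff(np.concatenate([[N], alive])).astype(int)
        death_weeks = np.repeat(weeks, deaths)
        return cls(death_weeks, N=N)

    def alive_counts(self) -> dict:
        """Alive count just before the first death and at each death week."""
        out = {}
        if len(self.death_weeks):
            first = self.death_weeks[0]
            out[first - 1] = self.N
        for w in np.unique(self.death_weeks):
            dead = np.sum(self.death_weeks <= w)
            lost = np.sum(self.censor_weeks <= w)
            out[w] = int(self.N - dead - lost)
        return out


@dataclass
class MortalitySeries:
    """Weekly cumulative mortality with its log10 transform.

    ``log_weeks``/``log_values`` cover only weeks with M > 0 (the log curve
    starts at the first death).
    """

    weeks: np.ndarray
    mortality: np.ndarray
    N: int

    def __post_init__(self) -> None:
        self.weeks = np.asarray(self.weeks, float)
        self.mortality = np.asarray(self.mortality, float)
        if self.N <= 0:
            raise ValueError("cohort size N must be positive")
        if (np.diff(self.weeks) <= 0).any():
            raise ValueError("weeks must be strictly increasing")
        if (np.diff(self.mortality) < -1e-12).any():
            raise ValueError("cumulative mortality must be nondecreasing")

    @property
    def log_weeks(self) -> np.ndarray:
        return self.weeks[self.mortality > 0]

    @property
    def log_values(self) -> np.ndarray:
        return np.log10(self.mortality[self.mortality > 0])


def cumulative_mortality(data: SurvivalData, N: int | None = None) -> MortalitySeries:
    """Weekly cumulative mortality M(t) = deaths(<= t) / N.

    The census runs on integer weeks from week 1 (or the first recorded
    week, if earlier) through the last death.
    """
    N = data.N if N is None else N
    if N <= 0:
        raise ValueError("cohort size N must be positive")
    if len(data.death_weeks) == 0:
        warnings.warn("no deaths recorded; log-mortality series is empty")
        return MortalitySeries(np.array([1.0]), np.array([0.0]), N)
    last = int(np.ceil(data.death_weeks.max()))
    weeks = np.arange(1, last + 1, dtype=float)
    deaths = np.searchsorted(data.death_weeks, weeks, side="right")
    return MortalitySeries(weeks, deaths / N, N)


@dataclass
class InflectionEstimate:
    """One ESE inflection: midpoint of the left/right surface extrema."""

    x_hat: float
    j1: int
    j2: int
    orientation: str  # "convex_concave" or "concave_convex"
    confirmed: bool = True


def _second_differences(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Second divided differences at interior points (length n-2)."""
    h1 = x[1:-1] - x[:-2]
    h2 = x[2:] - x[1:-1]
    return 2 * (
        y[:-2] / (h1 * (h1 + h2)) - y[1:-1] / (h1 * h2) + y[2:] / (h2 * (h1 + h2))
    )


def ese_inflection(x, y) -> InflectionEstimate | None:
    """Extremum surface estimator for a single inflection point.

    For each interior index i, ``a_i`` is the trapezoidal area of the data
    polyline over [x_0, x_i] minus the chord trapezoid, and ``b_i`` the same
    from the right.  For an S-shaped (convex-then-concave) curve the
    inflection lies midway between argmin a and argmax b; the opposite
    orientation swaps the extrema.  The orientation is chosen by which
    extremum pair is jointly stronger — an asymmetric sigmoid can have
    either curvature regime dominate the total signed area, so the sign
    of the full-span surface alone is not reliable.  Returns ``None``
    when the second differences show no curvature sign change
    ("no inflection").
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 5:
        raise ValueError(f"need at least 5 points, got {n}")
    if (np.diff(x) <= 0).any():
        raise ValueError("x must be strictly increasing")

    d2 = _second_differences(x, y)
    # scale-aware zero: float fuzz on straight data is not curvature
    atol = 1e-9 * max(1.0, np.abs(y).max()) / np.median(np.diff(x)) ** 2
    signs = np.sign(d2[np.abs(d2) > atol])
    if len(signs) == 0 or np.all(signs == signs[0]):
        return None

    seg = 0.5 * (y[1:] + y[:-1]) * np.diff(x)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    a = cum - 0.5 * (x - x[0]) * (y[0] + y)                 # left surfaces
    b = (total - cum) - 0.5 * (x[-1] - x) * (y + y[-1])     # right surfaces

    ai, bi = a[1 : n - 1], b[1 : n - 1]
    # convex-then-concave shows a deep minimum of the left surfaces and a
    # high maximum of the right surfaces; concave-then-convex the reverse
    score_cc = max(0.0, -ai.min()) + max(0.0, bi.max())
    score_cx = max(0.0, ai.max()) + max(0.0, -bi.min())
    if score_cc >= score_cx:
        orientation = "convex_concave"
        j1 = 1 + int(np.argmin(ai))
        j2 = 1 + int(np.argmax(bi))
    else:
        orientation = "concave_convex"
        j1 = 1 + int(np.argmax(ai))
        j2 = 1 + int(np.argmin(bi))
    x_hat = 0.5 * (x[j1] + x[j2])
    return InflectionEstimate(x_hat=float(x_hat), j1=j1, j2=j2, orientation=orientation)


def _smoothed_d2_sign_changes(x, y, window: int = 3) -> np.ndarray:
    """Abscissae of sign changes in second differences of the smoothed curve."""
    y = np.asarray(y, float)
    if window > 1 and len(y) >= window:
        kernel = np.ones(window) / window
        ys = np.convolve(y, kernel, mode="same")
        half = window // 2
        ys[:half] = y[:half]
        ys[-half:] = y[-half:]
    else:
        ys = y
    x = np.asarray(x, float)
    d2 = _second_differences(x, ys)
    atol = 1e-9 * max(1.0, np.abs(ys).max()) / np.median(np.diff(x)) ** 2
    d2 = np.where(np.abs(d2) > atol, d2, 0.0)
    xs = x[1:-1]
    s = np.sign(d2)
    idx = np.where((s[:-1] != s[1:]) & (s[:-1] != 0) & (s[1:] != 0))[0]
    return 0.5 * (xs[idx] + xs[idx + 1])


def find_inflections(
    series,
    max_points: int = 2,
    smooth_window: int = 3,
    confirm_halfwidth: float | None = None,
    mode: str = "bisection",
):
    """Locate up to ``max_points`` inflections of the log-mortality curve.

    ``series`` is a :class:`MortalitySeries` or an ``(x, y)`` pair.  In the
    default recursive-bisection mode, ESE runs on the full series, the
    series is split at the resulting abscissa, and the search recurses on
    each side; candidates are kept only when a sign change of the smoothed
    second differences falls within ``confirm_halfwidth`` of the estimate
    (default: three median grid steps), and at most one candidate — the
    closest — survives per sign-change location.  ``mode="sliding_window"``
    instead scans half-length windows.  Returns estimates sorted by x;
    when fewer than requested are confirmed, a warning is issued.
    """
    if isinstance(series, MortalitySeries):
        x, y = series.log_weeks, series.log_values
    else:
        x, y = series
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 5:
        raise ValueError("need at least 5 points with positive mortality")

    step = float(np.median(np.diff(x)))
    if confirm_halfwidth is None:
        confirm_halfwidth = 3.0 * step
    changes = _smoothed_d2_sign_changes(x, y, smooth_window)

    candidates: list[InflectionEstimate] = []

    def consider(est: InflectionEstimate | None) -> None:
        if est is None:
            return
        est.confirmed = bool(
            len(changes) and np.min(np.abs(changes - est.x_hat)) <= confirm_halfwidth
        )
        candidates.append(est)

    if mode == "bisection":

        def recurse(mask: np.ndarray, depth: int) -> None:
            if depth > 4 or mask.sum() < 5:
                return
            est = ese_inflection(x[mask], y[mask])
            if est is None:
                return
            consider(est)
            recurse(mask & (x <= est.x_hat), depth + 1)
            recurse(mask & (x >= est.x_hat), depth + 1)

        recurse(np.ones_like(x, dtype=bool), 0)
    elif mode == "sliding_window":
        width = max(5, len(x) // 2)
        for start in range(0, len(x) - width + 1, max(1, width // 4)):
            consider(ese_inflection(x[start : start + width], y[start : start + width]))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # one estimate per curvature sign change: keep the closest candidate
    best: dict[int, InflectionEstimate] = {}
    for c in candidates:
        if not c.confirmed:
            continue
        nearest = int(np.argmin(np.abs(changes - c.x_hat)))
        if nearest not in best or abs(c.x_hat - changes[nearest]) < abs(
            best[nearest].x_hat - changes[nearest]
        ):
            best[nearest] = c
    confirmed = sorted(best.values(), key=lambda c: c.x_hat)
    if len(confirmed) < max_points:
        warnings.warn(
            f"only {len(confirmed)} confirmed inflection(s) found "
            f"(requested {max_points})"
        )
    return confirmed[:max_points]


def phases(series: MortalitySeries, inflections) -> list[tuple[float, float]]:
    """Life-history phase boundaries implied by the inflection abscissae."""
    cuts = [series.weeks[0], *[e.x_hat for e in inflections], series.weeks[-1]]
    return [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]
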