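"""Synthetic data with planted ground truth for every pipeline stage.

Three generators emulate the study's raw material without any download:

* :func:`generate_abundance` — a metabolite x sample intensity matrix for
  three ordered age groups, with planted trend types (group-mean shifts in
  log2 space), correlated metabolite modules from a latent-factor model
  (x = loading * z_module + sqrt(1 - loading^2) * noise, so within-module
  correlation is loading^2), and optional hub metabolites that load on a
  factor shared by several modules;
* :func:`generate_survival` — per-individual death weeks from a discrete
  weekly hazard that rises exponentially (Gompertz a*exp(b*t)) until a
  plateau week and stays constant afterwards (late-life mortality
  deceleration);
* :func:`generate_fiber_areas` — fiber cross-sectional areas from a
  lognormal mixture.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mortality import SurvivalData
from .tables import AbundanceTable, make_sample_frame
from .trends import TREND_TYPES

__all__ = [
    "TrendSpec",
    "ModuleSpec",
    "HubSpec",
    "SurvivalSpec",
    "trend_pattern",
    "default_trend_mixture",
    "generate_abundance",
    "generate_survival",
    "expected_log10_cumulative_mortality",
    "generate_fiber_areas",
]

DEFAULT_GROUPS = ("22wk", "37wk", "52wk")


@dataclass
class TrendSpec:
    """Planted trend for one metabolite, in log2 units."""

    trend_type: str = "no_change"
    base_log2_mean: float = 20.0  # ~1e6 raw intensity, typical LC-MS peak
    effect_size: float = 2.0
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.trend_type not in TREND_TYPES:
            raise ValueError(f"unknown trend type {self.trend_type!r}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass
class ModuleSpec:
    """Correlated metabolite block; pairwise correlation ~ loading^2."""

    size: int
    loading: float = 0.9
    hub_count: int = 0  # hubs on this module's own factor

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("module size must be >= 2")
        if not 0 < self.loading < 1:
            raise ValueError("loading must lie in (0, 1)")
        if self.hub_count < 0:
            raise ValueError("hub_count must be >= 0")


@dataclass
class HubSpec:
    """Hub metabolite loading on a factor shared by several modules.

    The listed modules are made mutually correlated through a common group
    factor (inter-module factor correlation = ``group_correlation``); the
    hub loads on the normalized mean of its spanned modules' factors, so
    its correlation with each module factor is
    ``sqrt((1 + (k-1)*rho) / k)`` for k spanned modules — e.g. 0.913 for
    k = 3, rho = 0.75, putting hub-member correlations around 0.8.
    Orthogonal module factors cannot achieve this for more than one
    module (the mean of k independent factors correlates with each at
    only 1/sqrt(k)), which is why the group factor exists.
    """

    modules: tuple
    loading: float = 0.98
    group_correlation: float = 0.75

    def __post_init__(self) -> None:
        if len(self.modules) < 1:
            raise ValueError("a hub must span at least one module")
        if not 0 < self.loading <= 1:
            raise ValueError("hub loading must lie in (0, 1]")
        if not 0 < self.group_correlation <= 1:
            raise ValueError("group_correlation must lie in (0, 1]")


# trend-type mean patterns in units of the effect size
_PATTERNS = {
    "no_change": (0.0, 0.0, 0.0),
    "up_early": (0.0, 1.0, 1.0),
    "up_late": (0.0, 0.0, 1.0),
    "up_both": (0.0, 1.0, 2.0),
    "up_gradual": (0.0, 0.5, 1.0),
    "bell_early": (0.0, 1.0, 0.5),
    "bell_late": (0.5, 1.0, 0.0),
    "bell_both": (0.0, 1.0, 0.0),
    "bell_gradual": (0.0, 0.5, -0.5),
}
_PATTERNS.update(
    {
        t.replace("up_", "down_"): tuple(-v for v in _PATTERNS[t])
        for t in list(_PATTERNS)
        if t.startswith("up_")
    }
)
_PATTERNS.update(
    {
        t.replace("bell_", "u_shape_"): tuple(-v for v in _PATTERNS[t])
        for t in list(_PATTERNS)
        if t.startswith("bell_")
    }
)


def trend_pattern(trend_type: str, effect_size: float) -> np.ndarray:
    """Group-mean offsets (log2) for a trend type at a given effect size."""
    return effect_size * np.asarray(_PATTERNS[trend_type])


def default_trend_mixture(
    n_metabolites: int,
    effect_size: float = 2.0,
    noise_sd: float = 0.3,
    base_log2_mean: float = 20.0,
    proportions: dict | None = None,
) -> list:
    """Trend specs following the published trend-group proportions.

    72.1% no-change and 12.8% bell-shaped are the two printed fractions;
    the remaining 15.1% is split evenly across up, down and U-shape.
    Non-null groups plant their ``_both`` subtype.
    """
    if proportions is None:
        rest = (1.0 - 0.721 - 0.128) / 3.0
        proportions = {
            "no_change": 0.721,
            "bell_both": 0.128,
            "up_both": rest,
            "down_both": rest,
            "u_shape_both": rest,
        }
    items = list(proportions.items())
    raw = np.array([p for _, p in items]) * n_metabolites
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for i in np.argsort(-remainder)[: n_metabolites - counts.sum()]:
        counts[i] += 1
    specs = []
    for (t, _), c in zip(items, counts):
        specs.extend(
            TrendSpec(t, base_log2_mean, effect_size, noise_sd) for _ in range(c)
        )
    return specs


def generate_abundance(
    specs,
    groups=DEFAULT_GROUPS,
    n_per_group: int = 7,
    modules=(),
    hubs=(),
    seed: int = 0,
):
    """Simulate an abundance table with planted trends and modules.

    Module membership is assigned to the leading metabolites in spec
    order (module 0 first).  Hub metabolites are appended after the
    regular specs with a flat (no-change) profile.  Intensities are
    2^(base + trend offset + correlated log2 noise).

    Returns ``(table, truth)``; ``truth`` records the planted trend type,
    trend group, module index (-1 for none) and hub status per metabolite.
    """
    specs = list(specs)
    modules = list(modules)
    hubs = list(hubs)
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3 for Tukey degrees of freedom")
    if len(groups) != 3:
        raise ValueError("exactly 3 ordered groups are required")
    if sum(m.size for m in modules) > len(specs):
        raise ValueError("module sizes exceed the number of metabolites")

    rng = np.random.default_rng(seed)
    n_samples = 3 * n_per_group
    group_of_sample = np.repeat(np.arange(3), n_per_group)

    # group factors shared by hub-spanned modules
    hub_groups = []  # (hub index, group factor)
    module_parent = {}  # module index -> (hub group idx)
    for h_idx, hub in enumerate(hubs):
        g = rng.normal(size=n_samples)
        hub_groups.append(g)
        for m_idx in hub.modules:
            if not 0 <= m_idx < len(modules):
                raise ValueError(f"hub references unknown module {m_idx}")
            module_parent[m_idx] = h_idx

    factors = np.empty((len(modules), n_samples))
    for m_idx, mod in enumerate(modules):
        eta = rng.normal(size=n_samples)
        if m_idx in module_parent:
            rho = hubs[module_parent[m_idx]].group_correlation
            g = hub_groups[module_parent[m_idx]]
            factors[m_idx] = np.sqrt(rho) * g + np.sqrt(1 - rho) * eta
        else:
            factors[m_idx] = eta

    module_of = np.full(len(specs), -1)
    pos = 0
    for m_idx, mod in enumerate(modules):
        module_of[pos : pos + mod.size] = m_idx
        pos += mod.size

    eps = rng.normal(size=(len(specs), n_samples))
    log2 = np.empty((len(specs), n_samples))
    for i, spec in enumerate(specs):
        offsets = trend_pattern(spec.trend_type, spec.effect_size)[group_of_sample]
        m_idx = module_of[i]
        if m_idx >= 0:
            lam = modules[m_idx].loading
            noise = lam * factors[m_idx] + np.sqrt(1 - lam**2) * eps[i]
        else:
            noise = eps[i]
        log2[i] = spec.base_log2_mean + offsets + spec.noise_sd * noise

    # hubs on single-module factors (ModuleSpec.hub_count), then HubSpec hubs
    hub_rows = []
    hub_labels = []
    for m_idx, mod in enumerate(modules):
        for j in range(mod.hub_count):
            lam = 0.98
            row = lam * factors[m_idx] + np.sqrt(1 - lam**2) * rng.normal(size=n_samples)
            hub_rows.append(row)
            hub_labels.append(m_idx)
    for h_idx, hub in enumerate(hubs):
        k = len(hub.modules)
        rho = hub.group_correlation
        shared = factors[list(hub.modules)].sum(axis=0) / np.sqrt(
            k + k * (k - 1) * rho
        )
        row = hub.loading * shared + np.sqrt(1 - hub.loading**2) * rng.normal(
            size=n_samples
        )
        hub_rows.append(row)
        hub_labels.append(-1)

    base = specs[0].base_log2_mean if specs else 20.0
    sd = specs[0].noise_sd if specs else 0.3
    for row in hub_rows:
        log2 = np.vstack([log2, base + sd * row])

    n_total = len(specs) + len(hub_rows)
    width = max(4, len(str(n_total)))
    ids = [f"M{i + 1:0{width}d}" for i in range(n_total)]
    sample_ids = [f"{groups[g]}_r{r + 1}" for g in range(3) for r in range(n_per_group)]

    values = pd.DataFrame(
        np.exp2(log2), index=pd.Index(ids, name="metabolite_id"), columns=sample_ids
    )
    metabolites = pd.DataFrame(
        {"putative_name": ids, "confidence": np.full(n_total, 8.0)},
        index=values.index,
    )
    samples = make_sample_frame(
        sample_ids, [groups[g] for g in group_of_sample], group_order=list(groups)
    )
    table = AbundanceTable(values, metabolites, samples, scale="raw")

    truth = pd.DataFrame(
        {
            "trend_type": [s.trend_type for s in specs] + ["no_change"] * len(hub_rows),
            "trend_group": [
                s.trend_type.rsplit("_", 1)[0] if s.trend_type != "no_change" else "no_change"
                for s in specs
            ]
            + ["no_change"] * len(hub_rows),
            "module": np.concatenate([module_of, np.asarray(hub_labels, int)])
            if n_total
            else np.empty(0, int),
            "is_hub": [False] * len(specs) + [True] * len(hub_rows),
        },
        index=values.index,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalSpec:
    """Gompertz-plateau cohort: h(t) = a*exp(b*t) before the plateau week,
    constant ``plateau_hazard`` afterwards.

    The default plateau hazard of 0.1/week reflects a decelerated
    late-life mortality level: survivors at plateau onset dying out over
    roughly a dozen weeks, as in short-lived killifish cohorts.
    """

    n: int = 39
    gompertz_a: float = 1e-4
    gompertz_b: float = 0.2
    plateau_week: float = 45.0
    plateau_hazard: float = 0.1
    seed: int = 0
    max_week: int = 520  # censoring horizon for (near-)immortal plateaus

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if self.gompertz_a <= 0 or self.gompertz_b <= 0:
            raise ValueError("Gompertz parameters must be positive")
        if self.plateau_week <= 0:
            raise ValueError("plateau_week must be positive")
        if self.plateau_hazard < 0:
            raise ValueError("plateau_hazard must be >= 0")

    def hazard(self, t):
        t = np.asarray(t, float)
        return np.where(
            t < self.plateau_week,
            self.gompertz_a * np.exp(self.gompertz_b * t),
            self.plateau_hazard,
        )

    def cumulative_hazard(self, t):
        t = np.asarray(t, float)
        a, b, pw = self.gompertz_a, self.gompertz_b, self.plateau_week
        gomp = a / b * (np.exp(b * np.minimum(t, pw)) - 1)
        return gomp + self.plateau_hazard * np.maximum(t - pw, 0.0)


def generate_survival(spec: SurvivalSpec) -> SurvivalData:
    """Discrete weekly cohort simulation under the Gompertz-plateau hazard.

    Each animal alive at the start of week t dies during it with
    probability 1 - exp(-(H(t) - H(t-1))).  Animals still alive at the
    censoring horizon are censored there.
    """
    rng = np.random.default_rng(spec.seed)
    alive = spec.n
    deaths = []
    t = 0
    while alive > 0 and t < spec.max_week:
        t += 1
        p = 1.0 - np.exp(-(spec.cumulative_hazard(t) - spec.cumulative_hazard(t - 1)))
        d = rng.binomial(alive, p)
        deaths.extend([t] * int(d))
        alive -= d
    censor = [spec.max_week] * alive
    return SurvivalData.from_death_weeks(deaths, censor_weeks=censor, N=spec.n)


def expected_log10_cumulative_mortality(spec: SurvivalSpec, weeks):
    """Closed-form log10 M(t) = log10(1 - exp(-H(t))) for noise-free checks."""
    weeks = np.asarray(weeks, float)
    M = 1.0 - np.exp(-spec.cumulative_hazard(weeks))
    out = np.full_like(M, np.nan)
    pos = M > 0
    out[pos] = np.log10(M[pos])
    return out


# ---------------------------------------------------------------------------
# Fiber areas
# ---------------------------------------------------------------------------


def generate_fiber_areas(n: int, components=((1.0, 800.0, 0.4),), seed: int = 0):
    """Lognormal-mixture fiber cross-sectional areas in um^2.

    ``components`` is a sequence of ``(weight, median_um2, sigma_log)``
    triples; weights must sum to 1 and parameters must be positive.
    """
    comps = [tuple(map(float, c)) for c in components]
    weights = np.array([c[0] for c in comps])
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("component weights must sum to 1")
    for w, med, sig in comps:
        if w <= 0 or med <= 0 or sig <= 0:
            raise ValueError("mixture parameters must be positive")
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    which = rng.choice(len(comps), size=n, p=weights)
    mu = np.log([c[1] for c in comps])
    sigma = np.array([c[2] for c in comps])
    return np.exp(mu[which] + sigma[which] * rng.normal(size=n))
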