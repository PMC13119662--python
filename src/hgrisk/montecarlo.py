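"""Probabilistic exposure engine: Monte Carlo THQ and HI.

Per iteration, the muscle concentration C is one draw from the
species-specific empirical bootstrap (uniform resampling with replacement
of the observed values, preserving skewness and tails without a parametric
form) and the weekly intake IR is one draw from a triangular distribution
Tri(50, 140, 350) g/week via its inverse CDF; body weight is fixed per
consumer group.  C and IR are sampled independently, from two uniform
streams of a single seeded generator, as a transparent baseline.  Each
iteration's THQ goes through the same arithmetic as the deterministic
engine; runs are summarised by the median (P50), the 95th percentile (P95,
linear interpolation between order statistics) and the exceedance
probability P(THQ > 1).

The triangular CDF/inverse-CDF here are closed forms, so degenerate
configurations (a single observed concentration, a collapsed intake
distribution) reproduce the deterministic engine exactly and analytic
survival probabilities bound the Monte Carlo error — used as the module's
correctness oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import defaults
from .risk import ConsumerGroup, DEFAULT_GROUPS, DietBasket, ToxReference, \
    compute_thq
from .survey import Survey

__all__ = [
    "TriangularIntake",
    "McConfig",
    "McSummary",
    "triangular_inverse_cdf",
    "triangular_cdf",
    "triangular_sf",
    "bootstrap_concentration",
    "run_mc_thq",
    "run_mc_hi",
    "mc_risk_table",
]


@dataclass(frozen=True)
class TriangularIntake:
    """Weekly fish-intake distribution Tri(min, mode, max), g/week."""

    a_g_week: float = defaults.TRI_MIN_G_WEEK
    c_g_week: float = defaults.TRI_MODE_G_WEEK
    b_g_week: float = defaults.TRI_MAX_G_WEEK

    def __post_init__(self) -> None:
        if not (self.a_g_week <= self.c_g_week <= self.b_g_week):
            raise ValueError("triangular parameters need a <= c <= b")

    @property
    def degenerate(self) -> bool:
        return self.a_g_week == self.b_g_week


@dataclass(frozen=True)
class McConfig:
    """Monte Carlo settings: iterations, seed, intake model, groups, tox."""

    n_iter: int = defaults.MC_N_ITER
    seed: int = 0
    intake: TriangularIntake = field(default_factory=TriangularIntake)
    groups: tuple[ConsumerGroup, ...] = DEFAULT_GROUPS
    tox: ToxReference = field(default_factory=ToxReference)

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass(frozen=True)
class McSummary:
    """P50 / P95 / exceedance summary of one simulated THQ (or HI) run."""

    species: str
    group: str
    p50: float
    p95: float
    p_exceed: float
    n_iter: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_exceed <= 1.0):
            raise ValueError("exceedance probability outside [0, 1]")
        if self.p50 > self.p95 + 1e-12:
            raise ValueError("P50 cannot exceed P95")


def triangular_inverse_cdf(u, tri: TriangularIntake):
    """Quantile function of Tri(a, c, b); accepts scalars or arrays.

    For u <= (c-a)/(b-a): a + sqrt(u (b-a)(c-a)); otherwise
    b - sqrt((1-u)(b-a)(b-c)).  Output lies in [a, b].
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any((u_arr < 0) | (u_arr > 1)):
        raise ValueError("u must lie in [0, 1]")
    a, c, b = tri.a_g_week, tri.c_g_week, tri.b_g_week
    if tri.degenerate:
        out = np.full_like(u_arr, a)
        return float(out) if np.isscalar(u) else out
    f_c = (c - a) / (b - a)
    left = a + np.sqrt(u_arr * (b - a) * (c - a))
    right = b - np.sqrt((1.0 - u_arr) * (b - a) * (b - c))
    out = np.where(u_arr <= f_c, left, right)
    if np.isscalar(u):
        return float(out)
    return out


def triangular_cdf(x: float, tri: TriangularIntake) -> float:
    """Exact CDF of Tri(a, c, b), clamped outside the support."""
    a, c, b = tri.a_g_week, tri.c_g_week, tri.b_g_week
    if x <= a:
        return 0.0
    if x >= b:
        return 1.0
    if tri.degenerate:
        return 1.0
    if x <= c:
        return (x - a) ** 2 / ((b - a) * (c - a)) if c > a else 1.0
    return 1.0 - (b - x) ** 2 / ((b - a) * (b - c))


def triangular_sf(x: float, tri: TriangularIntake) -> float:
    """Survival function 1 - CDF of Tri(a, c, b)."""
    return 1.0 - triangular_cdf(x, tri)


def bootstrap_concentration(muscle_values, rng: np.random.Generator,
                            size: int | None = None):
    """Empirical bootstrap draw(s) from a species' observed muscle values.

    One value is drawn uniformly with replacement per request, via a
    uniform variate so that the generator consumes one stream position per
    draw; the support of the draws equals the support of the input.
    """
    x = np.asarray(muscle_values, dtype=float)
    if x.size == 0:
        raise ValueError("empty concentration sample")
    n = 1 if size is None else size
    idx = np.minimum((rng.random(n) * x.size).astype(np.int64), x.size - 1)
    draws = x[idx]
    return float(draws[0]) if size is None else draws


def _summarise(thq: np.ndarray, species: str, group: str, n_iter: int,
               seed: int) -> McSummary:
    return McSummary(
        species=species,
        group=group,
        p50=float(np.percentile(thq, 50)),
        p95=float(np.percentile(thq, 95)),
        p_exceed=float(np.mean(thq > 1.0)),
        n_iter=n_iter,
        seed=seed,
    )


def run_mc_thq(muscle_values, group: ConsumerGroup, config: McConfig, *,
               species: str = "", return_draws: bool = False):
    """Monte Carlo THQ for one species x consumer group.

    Per iteration: C by empirical bootstrap, IR by triangular inverse CDF,
    THQ by the deterministic arithmetic with fixed BW.  Deterministic given
    the config seed.  Returns an :class:`McSummary`, or ``(summary,
    draws)`` with ``return_draws=True``.
    """
    x = np.asarray(muscle_values, dtype=float)
    if x.size == 0:
        raise ValueError("empty concentration sample")
    rng = np.random.default_rng(config.seed)
    c = bootstrap_concentration(x, rng, size=config.n_iter)
    ir = triangular_inverse_cdf(rng.random(config.n_iter), config.intake)
    thq = np.array([
        compute_thq(ci, iri, group.bw_kg, config.tox.rfd_mg_kg_day)
        for ci, iri in zip(c, ir)
    ])
    summary = _summarise(thq, species, group.name, config.n_iter,
                         config.seed)
    return (summary, thq) if return_draws else summary


def run_mc_hi(basket: DietBasket, samples: dict[str, np.ndarray],
              group: ConsumerGroup, config: McConfig, *,
              return_draws: bool = False):
    """Monte Carlo hazard index for a multi-species diet basket.

    One shared weekly-intake draw per iteration is split by the basket
    shares; concentrations are bootstrapped independently per species; the
    per-iteration HI is the sum of the species THQ terms.  Summarised with
    P(HI > 1) in the ``p_exceed`` slot.
    """
    missing = [s for s in basket.shares if s not in samples]
    if missing:
        raise KeyError(f"no concentration sample for: {missing}")
    rng = np.random.default_rng(config.seed)
    species_conc = {}
    for sp in basket.shares:  # fixed basket order -> deterministic stream
        species_conc[sp] = bootstrap_concentration(
            np.asarray(samples[sp], dtype=float), rng, size=config.n_iter)
    ir_total = triangular_inverse_cdf(rng.random(config.n_iter),
                                      config.intake)
    hi = np.zeros(config.n_iter)
    for sp, share in basket.shares.items():
        if share == 0.0:
            continue
        ir_sp = share * ir_total
        hi += np.array([
            compute_thq(ci, iri, group.bw_kg, config.tox.rfd_mg_kg_day)
            for ci, iri in zip(species_conc[sp], ir_sp)
        ])
    label = "+".join(sorted(basket.shares))
    summary = _summarise(hi, label, group.name, config.n_iter, config.seed)
    return (summary, hi) if return_draws else summary


def mc_risk_table(survey: Survey, config: McConfig, *,
                  size_class_species: dict[str, str] | None = None
                  ) -> pd.DataFrame:
    """Probabilistic summary table, one row per species x consumer group.

    Columns: species, group, p50, p95, p_exceed_pct (in percent), n_iter,
    seed.  Each species x group run uses a sub-seed spawned deterministically
    from the config seed so rows are independent but reproducible.
    """
    rows = []
    seq = np.random.SeedSequence(config.seed)
    species = survey.species_list()
    children = seq.spawn(len(species) * len(config.groups))
    i = 0
    for sp in species:
        muscle = survey.muscle_values(sp)
        for grp in config.groups:
            sub = McConfig(
                n_iter=config.n_iter,
                seed=int(children[i].generate_state(1)[0] % (2 ** 31)),
                intake=config.intake, groups=config.groups, tox=config.tox)
            i += 1
            s = run_mc_thq(muscle, grp, sub, species=sp)
            rows.append({
                "species": sp, "group": grp.name,
                "p50": round(s.p50, 3), "p95": round(s.p95, 3),
                "p_exceed_pct": round(100.0 * s.p_exceed, 1),
                "n_iter": s.n_iter, "seed": s.seed,
            })
    return pd.DataFrame(rows)


def critical_intake_g_week(c_mg_kg: float, bw_kg: float,
                           rfd_mg_kg_day: float = defaults.RFD_MG_KG_DAY
                           ) -> float:
    """Weekly intake at which THQ reaches 1 for a fixed concentration.

    THQ > 1 iff IR > 7000 * BW * RfD / C (g/week); with the closed-form
    triangular survival function this yields the analytic exceedance
    probability used to validate the simulation.
    """
    return (defaults.DAYS_PER_WEEK * 1000.0 * bw_kg
            * rfd_mg_kg_day / c_mg_kg)
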