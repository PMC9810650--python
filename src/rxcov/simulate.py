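"""Noise-injection simulation framework.

Emulates a two-group immunoassay experiment: clean analyte signals s_X and
s_Y are drawn once per scenario, then observed data are formed as

    d_X = s_X + gamma * n_X,    d_Y = s_Y + gamma * n_Y

where n are draws from a base noise law and gamma scales the noise
severity.  Each measurement is drawn twice with independent noise (the two
simulated aliquots), so the assay noise variable per sample is
N = gamma * |n - n'|.  Sweeping gamma traces how the rxCOV fidelity metric
and the between-group p-value degrade as noise grows; the gamma at which
rxCOV crosses zero (gamma*) is the experiment-specific low-fidelity
threshold, and any statistical significance beyond it is spurious.

Averaging R independent replicates shrinks the effective noise standard
deviation by 1/sqrt(R), so gamma* shifts right roughly proportionally to
sqrt(R) — the basis of the replicate-sufficiency analysis.

This module doubles as the package's synthetic-data generator: the
canonical scenario (two normal signal groups whose clean difference is
statistically significant, plus two slightly different noise laws) defines
the study conditions used throughout the tests and docs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConfigError,
    DegenerateStatisticError,
    DomainError,
    InsufficientDataError,
    ValidationError,
)
from .metric import (
    combine_noise,
    noise_from_repeats,
    paired_differential,
    rxcov,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DistributionSpec",
    "Scenario",
    "ScenarioDraw",
    "GammaScan",
    "ReplicateStudy",
    "canonical_scenario",
    "generate_scenario",
    "apply_noise",
    "simulate_aliquot_pair",
    "pvalue_two_group",
    "gamma_scan",
    "find_zero_crossing",
    "find_significance_crossing",
    "replicate_study",
    "replicate_sufficiency",
]


# ---------------------------------------------------------------------------
# scenario definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """A one-dimensional sampling law for signals or base noise."""

    family: Literal["normal", "lognormal"]
    loc: float
    scale: float

    def __post_init__(self):
        if self.family not in ("normal", "lognormal"):
            raise ConfigError(f"unsupported distribution family {self.family!r}")
        if self.scale < 0:
            raise ConfigError(f"scale must be >= 0, got {self.scale!r}")

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.family == "normal":
            return rng.normal(self.loc, self.scale, size)
        return rng.lognormal(self.loc, self.scale, size)


@dataclass(frozen=True)
class Scenario:
    """Two-group simulation scenario: signal and base-noise laws plus seed."""

    n_per_group: int
    dist_sx: DistributionSpec
    dist_sy: DistributionSpec
    dist_noise_x: DistributionSpec
    dist_noise_y: DistributionSpec
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 3:
            raise ConfigError(
                f"n_per_group must be >= 3, got {self.n_per_group}"
            )


def canonical_scenario(
    noise_scenario: int = 1, n_per_group: int = 12, seed: int = 0
) -> Scenario:
    """The package's default two-group cytokine-like scenario.

    Clean signals: s_X ~ Normal(10, 2), s_Y ~ Normal(12.5, 2) — a
    between-group shift that is statistically significant at typical group
    sizes.  Base noise: scenario 1 is zero-mean unit normal; scenario 2 is
    Normal(0.2, 1.1), a slightly biased and wider assay-noise law.
    """
    if noise_scenario == 1:
        noise = DistributionSpec("normal", 0.0, 1.0)
    elif noise_scenario == 2:
        noise = DistributionSpec("normal", 0.2, 1.1)
    else:
        raise ConfigError(f"noise_scenario must be 1 or 2, got {noise_scenario}")
    return Scenario(
        n_per_group=n_per_group,
        dist_sx=DistributionSpec("normal", 10.0, 2.0),
        dist_sy=DistributionSpec("normal", 12.5, 2.0),
        dist_noise_x=noise,
        dist_noise_y=noise,
        seed=seed,
    )


@dataclass
class ScenarioDraw:
    """Realized clean signals plus a seeded stream of base-noise draws."""

    s_x: np.ndarray
    s_y: np.ndarray
    noise_x: Callable[[], np.ndarray]
    noise_y: Callable[[], np.ndarray]
    n_clipped: int = 0


def generate_scenario(scenario: Scenario) -> ScenarioDraw:
    """Draw the clean signals once and build i.i.d. base-noise samplers.

    Signals are clipped at 0 (expression is ratio-scale); clip events are
    logged.  Deterministic under a fixed scenario seed: the signal draw and
    the noise stream use independent child seeds so that consuming more
    noise (e.g. more replicates) never perturbs the signals.
    """
    ss = np.random.SeedSequence(scenario.seed)
    sig_seed, noise_seed = ss.spawn(2)
    sig_rng = np.random.default_rng(sig_seed)
    noise_rng = np.random.default_rng(noise_seed)
    n = scenario.n_per_group
    s_x = scenario.dist_sx.sample(sig_rng, n)
    s_y = scenario.dist_sy.sample(sig_rng, n)
    n_clipped = int((s_x < 0).sum() + (s_y < 0).sum())
    if n_clipped:
        logger.warning("clipped %d negative clean-signal draws to 0", n_clipped)
    s_x = np.clip(s_x, 0.0, None)
    s_y = np.clip(s_y, 0.0, None)
    return ScenarioDraw(
        s_x=s_x,
        s_y=s_y,
        noise_x=lambda: scenario.dist_noise_x.sample(noise_rng, n),
        noise_y=lambda: scenario.dist_noise_y.sample(noise_rng, n),
        n_clipped=n_clipped,
    )


# ---------------------------------------------------------------------------
# data assembly
# ---------------------------------------------------------------------------

def apply_noise(s: Sequence[float], noise_draw: Sequence[float], gamma: float) -> np.ndarray:
    """Observed data d = s + gamma * n, clipped at 0 (ratio scale)."""
    if gamma < 0:
        raise DomainError(f"gamma must be >= 0, got {gamma!r}")
    s = np.asarray(s, dtype=float)
    nd = np.asarray(noise_draw, dtype=float)
    if s.shape != nd.shape:
        raise ValidationError(
            f"signal and noise shapes differ: {s.shape} vs {nd.shape}"
        )
    d = s + gamma * nd
    n_neg = int((d < 0).sum())
    if n_neg:
        logger.debug("clipped %d negative observations to 0", n_neg)
    return np.clip(d, 0.0, None)


def simulate_aliquot_pair(
    s: Sequence[float],
    gamma: float,
    noise_sampler: Callable[[], np.ndarray],
    r_replicates: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a measurement and its repeat-aliquot measurement.

    Each is the average of ``r_replicates`` independent noisy realizations
    of the same clean signal; the two aliquots use independent noise, so
    their difference isolates assay noise.
    """
    if r_replicates < 1:
        raise ConfigError(f"r_replicates must be >= 1, got {r_replicates!r}")
    s = np.asarray(s, dtype=float)

    def one() -> np.ndarray:
        acc = np.zeros_like(s)
        for _ in range(r_replicates):
            acc += apply_noise(s, noise_sampler(), gamma)
        return acc / r_replicates

    return one(), one()


def pvalue_two_group(
    d_x: Sequence[float],
    d_y: Sequence[float],
    test: Literal["welch_t", "student_t", "mann_whitney"] = "welch_t",
) -> float:
    """Two-sided p-value for a between-group difference in location."""
    d_x = np.asarray(d_x, dtype=float)
    d_y = np.asarray(d_y, dtype=float)
    if d_x.size < 2 or d_y.size < 2:
        raise InsufficientDataError(
            f"each group needs >= 2 values, got {d_x.size} and {d_y.size}"
        )
    if test == "welch_t":
        p = stats.ttest_ind(d_x, d_y, equal_var=False).pvalue
    elif test == "student_t":
        p = stats.ttest_ind(d_x, d_y, equal_var=True).pvalue
    elif test == "mann_whitney":
        p = stats.mannwhitneyu(d_x, d_y, alternative="two-sided").pvalue
    else:
        raise ConfigError(f"unknown test {test!r}")
    return float(p)


# ---------------------------------------------------------------------------
# crossings
# ---------------------------------------------------------------------------

def _valid_points(grid, track):
    g, t = [], []
    for gi, ti in zip(grid, track, strict=True):
        if ti is not None and np.isfinite(ti):
            g.append(float(gi))
            t.append(float(ti))
    if len(g) < 2:
        raise ValidationError("need at least 2 valid points to locate a crossing")
    return g, t


def find_zero_crossing(
    grid: Sequence[float], track: Sequence[float]
) -> tuple[float | None, list[float]]:
    """First downward zero crossing of a track, by linear interpolation.

    Returns ``(gamma_star, later_crossings)``: the first gamma at which the
    track passes from positive to <= 0 (the exact grid point if the track
    hits 0 there), plus any later downward re-crossings as a warning list.
    ``gamma_star`` is None when the track never crosses.
    """
    g, t = _valid_points(grid, track)
    crossings: list[float] = []
    for i in range(len(t) - 1):
        if t[i] > 0 >= t[i + 1]:
            if t[i + 1] == 0:
                crossings.append(g[i + 1])
            else:
                frac = t[i] / (t[i] - t[i + 1])
                crossings.append(g[i] + frac * (g[i + 1] - g[i]))
        elif t[i] == 0 and i == 0 and t[i + 1] < 0:
            crossings.append(g[i])
    if not crossings:
        return None, []
    if len(crossings) > 1:
        logger.warning(
            "track re-crosses zero %d time(s) after the first crossing",
            len(crossings) - 1,
        )
    return crossings[0], crossings[1:]


def find_significance_crossing(
    grid: Sequence[float], pvalues: Sequence[float], alpha: float = 0.05
) -> float | None:
    """First upward crossing of the significance level by the p-value track."""
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha!r}")
    g, p = _valid_points(grid, pvalues)
    for i in range(len(p) - 1):
        if p[i] == alpha:
            return g[i]
        if p[i] < alpha <= p[i + 1]:
            if p[i + 1] == alpha:
                return g[i + 1]
            frac = (alpha - p[i]) / (p[i + 1] - p[i])
            return g[i] + frac * (g[i + 1] - g[i])
    if p and p[-1] == alpha:
        return g[-1]
    return None


# ---------------------------------------------------------------------------
# gamma scan
# ---------------------------------------------------------------------------

@dataclass
class GammaScan:
    """rxCOV and p-value trajectories over a gamma grid.

    ``gamma_star`` is the detected low-fidelity threshold (first downward
    zero crossing of the rxCOV track); ``gamma_sig`` the first upward
    crossing of the p-value track through ``alpha``.  ``spurious_flags``
    marks grid points beyond gamma* whose p-value still claims
    significance — there, significance is a noise artifact regardless of
    how small the p-value is.
    """

    gamma_grid: np.ndarray
    rxcov_track: np.ndarray
    mean_term_track: np.ndarray
    dispersion_term_track: np.ndarray
    pvalue_track: np.ndarray
    status: list[str]
    gamma_star: float | None
    gamma_sig: float | None
    later_crossings: list[float]
    n_replicates: int
    alpha: float
    seed: int
    k_smooth: int = 1

    @property
    def fidelity_flags(self) -> np.ndarray:
        """Per-point verdict: True where rxcov > 0."""
        with np.errstate(invalid="ignore"):
            return self.rxcov_track > 0

    @property
    def beyond_threshold(self) -> np.ndarray:
        """True for grid points past the low-fidelity threshold gamma*."""
        if self.gamma_star is None:
            return np.zeros_like(self.gamma_grid, dtype=bool)
        return self.gamma_grid > self.gamma_star

    @property
    def spurious_flags(self) -> np.ndarray:
        """True where the test reports significance beyond gamma*."""
        with np.errstate(invalid="ignore"):
            significant = self.pvalue_track < self.alpha
        return self.beyond_threshold & significant

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gamma": self.gamma_grid,
                "rxcov": self.rxcov_track,
                "mean_term": self.mean_term_track,
                "dispersion_term": self.dispersion_term_track,
                "pvalue": self.pvalue_track,
                "status": self.status,
                "spurious_significance": self.spurious_flags,
            }
        )

    def plot(self, axes=None):
        """Two stacked panels: rxCOV with its zero line and gamma*, and the
        p-value track with the alpha line."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
        ax0, ax1 = axes
        ax0.plot(self.gamma_grid, self.rxcov_track, marker=".", color="tab:blue")
        ax0.axhline(0.0, color="red", lw=1)
        ax0.set_ylabel("rxCOV")
        ax1.plot(self.gamma_grid, self.pvalue_track, marker=".", color="tab:orange")
        ax1.axhline(self.alpha, color="red", lw=1)
        ax1.set_yscale("log")
        ax1.set_ylabel("p-value")
        ax1.set_xlabel(r"noise scale $\gamma$")
        if self.gamma_star is not None:
            for ax in (ax0, ax1):
                ax.axvline(self.gamma_star, color="black", ls="--", lw=1)
        return axes


def gamma_scan(
    scenario: Scenario,
    gamma_grid: Sequence[float],
    r_replicates: int = 1,
    test: Literal["welch_t", "student_t", "mann_whitney"] = "welch_t",
    alpha: float = 0.05,
    k_smooth: int = 1,
    noise_draws: Literal["redraw", "fixed"] = "redraw",
) -> GammaScan:
    """Sweep the noise scale and record rxCOV and p-value at each gamma.

    The clean signals are drawn once and reused across the whole scan, so
    only the injected noise varies with gamma.  At each gamma the two
    simulated aliquots give per-sample noise |d - d'|, combined across
    groups by elementwise max (group sizes are equal by construction); Z is
    the paired differential |d_X - d_Y|.  ``k_smooth`` > 1 averages the
    tracks over k independent noise realizations per gamma.  With
    ``noise_draws='fixed'`` a single base-noise realization is scaled
    across the grid instead of redrawing, which yields a smooth
    deterministic track.

    gamma = 0 is rejected: without noise the metric's denominators vanish
    and the log-ratio diverges.
    """
    grid = np.asarray(gamma_grid, dtype=float)
    if grid.size < 2:
        raise ValidationError("gamma grid needs at least 2 points")
    if not (np.diff(grid) > 0).all():
        raise ValidationError("gamma grid must be strictly increasing")
    if not (grid > 0).all():
        raise ValidationError("all gamma must be > 0 (the metric diverges at 0)")
    if k_smooth < 1:
        raise ConfigError(f"k_smooth must be >= 1, got {k_smooth!r}")
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha!r}")

    draw = generate_scenario(scenario)

    if noise_draws == "fixed":
        # pre-draw one noise realization per replicate/aliquot slot and
        # scale it across the grid
        fixed = [
            [
                (
                    [draw.noise_x() for _ in range(r_replicates)],
                    [draw.noise_x() for _ in range(r_replicates)],
                ),
                (
                    [draw.noise_y() for _ in range(r_replicates)],
                    [draw.noise_y() for _ in range(r_replicates)],
                ),
            ]
            for _ in range(k_smooth)
        ]
    elif noise_draws != "redraw":
        raise ConfigError(f"noise_draws must be 'redraw' or 'fixed', got {noise_draws!r}")

    rx = np.full(grid.size, np.nan)
    mt = np.full(grid.size, np.nan)
    dt = np.full(grid.size, np.nan)
    pv = np.full(grid.size, np.nan)
    status: list[str] = []

    for gi, gamma in enumerate(grid):
        rx_k, mt_k, dt_k, pv_k = [], [], [], []
        point_status = "ok"
        for k in range(k_smooth):
            if noise_draws == "fixed":
                (nx1, nx2), (ny1, ny2) = fixed[k]
                d_x = np.mean([apply_noise(draw.s_x, n, gamma) for n in nx1], axis=0)
                d_x2 = np.mean([apply_noise(draw.s_x, n, gamma) for n in nx2], axis=0)
                d_y = np.mean([apply_noise(draw.s_y, n, gamma) for n in ny1], axis=0)
                d_y2 = np.mean([apply_noise(draw.s_y, n, gamma) for n in ny2], axis=0)
            else:
                d_x, d_x2 = simulate_aliquot_pair(
                    draw.s_x, gamma, draw.noise_x, r_replicates
                )
                d_y, d_y2 = simulate_aliquot_pair(
                    draw.s_y, gamma, draw.noise_y, r_replicates
                )
            pv_k.append(pvalue_two_group(d_x, d_y, test=test))
            n_x = noise_from_repeats(d_x, d_x2)
            n_y = noise_from_repeats(d_y, d_y2)
            try:
                noise = combine_noise(n_x, n_y, mode="elementwise_max")
                if noise.summary.location == 0:
                    point_status = "noise_free"
                    continue
                diff = paired_differential(d_x, d_y)
                result = rxcov(diff.summary, noise.summary)
            except DegenerateStatisticError as err:
                point_status = f"degenerate:{err.statistic}"
                continue
            rx_k.append(result.rxcov)
            mt_k.append(result.mean_term)
            dt_k.append(result.dispersion_term)
        pv[gi] = float(np.mean(pv_k))
        if rx_k:
            rx[gi] = float(np.mean(rx_k))
            mt[gi] = float(np.mean(mt_k))
            dt[gi] = float(np.mean(dt_k))
            status.append("ok")
        else:
            status.append(point_status)
            logger.warning("gamma=%g: %s (point skipped)", gamma, point_status)

    finite = np.isfinite(rx)
    if finite.sum() >= 2:
        gamma_star, later = find_zero_crossing(grid[finite], rx[finite])
    else:
        gamma_star, later = None, []
    if np.isfinite(pv).sum() >= 2:
        gamma_sig = find_significance_crossing(
            grid[np.isfinite(pv)], pv[np.isfinite(pv)], alpha
        )
    else:
        gamma_sig = None

    return GammaScan(
        gamma_grid=grid,
        rxcov_track=rx,
        mean_term_track=mt,
        dispersion_term_track=dt,
        pvalue_track=pv,
        status=status,
        gamma_star=gamma_star,
        gamma_sig=gamma_sig,
        later_crossings=later,
        n_replicates=r_replicates,
        alpha=alpha,
        seed=scenario.seed,
        k_smooth=k_smooth,
    )


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------

@dataclass
class ReplicateStudy:
    """Gamma scans at several replicate-averaging depths R.

    Averaging R replicates raises the signal-to-noise ratio, so the
    low-fidelity threshold gamma* shifts right (approximately with
    sqrt(R)).
    """

    replicate_counts: list[int]
    scans: dict[int, GammaScan]
    gamma_star_by_r: dict[int, float | None]
    sufficiency: pd.DataFrame  # columns: gamma, r, rxcov, sufficient

    def summary(self) -> str:
        lines = ["replicate-averaging study", "-" * 40]
        for r in self.replicate_counts:
            gs = self.gamma_star_by_r[r]
            lines.append(
                f"R = {r}: gamma* = " + (f"{gs:.4g}" if gs is not None else "none")
            )
        return "\n".join(lines)


def replicate_study(
    scenario: Scenario,
    gamma_grid: Sequence[float],
    replicate_counts: Sequence[int],
    **scan_options,
) -> ReplicateStudy:
    """Run one gamma scan per replicate count under a common seed discipline.

    All scans share the scenario seed, hence the same clean signals; only
    the depth of replicate averaging differs.
    """
    counts = list(replicate_counts)
    if not counts or any(r < 1 for r in counts):
        raise ConfigError("replicate_counts must be a nonempty list of counts >= 1")
    if sorted(counts) != counts:
        raise ConfigError("replicate_counts must be sorted ascending")
    scans: dict[int, GammaScan] = {}
    rows = []
    for r in counts:
        scan = gamma_scan(scenario, gamma_grid, r_replicates=r, **scan_options)
        scans[r] = scan
        for gamma, value in zip(scan.gamma_grid, scan.rxcov_track):
            rows.append(
                {
                    "gamma": gamma,
                    "r": r,
                    "rxcov": value,
                    "sufficient": bool(np.isfinite(value) and value > 0),
                }
            )
    return ReplicateStudy(
        replicate_counts=counts,
        scans=scans,
        gamma_star_by_r={r: scans[r].gamma_star for r in counts},
        sufficiency=pd.DataFrame(rows),
    )


def replicate_sufficiency(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    mode: str = "paired",
    **options,
) -> pd.DataFrame:
    """Smallest replicate-averaging depth at which each analyte gains fidelity.

    The table must carry a ``replicate`` column.  For R = 1..R_max the
    first R replicates are averaged per (sample, analyte, aliquot) and
    rxCOV recomputed; an analyte is sufficiently replicated at the first R
    with rxCOV > 0.  Analytes that never reach fidelity get the verdict
    ``insufficient at max R`` rather than an error.

    Returns a DataFrame with columns analyte, min_sufficient_r, verdict and
    the rxcov value at each tried R.
    """
    from .model import rxcov_per_analyte

    if "replicate" not in table.columns:
        raise ValidationError("replicate_sufficiency requires a 'replicate' column")
    reps = sorted(int(r) for r in table["replicate"].dropna().unique())
    if not reps:
        raise ValidationError("no replicate indices present")
    r_max = max(reps)
    per_r = {}
    for r in range(1, r_max + 1):
        sub = table[table["replicate"] <= r]
        res = rxcov_per_analyte(sub, group_a, group_b, mode=mode, **options)
        per_r[r] = res.set_index("analyte")["rxcov"]
    rows = []
    for analyte in per_r[1].index:
        track = {r: per_r[r].get(analyte, np.nan) for r in per_r}
        min_r = next(
            (r for r, v in track.items() if np.isfinite(v) and v > 0), None
        )
        rows.append(
            {
                "analyte": analyte,
                "min_sufficient_r": min_r,
                "verdict": (
                    "sufficient" if min_r is not None else f"insufficient at max R={r_max}"
                ),
                **{f"rxcov_r{r}": v for r, v in track.items()},
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixture generation (synthetic measurement tables)
# ---------------------------------------------------------------------------

def make_fixture_table(
    scenario: Scenario,
    gamma: float,
    analytes: Sequence[str] = ("A1", "A2", "A3", "A4", "A5", "A6"),
    group_a: str = "G1",
    group_b: str = "G2",
    n_replicates: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Emit a tidy measurement table drawn from the simulation model.

    One independent scenario realization per analyte (clean signals and
    noise), duplicate aliquots per sample, and optional replicate indices —
    exactly the schema the per-analyte screen consumes, so every analysis
    path is testable without external data.
    """
    if gamma < 0:
        raise DomainError(f"gamma must be >= 0, got {gamma!r}")
    base_seed = scenario.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    records = []
    for analyte, child in zip(analytes, ss.spawn(len(analytes))):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        draw = generate_scenario(replace(scenario, seed=sub_seed))
        n = scenario.n_per_group
        for rep in range(1, n_replicates + 1):
            d_x, d_x2 = simulate_aliquot_pair(draw.s_x, gamma, draw.noise_x, 1)
            d_y, d_y2 = simulate_aliquot_pair(draw.s_y, gamma, draw.noise_y, 1)
            for i in range(n):
                sid_a, sid_b = f"{group_a}_S{i + 1:03d}", f"{group_b}_S{i + 1:03d}"
                records.append((sid_a, group_a, analyte, 1, rep, d_x[i]))
                records.append((sid_a, group_a, analyte, 2, rep, d_x2[i]))
                records.append((sid_b, group_b, analyte, 1, rep, d_y[i]))
                records.append((sid_b, group_b, analyte, 2, rep, d_y2[i]))
    df = pd.DataFrame(
        records,
        columns=["sample_id", "group", "analyte", "aliquot", "replicate", "value"],
    )
    if n_replicates == 1:
        df = df.drop(columns="replicate")
    return df
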