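"""The rxCOV analyte-fidelity metric and its building blocks.

An immunoassay compares an analyte's expression between two sample groups.
The measured between-group difference (the differential expression ``Z``)
is only meaningful if its effect size exceeds that of the assay-associated
noise ``N``, which is revealed by re-measuring an aliquot of each sample.
rxCOV quantifies this on a log10 scale:

    rxCOV(Z, N) = log10(mu_Z / mu_N) + log10(sigma_Z / sigma_N)
                = log10( (sigma_Z / mu_N) / (sigma_N / mu_Z) )

i.e. the ratio of two *cross* coefficients of variation, each dispersion
standardized by the other variable's mean.  rxCOV > 0 means the
differential signal dominates the noise (high fidelity); rxCOV <= 0 means
any downstream statistical significance is a noise artifact (low fidelity).

All quantities are ratio-scale: zero expression is well defined, and the
metric is invariant to the measurement unit (multiplying every raw value
by a positive constant leaves rxCOV unchanged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .exceptions import (
    DegenerateStatisticError,
    DomainError,
    InsufficientDataError,
    PairingError,
    ValidationError,
)

Estimator = Literal["moment", "robust"]
NoiseMode = Literal["elementwise_max", "cross_product_max", "single_group"]

__all__ = [
    "EffectSummary",
    "DifferentialExpression",
    "NoiseVariable",
    "RxcovResult",
    "DeltaGrid",
    "summarize",
    "paired_differential",
    "unpaired_differential",
    "noise_from_repeats",
    "combine_noise",
    "relative_change_f",
    "rxcov",
    "rxcov_from_statistics",
    "delta_rxcov",
    "delta_grid",
    "normalize_by_weight",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSummary:
    """Location/dispersion pair summarizing a ratio-scale variable.

    ``moment`` estimation uses the arithmetic mean and the sample standard
    deviation (n-1 denominator); ``robust`` uses the median and the
    interquartile range (Q3 - Q1, linear interpolation between order
    statistics).
    """

    location: float
    dispersion: float
    estimator: Estimator = "moment"
    n: int = 0

    @property
    def is_degenerate(self) -> bool:
        return not (self.location > 0 and self.dispersion > 0)


@dataclass(frozen=True)
class DifferentialExpression:
    """Differential analyte expression Z between two sample groups.

    Paired mode carries the realizations z_i = |x_i - y_i|; unpaired mode
    carries only the summary (location |mu_X - mu_Y|, dispersion
    sqrt(sigma_X^2 + sigma_Y^2)).
    """

    summary: EffectSummary
    mode: Literal["paired", "unpaired"]
    z_values: np.ndarray | None = None


@dataclass(frozen=True)
class NoiseVariable:
    """Assay-associated noise N, the worst case over the two groups.

    Per group, noise realizations are absolute differences between repeat
    aliquot measurements of the same sample; the groups are combined as a
    max — elementwise for aligned groups, over the full cross product for
    unequal group sizes, or one group alone.
    """

    n_values: np.ndarray
    summary: EffectSummary
    combine_mode: NoiseMode


@dataclass(frozen=True)
class RxcovResult:
    """The four statistics, the metric value and the fidelity verdict."""

    mu_z: float
    mu_n: float
    sigma_z: float
    sigma_n: float
    mean_term: float
    dispersion_term: float
    rxcov: float
    fidelity: Literal["high", "low"]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"rxCOV = {self.rxcov:+.4f} ({self.fidelity} fidelity; "
            f"mean term {self.mean_term:+.4f}, "
            f"dispersion term {self.dispersion_term:+.4f})"
        )


@dataclass
class DeltaGrid:
    """ΔrxCOV surface over relative paired-vs-unpaired deviations.

    The unpaired redefinition of Z can only lower the mean
    (Δμ_Z/μ_Z in [-mu_max_dev, 0]) and raise the dispersion
    (Δσ_Z/σ_Z in [0, sigma_max_dev]).
    """

    rel_dmu: np.ndarray
    rel_dsigma: np.ndarray
    surface: np.ndarray  # shape (len(rel_dmu), len(rel_dsigma))
    min_value: float = field(init=False)
    max_value: float = field(init=False)

    def __post_init__(self) -> None:
        self.min_value = float(self.surface.min())
        self.max_value = float(self.surface.max())

    def to_frame(self):
        """Long-format DataFrame with columns rel_dmu, rel_dsigma, delta_rxcov."""
        import pandas as pd

        mm, ss = np.meshgrid(self.rel_dmu, self.rel_dsigma, indexing="ij")
        return pd.DataFrame(
            {
                "rel_dmu": mm.ravel(),
                "rel_dsigma": ss.ravel(),
                "delta_rxcov": self.surface.ravel(),
            }
        )

    def plot(self, ax=None):
        """Heatmap of the surface (relative deviations in percent)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.pcolormesh(
            100 * self.rel_dsigma, 100 * self.rel_dmu, self.surface, shading="auto"
        )
        ax.set_xlabel("relative deviation in dispersion (%)")
        ax.set_ylabel("relative deviation in mean (%)")
        ax.figure.colorbar(im, ax=ax, label=r"$\Delta$rxCOV")
        return ax


# ---------------------------------------------------------------------------
# estimators and variable constructions
# ---------------------------------------------------------------------------

def _as_vector(values: Sequence[float], name: str = "values") -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        bad = np.flatnonzero(~np.isfinite(arr))
        raise ValidationError(
            f"{name} contains non-finite entries at positions {bad.tolist()[:5]}"
        )
    return arr


def summarize(values: Sequence[float], estimator: Estimator = "moment") -> EffectSummary:
    """Summarize a sample with (location, dispersion) under the chosen estimator.

    Parameters
    ----------
    values
        At least two finite observations.
    estimator
        ``moment`` -> (mean, sample sd with n-1 denominator);
        ``robust`` -> (median, IQR with linear interpolation).
    """
    arr = _as_vector(values)
    if arr.size < 2:
        raise InsufficientDataError(
            f"need at least 2 observations for a dispersion statistic, got {arr.size}"
        )
    if estimator == "moment":
        loc = float(arr.mean())
        disp = float(arr.std(ddof=1))
    elif estimator == "robust":
        loc = float(np.median(arr))
        q1, q3 = np.percentile(arr, [25, 75], method="linear")
        disp = float(q3 - q1)
    else:
        raise ValidationError(f"unknown estimator {estimator!r}")
    return EffectSummary(location=loc, dispersion=disp, estimator=estimator, n=arr.size)


def paired_differential(
    x: Sequence[float], y: Sequence[float], estimator: Estimator = "moment"
) -> DifferentialExpression:
    """Z = |X - Y| for sample-aligned measurement vectors."""
    xa, ya = _as_vector(x, "x"), _as_vector(y, "y")
    if xa.size != ya.size:
        raise PairingError(
            f"paired differential requires equal lengths, got {xa.size} and {ya.size}"
        )
    z = np.abs(xa - ya)
    return DifferentialExpression(summary=summarize(z, estimator), mode="paired", z_values=z)


def unpaired_differential(
    summary_x: EffectSummary, summary_y: EffectSummary
) -> DifferentialExpression:
    """Z for unpaired groups: |mu_X - mu_Y| with dispersions added in quadrature.

    The robust analogue (|median difference|, IQRs in quadrature) is an
    extension by analogy with the moment formula.
    """
    if summary_x.estimator != summary_y.estimator:
        raise ValidationError(
            "unpaired differential requires both summaries under the same estimator, "
            f"got {summary_x.estimator!r} and {summary_y.estimator!r}"
        )
    loc = abs(summary_x.location - summary_y.location)
    if loc == 0:
        raise DegenerateStatisticError("mu_z", 0.0)
    disp = math.hypot(summary_x.dispersion, summary_y.dispersion)
    summary = EffectSummary(
        location=loc,
        dispersion=disp,
        estimator=summary_x.estimator,
        n=summary_x.n + summary_y.n,
    )
    return DifferentialExpression(summary=summary, mode="unpaired")


def noise_from_repeats(primary: Sequence[float], repeat: Sequence[float]) -> np.ndarray:
    """Per-sample assay noise: |measurement - repeat aliquot measurement|."""
    pa, ra = _as_vector(primary, "primary"), _as_vector(repeat, "repeat")
    if pa.size != ra.size:
        raise PairingError(
            "aliquot vectors must be sample-aligned with equal lengths, "
            f"got {pa.size} and {ra.size}"
        )
    return np.abs(pa - ra)


def combine_noise(
    nx: Sequence[float],
    ny: Sequence[float] | None,
    mode: NoiseMode = "elementwise_max",
    estimator: Estimator = "moment",
) -> NoiseVariable:
    """Combine the two groups' noise into the worst-case variable N = max(N_X, N_Y).

    ``elementwise_max`` takes the max per aligned sample pair;
    ``cross_product_max`` enumerates max(nx[i], ny[j]) over all i, j —
    exact for the max of independent variables and valid for unequal group
    sizes; ``single_group`` uses one group's noise alone.
    """
    nxa = _as_vector(nx, "nx")
    if nxa.size == 0:
        raise ValidationError("noise vectors must be nonempty")
    if (nxa < 0).any():
        raise ValidationError("noise values must be nonnegative")
    if mode == "single_group":
        values = nxa
    else:
        if ny is None:
            raise ValidationError(f"mode {mode!r} requires both groups' noise")
        nya = _as_vector(ny, "ny")
        if nya.size == 0:
            raise ValidationError("noise vectors must be nonempty")
        if (nya < 0).any():
            raise ValidationError("noise values must be nonnegative")
        if mode == "elementwise_max":
            if nxa.size != nya.size:
                raise PairingError(
                    "elementwise_max requires equal group sizes, "
                    f"got {nxa.size} and {nya.size}"
                )
            values = np.maximum(nxa, nya)
        elif mode == "cross_product_max":
            values = np.maximum.outer(nxa, nya).ravel()
        else:
            raise ValidationError(f"unknown noise mode {mode!r}")
    return NoiseVariable(
        n_values=values, summary=summarize(values, estimator), combine_mode=mode
    )


# ---------------------------------------------------------------------------
# the metric
# ---------------------------------------------------------------------------

def relative_change_f(m_z: float, m_n: float) -> float:
    """Relative change between two effect sizes: log10(M(Z) / M(N)).

    Zero iff the effect sizes agree; positive iff the differential signal's
    exceeds the noise's; strictly increasing in ``m_z`` for fixed ``m_n``.
    """
    if not (m_z > 0):
        raise DomainError(f"effect size of Z must be > 0, got {m_z!r}")
    if not (m_n > 0):
        raise DomainError(f"effect size of N must be > 0, got {m_n!r}")
    return math.log10(m_z / m_n)


def rxcov_from_statistics(
    mu_z: float, mu_n: float, sigma_z: float, sigma_n: float
) -> RxcovResult:
    """Evaluate rxCOV from the four summary statistics directly.

    Raises :class:`DegenerateStatisticError` naming the offending statistic
    if any is not strictly positive; there is no silent epsilon floor —
    perturbing a fidelity metric would defeat its purpose.
    """
    for name, value in (
        ("mu_z", mu_z),
        ("mu_n", mu_n),
        ("sigma_z", sigma_z),
        ("sigma_n", sigma_n),
    ):
        if not (value > 0) or not math.isfinite(value):
            raise DegenerateStatisticError(name, value)
    mean_term = math.log10(mu_z / mu_n)
    dispersion_term = math.log10(sigma_z / sigma_n)
    value = mean_term + dispersion_term
    return RxcovResult(
        mu_z=mu_z,
        mu_n=mu_n,
        sigma_z=sigma_z,
        sigma_n=sigma_n,
        mean_term=mean_term,
        dispersion_term=dispersion_term,
        rxcov=value,
        fidelity="high" if value > 0 else "low",
    )


def rxcov(summary_z: EffectSummary, summary_n: EffectSummary) -> RxcovResult:
    """rxCOV from the summaries of Z and N.

    rxCOV = log10(mu_Z/mu_N) + log10(sigma_Z/sigma_N); high fidelity iff
    the value is strictly positive (a value of exactly 0 is low fidelity:
    signal and noise effect sizes are indistinguishable).
    """
    return rxcov_from_statistics(
        mu_z=summary_z.location,
        mu_n=summary_n.location,
        sigma_z=summary_z.dispersion,
        sigma_n=summary_n.dispersion,
    )


# ---------------------------------------------------------------------------
# paired-vs-unpaired sensitivity
# ---------------------------------------------------------------------------

def delta_rxcov(rel_dmu: float, rel_dsigma: float) -> float:
    """Change in rxCOV under relative deviations of mu_Z and sigma_Z.

    delta = log10(1 + rel_dmu) + log10(1 + rel_dsigma), the exact shift in
    the metric when the paired summaries (mu_Z, sigma_Z) are replaced by the
    unpaired ones; monotonically increasing in each argument.
    """
    if not (1.0 + rel_dmu > 0):
        raise DomainError(f"1 + rel_dmu must be positive, got rel_dmu={rel_dmu!r}")
    if not (1.0 + rel_dsigma > 0):
        raise DomainError(
            f"1 + rel_dsigma must be positive, got rel_dsigma={rel_dsigma!r}"
        )
    return math.log10(1.0 + rel_dmu) + math.log10(1.0 + rel_dsigma)


def delta_grid(
    mu_max_dev: float = 0.5, sigma_max_dev: float = 0.5, step: float = 0.01
) -> DeltaGrid:
    """Evaluate the ΔrxCOV surface over [-mu_max_dev, 0] x [0, sigma_max_dev].

    The sign conventions reflect the paired-to-unpaired transition: the
    unpaired mean can only shrink (Δμ_Z ≤ 0) and the unpaired dispersion can
    only grow (Δσ_Z ≥ 0).
    """
    if not (0 < mu_max_dev < 1):
        raise ValidationError(f"mu_max_dev must be in (0, 1), got {mu_max_dev!r}")
    if not (sigma_max_dev > 0):
        raise ValidationError(f"sigma_max_dev must be > 0, got {sigma_max_dev!r}")
    if not (0 < step <= max(mu_max_dev, sigma_max_dev)):
        raise ValidationError(
            f"step must be positive and no larger than the range, got {step!r}"
        )
    n_mu = int(round(mu_max_dev / step)) + 1
    n_sigma = int(round(sigma_max_dev / step)) + 1
    rel_dmu = np.linspace(-mu_max_dev, 0.0, n_mu)
    rel_dsigma = np.linspace(0.0, sigma_max_dev, n_sigma)
    surface = np.log10(1.0 + rel_dmu)[:, None] + np.log10(1.0 + rel_dsigma)[None, :]
    return DeltaGrid(rel_dmu=rel_dmu, rel_dsigma=rel_dsigma, surface=surface)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def normalize_by_weight(
    values: Sequence[float], weights: Sequence[float]
) -> np.ndarray:
    """Divide each expression value by its sample's tissue weight.

    Removes variation due to specimen size; preserves nonnegativity and the
    ratio scale.
    """
    va, wa = _as_vector(values, "values"), _as_vector(weights, "weights")
    if va.size != wa.size:
        raise ValidationError(
            f"values and weights must align, got {va.size} and {wa.size}"
        )
    if (wa <= 0).any():
        bad = np.flatnonzero(wa <= 0)
        raise ValidationError(
            f"weights must be strictly positive; offending positions {bad.tolist()[:5]}"
        )
    return va / wa
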