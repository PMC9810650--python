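"""Per-analyte fidelity screening over a multiplexed measurement table.

The model/results pair follows the familiar two-object pattern:
:class:`AnalyteFidelity` is constructed from a tidy measurement table and
the analysis options; :meth:`AnalyteFidelity.fit` evaluates rxCOV for every
analyte independently and returns an :class:`AnalyteFidelityResults` that
carries the four summary statistics, the metric, the high/low verdict and a
per-analyte status, with ``summary()``, ``plot()`` and ``to_csv()``.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import DegenerateStatisticError, PairingError, ValidationError
from .metric import (
    Estimator,
    NoiseMode,
    RxcovResult,
    combine_noise,
    noise_from_repeats,
    paired_differential,
    rxcov,
    summarize,
    unpaired_differential,
)

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "analyte",
    "mode",
    "estimator",
    "mu_z",
    "sigma_z",
    "mu_n",
    "sigma_n",
    "mean_term",
    "dispersion_term",
    "rxcov",
    "fidelity",
    "status",
]


def _aliquot_wide(sub: pd.DataFrame) -> pd.DataFrame:
    """Pivot one (group, analyte) block to one row per sample with aliquot
    1 and 2 columns, averaging replicates when a replicate column exists."""
    agg = sub.groupby(["sample_id", "aliquot"])["value"].mean().unstack("aliquot")
    missing = agg.index[agg.isna().any(axis=1)]
    if len(missing) > 0:
        logger.warning(
            "dropping %d sample(s) without both aliquots: %s",
            len(missing),
            list(missing[:5]),
        )
        agg = agg.drop(index=missing)
    return agg.sort_index()


def _analyte_rxcov(
    sub: pd.DataFrame,
    group_a: str,
    group_b: str,
    mode: str,
    estimator: Estimator,
    noise_mode: NoiseMode,
) -> dict:
    """Compute one analyte's result row; degeneracy becomes a status, not
    an exception, so one bad analyte never aborts the batch."""
    wide_a = _aliquot_wide(sub[sub["group"] == group_a])
    wide_b = _aliquot_wide(sub[sub["group"] == group_b])
    row: dict = {"mode": mode, "estimator": estimator}
    if len(wide_a) < 2 or len(wide_b) < 2:
        row["status"] = "insufficient_data"
        return row

    x1, x2 = wide_a[1].to_numpy(), wide_a[2].to_numpy()
    y1, y2 = wide_b[1].to_numpy(), wide_b[2].to_numpy()
    n_x = noise_from_repeats(x1, x2)
    n_y = noise_from_repeats(y1, y2)

    try:
        if mode == "paired":
            if len(x1) != len(y1):
                raise PairingError(
                    f"paired mode requires equal group sizes, got {len(x1)} "
                    f"({group_a}) and {len(y1)} ({group_b})"
                )
            diff = paired_differential(x1, y1, estimator=estimator)
        else:
            diff = unpaired_differential(
                summarize(x1, estimator), summarize(y1, estimator)
            )
        noise = combine_noise(n_x, n_y, mode=noise_mode, estimator=estimator)
        row.update(
            mu_z=diff.summary.location,
            sigma_z=diff.summary.dispersion,
            mu_n=noise.summary.location,
            sigma_n=noise.summary.dispersion,
        )
        if noise.summary.location == 0:
            # every repeat aliquot reproduced exactly: the assay is
            # noise-free and fidelity holds trivially, but the log-ratio
            # itself is undefined
            row["status"] = "noise_free"
            row["fidelity"] = "high"
            return row
        result = rxcov(diff.summary, noise.summary)
    except DegenerateStatisticError as err:
        row["status"] = f"degenerate:{err.statistic}"
        return row
    except PairingError as err:
        row["status"] = f"pairing_error:{err}"
        return row
    row.update(
        mean_term=result.mean_term,
        dispersion_term=result.dispersion_term,
        rxcov=result.rxcov,
        fidelity=result.fidelity,
        status="ok",
    )
    return row


def rxcov_per_analyte(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    mode: str = "paired",
    estimator: Estimator = "moment",
    noise_mode: NoiseMode | None = None,
) -> pd.DataFrame:
    """Evaluate rxCOV independently for every analyte in a tidy table.

    Parameters
    ----------
    table
        Long-format measurements with columns ``sample_id``, ``group``,
        ``analyte``, ``aliquot`` (1 or 2) and ``value``; an optional
        ``replicate`` column is averaged per (sample, aliquot).
    group_a, group_b
        The two group labels to compare.
    mode
        ``paired`` (Z from sample-aligned |x - y|) or ``unpaired``
        (summary-level Z).
    noise_mode
        Defaults to ``elementwise_max`` for paired data and
        ``cross_product_max`` for unpaired data.

    Returns
    -------
    DataFrame
        One row per analyte with the four statistics, the two log terms,
        rxcov, the fidelity verdict and a status; degenerate analytes get
        an explanatory status and NaN statistics.
    """
    groups = set(table["group"].unique())
    for label in (group_a, group_b):
        if label not in groups:
            raise ValidationError(
                f"group label {label!r} not present in table (has {sorted(groups)})"
            )
    if mode not in ("paired", "unpaired"):
        raise ValidationError(f"mode must be 'paired' or 'unpaired', got {mode!r}")
    if noise_mode is None:
        noise_mode = "elementwise_max" if mode == "paired" else "cross_product_max"

    rows = []
    for analyte, sub in table.groupby("analyte", sort=True):
        row = _analyte_rxcov(sub, group_a, group_b, mode, estimator, noise_mode)
        row["analyte"] = analyte
        if row["status"] != "ok":
            logger.warning("analyte %s: %s", analyte, row["status"])
        rows.append(row)
    if not rows:
        raise ValidationError("table contains no analytes")
    out = pd.DataFrame(rows).reindex(columns=RESULT_COLUMNS)
    return out


class AnalyteFidelity:
    """Fidelity screen of multiplexed immunoassay data between two groups.

    Parameters
    ----------
    data
        Tidy measurement table (see :func:`rxcov_per_analyte`); validated
        on construction.
    group_a, group_b
        Labels of the two sample groups being compared.
    mode, estimator, noise_mode
        Analysis options; see :func:`rxcov_per_analyte`.
    normalize_weight
        Divide each value by its ``weight`` column entry (e.g. tissue
        weight) before analysis.

    Examples
    --------
    >>> model = AnalyteFidelity(df, group_a="H", group_b="LS", mode="unpaired")
    >>> res = model.fit()
    >>> print(res.summary())        # doctest: +SKIP
    """

    def __init__(
        self,
        data: pd.DataFrame,
        group_a: str,
        group_b: str,
        mode: str = "paired",
        estimator: Estimator = "moment",
        noise_mode: NoiseMode | None = None,
        normalize_weight: bool = False,
    ):
        from .io import validate_measurements

        self.data = validate_measurements(data, normalize_weight=normalize_weight)
        self.group_a = group_a
        self.group_b = group_b
        self.mode = mode
        self.estimator = estimator
        self.noise_mode = noise_mode

    @classmethod
    def from_csv(cls, path, group_a: str, group_b: str, **options) -> "AnalyteFidelity":
        """Build the model from a long-format measurement CSV."""
        from .io import read_measurements

        normalize = options.pop("normalize_weight", False)
        table = read_measurements(path, normalize_weight=normalize)
        return cls(table, group_a, group_b, **options)

    def fit(self) -> "AnalyteFidelityResults":
        """Compute rxCOV for every analyte and return the results object."""
        table = rxcov_per_analyte(
            self.data,
            self.group_a,
            self.group_b,
            mode=self.mode,
            estimator=self.estimator,
            noise_mode=self.noise_mode,
        )
        return AnalyteFidelityResults(self, table)


class AnalyteFidelityResults:
    """Per-analyte rxCOV estimates and fidelity verdicts.

    Attributes
    ----------
    table : DataFrame
        One row per analyte (statistics, metric, verdict, status).
    """

    def __init__(self, model: AnalyteFidelity, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def results(self) -> Mapping[str, RxcovResult]:
        """Dict of analyte -> RxcovResult for analytes with status ``ok``."""
        out = {}
        for _, r in self.table[self.table["status"] == "ok"].iterrows():
            out[r["analyte"]] = RxcovResult(
                mu_z=r["mu_z"],
                mu_n=r["mu_n"],
                sigma_z=r["sigma_z"],
                sigma_n=r["sigma_n"],
                mean_term=r["mean_term"],
                dispersion_term=r["dispersion_term"],
                rxcov=r["rxcov"],
                fidelity=r["fidelity"],
            )
        return out

    def summary(self) -> str:
        """Plain-text summary table of the screen."""
        m = self.model
        lines = [
            "rxCOV analyte fidelity screen",
            "=" * 64,
            f"groups: {m.group_a} vs {m.group_b}   mode: {m.mode}   "
            f"estimator: {m.estimator}",
            f"analytes: {len(self.table)}   "
            f"high fidelity: {(self.table['fidelity'] == 'high').sum()}   "
            f"low fidelity: {(self.table['fidelity'] == 'low').sum()}",
            "-" * 64,
        ]
        with pd.option_context("display.width", 120, "display.precision", 4):
            lines.append(
                self.table[
                    ["analyte", "mu_z", "sigma_z", "mu_n", "sigma_n", "rxcov",
                     "fidelity", "status"]
                ].to_string(index=False)
            )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        """Write the result table as CSV (floats at 6 significant digits)."""
        from .io import write_result_table

        write_result_table(self.table, path)

    def plot(self, ax=None):
        """Bar plot of rxCOV per analyte, colored by fidelity verdict."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ok = self.table.dropna(subset=["rxcov"])
        colors = np.where(ok["fidelity"] == "high", "tab:blue", "tab:red")
        ax.bar(ok["analyte"], ok["rxcov"], color=colors)
        ax.axhline(0.0, color="black", lw=1)
        ax.set_ylabel("rxCOV")
        ax.set_title("analyte fidelity (blue: high, red: low)")
        return ax
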