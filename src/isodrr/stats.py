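"""Observer-agreement statistics: ICC(A,k), Bland–Altman, summaries.

The agreement analysis follows the cephalometric-validation design: each of
six point-to-point distances is measured on two modalities (real film vs
DRR, or analytic oracle vs image measurement), by k = 4 observers, giving a
12-item x 4-rater matrix.  Inter-observer agreement is the McGraw–Wong
intraclass correlation ICC(A,k) — two-way model, absolute agreement,
average of k raters, the SPSS "mean-rating, absolute-agreement, 2-way
mixed-effects" setting — and inter-modality agreement is Bland–Altman bias
and 95% limits of agreement on the six per-measurement means.

All statistics are computed at full precision; rounding (1 dp for summary
tables, 3 dp for ICC) happens only at report time, and reported mm values
round half away from zero.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .landmarks import round_half_away

logger = logging.getLogger(__name__)


@dataclass
class ObserverMatrix:
    """Items x raters measurement table (mm), with item provenance labels."""

    values: np.ndarray
    measurements: list[str]
    modalities: list[str]
    raters: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError(f"need >= 2 items and >= 2 raters, got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("observer matrix contains missing or non-finite cells")
        if len(self.measurements) != n or len(self.modalities) != n:
            raise ValueError("item label lengths must match the number of rows")
        if len(self.raters) != k:
            raise ValueError("rater label length must match the number of columns")

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_table_csv(cls, path: str | Path) -> "ObserverMatrix":
        """Read the `measurement,modality,obs1..obsK` CSV layout."""
        rows = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise ValueError(f"{path}: empty observer CSV")
            obs_cols = [c for c in reader.fieldnames if c.lower().startswith("obs")]
            if not obs_cols or "measurement" not in reader.fieldnames \
                    or "modality" not in reader.fieldnames:
                raise ValueError(
                    f"{path}: expected columns measurement, modality, obs1..obsK"
                )
            for row in reader:
                rows.append(row)
        if not rows:
            raise ValueError(f"{path}: no measurement rows")
        return cls(
            values=np.array([[float(r[c]) for c in obs_cols] for r in rows]),
            measurements=[r["measurement"] for r in rows],
            modalities=[r["modality"] for r in rows],
            raters=obs_cols,
        )

    def to_table_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["measurement", "modality", *self.raters])
            for meas, mod, row in zip(self.measurements, self.modalities, self.values):
                writer.writerow([meas, mod, *(f"{v:.6f}" for v in row)])
        return path


@dataclass
class AgreementReport:
    """ICC and/or Bland–Altman summary of an agreement analysis."""

    bias_mm: float
    sd_mm: float
    loa_low_mm: float
    loa_high_mm: float
    n_pairs: int
    icc: float | None = None
    icc_ci_low: float | None = None
    icc_ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.sd_mm < 0:
            raise ValueError("sd_mm must be non-negative")
        if not self.loa_low_mm <= self.bias_mm <= self.loa_high_mm:
            raise ValueError("limits of agreement must bracket the bias")


def anova_mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows, columns, error) of an items x raters table."""
    m = np.asarray(values, dtype=float)
    n, k = m.shape
    grand = m.mean()
    msr = k * ((m.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((m.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    resid = m - m.mean(axis=1, keepdims=True) - m.mean(axis=0, keepdims=True) + grand
    mse = (resid ** 2).sum() / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_a_1(m: ObserverMatrix, alpha: float = 0.05) -> tuple[float, float, float]:
    """Single-measure two-way absolute-agreement ICC(A,1) with 95% CI."""
    n, k = m.values.shape
    msr, msc, mse = anova_mean_squares(m.values)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        logger.info("ICC: zero total variance; agreement defined as perfect")
        return 1.0, 1.0, 1.0
    icc = (msr - mse) / denom

    if icc >= 1.0:
        return float(icc), 1.0, 1.0
    # F-based interval with Satterthwaite degrees of freedom
    a = (k * icc) / (n * (1.0 - icc))
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    low = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    high = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return float(icc), float(low), float(high)


def icc_a_k(m: ObserverMatrix, alpha: float = 0.05) -> tuple[float, float, float]:
    """Average-measures two-way absolute-agreement ICC(A,k) with 95% CI.

    Point estimate ``(MS_R - MS_E) / (MS_R + (MS_C - MS_E)/n)``; the
    confidence bounds are the single-measure bounds stepped up with the
    Spearman–Brown relation, as SPSS reports them.
    """
    n, k = m.values.shape
    msr, msc, mse = anova_mean_squares(m.values)
    denom = msr + (msc - mse) / n
    if denom == 0:
        logger.info("ICC: zero total variance; agreement defined as perfect")
        return 1.0, 1.0, 1.0
    icc = (msr - mse) / denom
    _, low1, high1 = icc_a_1(m, alpha=alpha)

    def step_up(r: float) -> float:
        return k * r / (1.0 + (k - 1) * r)

    return float(icc), step_up(low1), step_up(high1)


def bland_altman(pairs: list[tuple[float, float]]) -> AgreementReport:
    """Bland–Altman bias and 95% limits of agreement for paired measures.

    Differences are ``a - b``; bias is their mean, the spread their sample
    standard deviation (n-1), and the limits ``bias ± 1.96 sd`` — all from
    unrounded intermediates.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (a, b) pairs")
    d = arr[:, 0] - arr[:, 1]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementReport(
        bias_mm=bias,
        sd_mm=sd,
        loa_low_mm=bias - 1.96 * sd,
        loa_high_mm=bias + 1.96 * sd,
        n_pairs=len(d),
    )


def summarize_measurements(m: ObserverMatrix) -> tuple[pd.DataFrame, list[tuple[float, float]]]:
    """Per-measurement means/SDs over raters for each modality, plus the
    mean-difference column and the (modality_a, modality_b) mean pairs that
    feed Bland–Altman.

    Items must come in pairs: each measurement present once per modality,
    with exactly two modalities overall.  Returned statistics are full
    precision; display rounding is the caller's concern
    (:func:`format_summary` rounds to 1 dp).
    """
    modalities = list(dict.fromkeys(m.modalities))
    if len(modalities) != 2:
        raise ValueError(f"expected exactly 2 modalities, got {modalities}")
    mod_a, mod_b = modalities
    index: dict[tuple[str, str], np.ndarray] = {}
    for meas, mod, row in zip(m.measurements, m.modalities, m.values):
        key = (meas, mod)
        if key in index:
            raise ValueError(f"duplicate item {key}")
        index[key] = row
    measurements = list(dict.fromkeys(m.measurements))
    rows = []
    pairs = []
    for meas in measurements:
        try:
            ra, rb = index[(meas, mod_a)], index[(meas, mod_b)]
        except KeyError as exc:
            raise ValueError(f"measurement {meas!r} is missing a modality") from exc
        mean_a, mean_b = ra.mean(), rb.mean()
        rows.append({
            "measurement": meas,
            f"{mod_a}_mean": mean_a,
            f"{mod_a}_sd": ra.std(ddof=1),
            f"{mod_b}_mean": mean_b,
            f"{mod_b}_sd": rb.std(ddof=1),
            "diff_of_means": mean_a - mean_b,
        })
        pairs.append((float(mean_a), float(mean_b)))
    return pd.DataFrame(rows).set_index("measurement"), pairs


def format_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Display version of a measurement summary: 1 dp, half away from zero."""
    return summary.map(lambda v: round_half_away(v, 1))


def simulate_observers(
    true_distances: list[float] | np.ndarray,
    k: int = 4,
    sigma_mm: float = 1.5,
    round_to_mm: bool = True,
    seed: int | np.random.Generator = 0,
    measurements: list[str] | None = None,
    modalities: list[str] | None = None,
) -> ObserverMatrix:
    """Seeded observer simulator: true distance + N(0, sigma) per cell.

    Each cell is an independent observer reading; with ``round_to_mm`` the
    readings are recorded to whole millimetres, as humans do with a ruler.
    """
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be non-negative")
    if k < 2:
        raise ValueError("need at least 2 raters")
    true = np.asarray(true_distances, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = true[:, None] + rng.normal(0.0, sigma_mm, size=(true.size, k))
    if round_to_mm:
        values = np.sign(values) * np.floor(np.abs(values) + 0.5)
    n = true.size
    return ObserverMatrix(
        values=values,
        measurements=measurements or [f"item{i}" for i in range(n)],
        modalities=modalities or ["simulated"] * n,
        raters=[f"obs{j + 1}" for j in range(k)],
    )


def load_observer_table() -> ObserverMatrix:
    """The packaged 12-item x 4-observer study matrix."""
    ref = resources.files("isodrr.data") / "observer_measurements.csv"
    with resources.as_file(ref) as p:
        return ObserverMatrix.from_table_csv(p)


def load_mean_pairs() -> tuple[list[str], list[tuple[float, float]]]:
    """The packaged six per-measurement (real, DRR) mean pairs."""
    ref = resources.files("isodrr.data") / "measurement_means.csv"
    names, pairs = [], []
    with resources.as_file(ref) as p, open(p, newline="") as fh:
        for row in csv.DictReader(fh):
            names.append(row["measurement"])
            pairs.append((float(row["real_mean"]), float(row["drr_mean"])))
    return names, pairs


def plot_bland_altman(pairs: list[tuple[float, float]], report: AgreementReport,
                      path: str | Path) -> Path:
    """Mean-vs-difference plot with bias and limits-of-agreement lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = np.asarray(pairs, dtype=float)
    means = arr.mean(axis=1)
    diffs = arr[:, 0] - arr[:, 1]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, color="k", zorder=3)
    ax.axhline(report.bias_mm, color="tab:blue", label=f"bias {report.bias_mm:.2f}")
    for loa in (report.loa_low_mm, report.loa_high_mm):
        ax.axhline(loa, color="tab:red", linestyle="--")
    ax.set_xlabel("mean of paired measurements (mm)")
    ax.set_ylabel("difference (mm)")
    ax.legend(loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
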