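"""Method-agreement statistics for paired volume series.

Two segmentations of the same subjects are compared with (a) ordinary
least-squares regression of the new volumes on the reference volumes,
reporting the adjusted coefficient of determination
``R2_adj = 1 - (1 - r^2) (n - 1) / (n - 2)`` (single-predictor form), and
(b) Bland-Altman analysis: bias = mean(new - ref), sigma = sample SD of the
differences, limits of agreement bias +- 1.96 sigma, and a two-sided
one-sample t-test of the differences against zero (alpha = 0.05).
Mask overlap is quantified with the Dice coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateRegressionError,
    InputError,
    PairingError,
    SampleSizeError,
)

__all__ = [
    "AgreementResult",
    "regress",
    "bland_altman",
    "dice",
    "compare_runs",
    "write_agreement_csv",
]

#: limits-of-agreement multiplier (standard Bland-Altman convention)
LOA_FACTOR = 1.96


@dataclass
class AgreementResult:
    """Regression and Bland-Altman summary for one volume comparison."""

    slope: float
    intercept_l: float
    r2_adj: float
    bias_l: float
    sd_l: float
    loa_low_l: float
    loa_high_l: float
    p_bias: float
    n: int

    def equation(self) -> str:
        sign = "+" if self.intercept_l >= 0 else "-"
        return (
            f"V_new = {self.slope:.3f} * V_ref {sign} {abs(self.intercept_l):.3f} L"
        )


def _paired(ref, new):
    ref = np.asarray(ref, dtype=np.float64).ravel()
    new = np.asarray(new, dtype=np.float64).ravel()
    if ref.shape != new.shape:
        raise InputError("reference and new series must have equal length")
    return ref, new


def regress(ref_volumes, new_volumes) -> tuple[float, float, float]:
    """OLS of new on ref; returns (slope, intercept, adjusted R^2)."""
    ref, new = _paired(ref_volumes, new_volumes)
    n = ref.size
    if n < 3:
        raise SampleSizeError(f"regression needs n >= 3, got {n}")
    if np.ptp(ref) == 0:
        raise DegenerateRegressionError("reference values are constant")
    fit = stats.linregress(ref, new)
    r2 = fit.rvalue**2
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return float(fit.slope), float(fit.intercept), float(r2_adj)


def bland_altman(
    ref_volumes, new_volumes
) -> tuple[float, float, tuple[float, float], float]:
    """Bland-Altman bias, SD, limits of agreement and bias p-value.

    Differences are ``new - ref``; the SD uses the n-1 denominator and the
    limits are bias +- 1.96 SD.  With zero-variance differences the t-test
    is undefined: p is 1 when the bias is also 0, NaN otherwise.
    """
    ref, new = _paired(ref_volumes, new_volumes)
    n = ref.size
    if n < 3:
        raise SampleSizeError(f"Bland-Altman needs n >= 3, got {n}")
    d = new - ref
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    limits = (bias - LOA_FACTOR * sd, bias + LOA_FACTOR * sd)
    if sd == 0.0:
        p = 1.0 if bias == 0.0 else float("nan")
    else:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    return bias, sd, limits, p


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A&B| / (|A| + |B|); two empty masks give 1."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise InputError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def agreement(ref_volumes, new_volumes) -> AgreementResult:
    """Full regression + Bland-Altman summary for one tissue."""
    slope, intercept, r2_adj = regress(ref_volumes, new_volumes)
    bias, sd, (lo, hi), p = bland_altman(ref_volumes, new_volumes)
    return AgreementResult(
        slope=slope,
        intercept_l=intercept,
        r2_adj=r2_adj,
        bias_l=bias,
        sd_l=sd,
        loa_low_l=lo,
        loa_high_l=hi,
        p_bias=p,
        n=int(np.asarray(ref_volumes).size),
    )


def compare_runs(
    report_a: pd.DataFrame,
    report_b: pd.DataFrame,
    plot_dir: str | Path | None = None,
) -> dict[str, AgreementResult]:
    """Subject-level SAT and VAT agreement between two runs.

    Each report is a DataFrame with columns ``source_id``, ``sat_volume_l``,
    ``vat_volume_l`` (one row per subject); ``report_a`` is the reference.
    Subjects are matched by ``source_id``, so row order is irrelevant.
    Optionally writes scatter + Bland-Altman plots per tissue.
    """
    required = {"source_id", "sat_volume_l", "vat_volume_l"}
    for name, df in (("a", report_a), ("b", report_b)):
        missing = required - set(df.columns)
        if missing:
            raise InputError(f"report {name} lacks columns {sorted(missing)}")
    ids_a = set(report_a["source_id"])
    ids_b = set(report_b["source_id"])
    if ids_a != ids_b:
        raise PairingError(
            f"subject sets differ: only in a {sorted(ids_a - ids_b)}, "
            f"only in b {sorted(ids_b - ids_a)}"
        )
    if len(report_a) != len(ids_a) or len(report_b) != len(ids_b):
        raise PairingError("duplicate source_id rows in a report")
    a = report_a.set_index("source_id").sort_index()
    b = report_b.set_index("source_id").sort_index()
    results = {}
    for tissue, column in (("sat", "sat_volume_l"), ("vat", "vat_volume_l")):
        results[tissue] = agreement(a[column].to_numpy(), b[column].to_numpy())
        if plot_dir is not None:
            _agreement_plots(
                a[column].to_numpy(),
                b[column].to_numpy(),
                results[tissue],
                tissue,
                Path(plot_dir),
            )
    return results


def _agreement_plots(ref, new, result: AgreementResult, tissue: str, out: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out.mkdir(parents=True, exist_ok=True)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.scatter(ref, new, s=18)
    xs = np.linspace(min(ref), max(ref), 50)
    ax1.plot(xs, result.slope * xs + result.intercept_l, "r-")
    ax1.set_xlabel("reference volume [L]")
    ax1.set_ylabel("new volume [L]")
    ax1.set_title(f"{tissue.upper()}: {result.equation()}, R2adj={result.r2_adj:.3f}")
    mean = (np.asarray(ref) + np.asarray(new)) / 2
    diff = np.asarray(new) - np.asarray(ref)
    ax2.scatter(mean, diff, s=18)
    for y, style in ((result.bias_l, "r-"), (result.loa_low_l, "k--"),
                     (result.loa_high_l, "k--")):
        ax2.axhline(y, linestyle=style[1:], color=style[0])
    ax2.set_xlabel("mean volume [L]")
    ax2.set_ylabel("difference new - ref [L]")
    ax2.set_title(f"bias={result.bias_l:.3f} L, sd={result.sd_l:.3f} L")
    fig.tight_layout()
    fig.savefig(out / f"agreement_{tissue}.png", dpi=120)
    plt.close(fig)


def write_agreement_csv(
    results: Mapping[str, AgreementResult], path: str | Path
) -> Path:
    """One row per tissue with regression and Bland-Altman columns."""
    rows = []
    for tissue, r in results.items():
        rows.append(
            {
                "tissue": tissue.upper(),
                "equation": r.equation(),
                "slope": r.slope,
                "intercept_l": r.intercept_l,
                "r2_adj": r.r2_adj,
                "sigma_ba_l": r.sd_l,
                "delta_ba_l": r.bias_l,
                "loa_low_l": r.loa_low_l,
                "loa_high_l": r.loa_high_l,
                "p_bias": r.p_bias,
                "n": r.n,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)
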