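"""Test-retest reliability and method-agreement statistics.

Reliability of the repeated (24 h apart) app measurements is quantified by
the single-measure, absolute-agreement intraclass correlation under a
two-way random-effects ANOVA — Shrout & Fleiss ICC(2,1), McGraw & Wong
ICC(A,1) — with an F-distribution 95% confidence interval.  From the ICC,

    SEM = S * sqrt(1 - ICC)          (S = SD of the pooled session scores)
    MDC = SEM * sqrt(2) * 1.96

give the measurement error and the minimal detectable change, both in
degrees.  ICC values are labelled on the Landis-Koch ordinal scale.

Validity of the app against the reference picture uses Pearson's r (with
an ordinal strength label) and Bland-Altman limits of agreement on the
paired app - reference differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union
import warnings

import numpy as np
from scipy import stats

from .errors import (
    InsufficientDataError,
    UndefinedStatisticError,
    ValidationError,
)
from .pose_model import Method, Movement, PROTOCOL_ORDER, StudyTable

MDC_FACTOR = math.sqrt(2.0) * 1.96

# Landis-Koch bands for ICC (lower bound inclusive)
_ICC_BANDS = [
    (0.81, "almost perfect"),
    (0.61, "substantial"),
    (0.41, "moderate"),
    (0.21, "fair"),
    (0.0, "slight"),
]

# correlation-strength bands on |r| (lower bound inclusive)
_R_BANDS = [
    (0.90, "very strong"),
    (0.70, "strong"),
    (0.50, "moderate"),
    (0.30, "weak"),
    (0.0, "very weak"),
]


@dataclass(frozen=True)
class ReliabilityResult:
    movement: Movement
    icc: float
    ci_low: float
    ci_high: float
    s_pooled: float
    sem: float
    mdc: float
    icc_class: str


@dataclass(frozen=True)
class ValidityResult:
    movement: Movement
    r: float
    r_class: str
    bias: float
    loa_low: float
    loa_high: float
    n_outside_loa: int


@dataclass(frozen=True)
class BlandAltman:
    """Paired-difference agreement summary with per-pair values for plotting."""

    bias: float
    loa_low: float
    loa_high: float
    n_outside_loa: int
    sd_diff: float
    diffs: np.ndarray = field(repr=False)
    means: np.ndarray = field(repr=False)


def _anova_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subjects x sessions) ANOVA mean squares for an n x k table:
    rows MSR, columns MSC, residual MSE."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_two_way_random(
    session1: Sequence[float],
    session2: Sequence[float],
    *,
    ci: float = 0.95,
    form: str = "agreement",
) -> tuple[float, float, float]:
    """Two-way random-effects, single-measure ICC of two paired sessions.

    ``form="agreement"`` (default) gives ICC(A,1) = ICC(2,1):

        ICC = (MSR - MSE) / (MSR + MSE + 2 (MSC - MSE) / n)

    with the McGraw-Wong F-distribution confidence interval.
    ``form="consistency"`` gives ICC(C,1) = (MSR - MSE) / (MSR + MSE),
    provided as a sensitivity check.

    Returns ``(icc, ci_low, ci_high)``.
    """
    x1 = np.asarray(session1, dtype=float)
    x2 = np.asarray(session2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValidationError("sessions must be equal-length 1-D score vectors")
    n = x1.size
    if n < 3:
        raise InsufficientDataError(f"ICC needs at least 3 paired subjects, got {n}")
    data = np.column_stack([x1, x2])
    if np.ptp(data) == 0:
        raise UndefinedStatisticError("ICC undefined: all scores identical (zero variance)")
    k = 2
    msr, msc, mse = _anova_mean_squares(data)
    alpha = 1.0 - ci

    if form == "consistency":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0.0:
            return 1.0, 1.0, 1.0
        f_obs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return float(icc), float(lo), float(hi)
    if form != "agreement":
        raise ValidationError(f"unknown ICC form {form!r}")

    icc = (msr - mse) / (msr + mse + 2.0 * (msc - mse) / n)
    if mse == 0.0 and msc == 0.0:
        # sessions agree exactly; the interval degenerates
        return 1.0, 1.0, 1.0
    # McGraw & Wong F-based interval for ICC(A,1)
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else math.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else math.inf
    if not math.isfinite(a):
        return float(icc), float(icc), float(icc)
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num_v / den_v
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return float(icc), float(lo), float(hi)


def sem(scores_both_sessions: Sequence[float], icc: float) -> float:
    """Standard error of measurement, SEM = S * sqrt(1 - ICC).

    ``S`` is the sample SD (denominator 2N-1) of the pooled first- and
    second-session scores.
    """
    if not 0.0 <= icc <= 1.0:
        raise ValidationError(f"icc must be in [0, 1] for SEM, got {icc}")
    s = float(np.std(np.asarray(scores_both_sessions, dtype=float), ddof=1))
    return s * math.sqrt(1.0 - icc)


def mdc(sem_value: float) -> float:
    """Minimal detectable change at 95% confidence, MDC = SEM * sqrt(2) * 1.96."""
    if sem_value < 0:
        raise ValidationError(f"sem must be >= 0, got {sem_value}")
    return sem_value * MDC_FACTOR


def classify_icc(icc: float) -> str:
    """Landis-Koch label for an ICC: almost perfect (>= 0.81), substantial
    (>= 0.61), moderate (>= 0.41), fair (>= 0.21), slight (< 0.21)."""
    if icc < 0:
        warnings.warn(
            f"ICC {icc} is negative; the ordinal scale starts at 0 — labelling 'slight'",
            stacklevel=2,
        )
        return "slight"
    for lower, label in _ICC_BANDS:
        if icc >= lower:
            return label
    return "slight"


def classify_r(r: float) -> str:
    """Correlation-strength label on |r|: very strong (>= 0.90), strong
    (>= 0.70), moderate (>= 0.50), weak (>= 0.30), very weak (< 0.30)."""
    if abs(r) > 1.0:
        raise ValidationError(f"|r| must be <= 1, got {r}")
    for lower, label in _R_BANDS:
        if abs(r) >= lower:
            return label
    return "very weak"


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of paired measurements."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    if xa.size < 3:
        raise InsufficientDataError(f"Pearson r needs n >= 3, got {xa.size}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant input")
    return float(stats.pearsonr(xa, ya).statistic)


def bland_altman(app: Sequence[float], reference: Sequence[float]) -> BlandAltman:
    """Bland-Altman agreement of paired measurements.

    Differences are taken app - reference; limits of agreement are
    bias +/- 1.96 * SD(d) with the sample SD (n-1).  ``n_outside_loa``
    counts differences strictly outside the limits.
    """
    a = np.asarray(app, dtype=float)
    r = np.asarray(reference, dtype=float)
    if a.shape != r.shape or a.ndim != 1:
        raise ValidationError("app and reference must be equal-length 1-D vectors")
    if a.size < 2:
        raise InsufficientDataError(f"Bland-Altman needs n >= 2, got {a.size}")
    d = a - r
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    n_out = int(np.sum((d < lo) | (d > hi)))
    return BlandAltman(
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        n_outside_loa=n_out,
        sd_diff=sd,
        diffs=d,
        means=(a + r) / 2.0,
    )


# ---------------------------------------------------------------------------
# study-level analyses


def _movements_present(table: StudyTable) -> list[Movement]:
    present = {r.movement for r in table}
    if not present:
        raise InsufficientDataError("study table is empty")
    return [m for m in PROTOCOL_ORDER if m in present]


def _paired_sessions(
    table: StudyTable, movement: Movement
) -> tuple[np.ndarray, np.ndarray]:
    s1 = {r.participant_id: r.angle_deg for r in table.select(movement=movement, session=1, method=Method.APP)}
    s2 = {r.participant_id: r.angle_deg for r in table.select(movement=movement, session=2, method=Method.APP)}
    missing = sorted(set(s1) ^ set(s2))
    if missing:
        raise ValidationError(
            f"{movement.value}: participants missing one app session: {missing}"
        )
    pids = sorted(s1)
    if not pids:
        raise InsufficientDataError(f"{movement.value}: no app measurements found")
    return (
        np.array([s1[p] for p in pids]),
        np.array([s2[p] for p in pids]),
    )


def analyze_reliability(
    table: StudyTable,
    *,
    icc_form: str = "agreement",
    s_mode: str = "pooled",
) -> list[ReliabilityResult]:
    """One ReliabilityResult per movement, in protocol order.

    ``s_mode="pooled"`` (default) uses the SD of the concatenated 2N scores
    for S in the SEM; ``"session_mean"`` averages the two per-session SDs.
    """
    results = []
    for movement in _movements_present(table):
        x1, x2 = _paired_sessions(table, movement)
        icc, lo, hi = icc_two_way_random(x1, x2, form=icc_form)
        if s_mode == "pooled":
            s = float(np.std(np.concatenate([x1, x2]), ddof=1))
        elif s_mode == "session_mean":
            s = float((np.std(x1, ddof=1) + np.std(x2, ddof=1)) / 2.0)
        else:
            raise ValidationError(f"unknown s_mode {s_mode!r}")
        sem_v = s * math.sqrt(max(0.0, 1.0 - icc))
        results.append(
            ReliabilityResult(
                movement=movement,
                icc=icc,
                ci_low=lo,
                ci_high=hi,
                s_pooled=s,
                sem=sem_v,
                mdc=mdc(sem_v),
                icc_class=classify_icc(icc),
            )
        )
    return results


def _paired_methods(
    table: StudyTable, movement: Movement, session: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    app = {r.participant_id: r.angle_deg for r in table.select(movement=movement, session=session, method=Method.APP)}
    ref = {r.participant_id: r.angle_deg for r in table.select(movement=movement, session=session, method=Method.REFERENCE)}
    unpaired = sorted(set(app) ^ set(ref))
    if unpaired:
        raise ValidationError(
            f"{movement.value}: unpaired method records for participants: {unpaired}"
        )
    pids = sorted(app)
    if not pids:
        raise InsufficientDataError(f"{movement.value}: no session-{session} records")
    return (
        np.array([app[p] for p in pids]),
        np.array([ref[p] for p in pids]),
    )


def analyze_validity(table: StudyTable, *, session: int = 1) -> list[ValidityResult]:
    """One ValidityResult per movement (app vs reference, first session)."""
    results = []
    for movement in _movements_present(table):
        app, ref = _paired_methods(table, movement, session)
        r = pearson_r(app, ref)
        ba = bland_altman(app, ref)
        results.append(
            ValidityResult(
                movement=movement,
                r=r,
                r_class=classify_r(r),
                bias=ba.bias,
                loa_low=ba.loa_low,
                loa_high=ba.loa_high,
                n_outside_loa=ba.n_outside_loa,
            )
        )
    return results


# ---------------------------------------------------------------------------
# report writers (CSV, with provenance comment lines)


def write_reliability_report(
    results: Sequence[ReliabilityResult],
    path: Union[str, Path],
    *,
    header_comments: Sequence[str] = (),
) -> None:
    """Reliability table: movement, ICC (95% CI), SEM, MDC, classification."""
    with open(path, "w", encoding="utf-8") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("movement,icc,ci_low,ci_high,sem,mdc,icc_class\n")
        for res in results:
            fh.write(
                f"{res.movement.value},{res.icc:.6f},{res.ci_low:.6f},"
                f"{res.ci_high:.6f},{res.sem:.6f},{res.mdc:.6f},{res.icc_class}\n"
            )


def write_validity_report(
    results: Sequence[ValidityResult],
    path: Union[str, Path],
    *,
    header_comments: Sequence[str] = (),
) -> None:
    """Validity table: movement, Pearson r, class, bias, LoA, outliers."""
    with open(path, "w", encoding="utf-8") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("movement,r,r_class,bias,loa_low,loa_high,n_outside_loa\n")
        for res in results:
            fh.write(
                f"{res.movement.value},{res.r:.6f},{res.r_class},{res.bias:.6f},"
                f"{res.loa_low:.6f},{res.loa_high:.6f},{res.n_outside_loa}\n"
            )


def plot_validity(
    table: StudyTable,
    out_dir: Union[str, Path],
    *,
    session: int = 1,
) -> list[Path]:
    """Write a correlation scatter and a Bland-Altman plot per movement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for movement in _movements_present(table):
        app, ref = _paired_methods(table, movement, session)
        ba = bland_altman(app, ref)
        r = pearson_r(app, ref)

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(ref, app, s=18)
        lims = [min(ref.min(), app.min()) - 2, max(ref.max(), app.max()) + 2]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_xlabel("reference picture (deg)")
        ax.set_ylabel("app (deg)")
        ax.set_title(f"{movement.value}  r = {r:.2f}")
        p = out_dir / f"correlation_{movement.value}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)

        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        ax.scatter(ba.means, ba.diffs, s=18)
        for yv, style in [(ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")]:
            ax.axhline(yv, color="k", ls=style, lw=0.8)
        ax.set_xlabel("mean of methods (deg)")
        ax.set_ylabel("app - reference (deg)")
        ax.set_title(f"{movement.value}  bias = {ba.bias:.1f}")
        p = out_dir / f"bland_altman_{movement.value}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)
    return written
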