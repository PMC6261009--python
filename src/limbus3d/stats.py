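"""Cohort summaries and two-sample t-tests.

Per-eye geometry reports are aggregated into a table of
``mean +/- STD`` / ``min : max`` cells per (quantity, orientation, side),
with Student's pooled-variance two-sample t-tests (two-sided, alpha =
0.05) between right and left eyes of each quantity and between the
nasal-temporal and superior-inferior directions within each side.  Welch's
unequal-variance variant is available by flag; paired structure between
fellow eyes is deliberately ignored — the comparisons are between
independent samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import EmptyGroup, EmptyInput, TooFewObservations


@dataclass
class SummaryStats:
    """Sample summary in the ``mean +/- STD`` / ``min : max`` layout."""

    n: int
    mean: float
    std: float
    min: float
    max: float
    unit: str = ""

    def mean_std(self, decimals: int = 2) -> str:
        return f"{self.mean:.{decimals}f} ± {self.std:.{decimals}f}"

    def min_max(self, decimals: int = 2) -> str:
        return f"{self.min:.{decimals}f} : {self.max:.{decimals}f}"


@dataclass
class TTestResult:
    """Two-sample t statistic with its degrees of freedom and two-sided p."""

    t: float
    df: float
    p: float


def summarize(values: Iterable[float], unit: str = "") -> SummaryStats:
    """Sample mean, n-1 standard deviation and range.

    A single observation has std 0 by convention.

    Raises
    ------
    EmptyInput
        No values, or any non-finite value.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise EmptyInput("cannot summarize an empty sample")
    if not np.isfinite(arr).all():
        raise EmptyInput("sample contains non-finite values")
    std = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return SummaryStats(
        n=int(arr.size),
        mean=float(arr.mean()),
        std=std,
        min=float(arr.min()),
        max=float(arr.max()),
        unit=unit,
    )


def two_sample_t(a: Sequence[float], b: Sequence[float],
                 equal_var: bool = True) -> TTestResult:
    """Student's pooled-variance (default) or Welch two-sample t-test.

    Two-sided p from the t distribution; with pooled variance
    ``df = n_a + n_b - 2``.  Two samples with identical means and zero
    variance give ``t = 0, p = 1``.

    Raises
    ------
    TooFewObservations
        Either sample has fewer than two finite observations.
    """
    xa = np.asarray(list(a), dtype=float)
    xb = np.asarray(list(b), dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise TooFewObservations("each sample needs at least 2 observations")
    if not (np.isfinite(xa).all() and np.isfinite(xb).all()):
        raise TooFewObservations("samples must be finite")
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    diff = xa.mean() - xb.mean()
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            df = float(xa.size + xb.size - 2)
            return TTestResult(t=0.0, df=df, p=1.0)
        df = float(xa.size + xb.size - 2)
        return TTestResult(t=float(np.sign(diff) * np.inf), df=df, p=0.0)
    if equal_var:
        na, nb = xa.size, xb.size
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        na, nb = xa.size, xb.size
        se = np.sqrt(va / na + vb / nb)
        df = float(
            (va / na + vb / nb) ** 2
            / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        )
    t = float(diff / se)
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p=p)


#: canonical per-eye report keys summarised by :func:`cohort_table`,
#: as (quantity, orientation) -> report key
_TABLE_KEYS = {
    ("limbus", "NT"): "limbus_nt_mm",
    ("limbus", "SI"): "limbus_si_mm",
    ("wtw", "NT"): "wtw_nt_mm",
    ("wtw", "SI"): "wtw_si_mm",
    ("delta", "NT"): "delta_nt_mm",
    ("delta", "SI"): "delta_si_mm",
    ("depth", "nasal"): "depth_nasal_mm",
    ("depth", "temporal"): "depth_temporal_mm",
    ("depth", "superior"): "depth_superior_mm",
    ("depth", "inferior"): "depth_inferior_mm",
}


def _group_values(reports: list[dict], side: str, key: str) -> np.ndarray:
    vals = [
        float(r[key])
        for r in reports
        if r.get("laterality") == side and r.get(key) is not None
    ]
    if not vals:
        raise EmptyGroup(f"no {side}-eye values for {key}")
    return np.asarray(vals)


def cohort_table(
    reports: list[dict],
    sides: tuple[str, ...] = ("right", "left"),
    equal_var: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Aggregate per-eye reports into a summary table plus pairwise p-values.

    Parameters
    ----------
    reports : list of dict
        Each dict carries ``laterality`` plus any of the canonical metric
        keys (``limbus_nt_mm``, ``wtw_si_mm``, ``depth_nasal_mm``, ...).
        Missing keys are skipped entirely.
    sides : tuple of str
        The cells the table must contain; a requested side with no eyes for
        a tabulated metric raises :class:`EmptyGroup` rather than silently
        shrinking the table.

    Returns
    -------
    table : DataFrame
        One row per (quantity, orientation): n/mean/std/min/max per side,
        formatted cells, and the right-vs-left p-value.
    pairwise : dict
        ``pairwise["nt_vs_si"][(quantity, side)]`` holds the p-value of the
        NT-vs-SI comparison within that side (quantities with both
        orientations only).
    """
    if not reports:
        raise EmptyInput("no reports to summarize")

    present = [
        (qty, orient, key)
        for (qty, orient), key in _TABLE_KEYS.items()
        if any(key in r and r[key] is not None for r in reports)
    ]
    rows = []
    for qty, orient, key in present:
        row: dict = {"quantity": qty, "orientation": orient}
        per_side = {}
        for side in sides:
            vals = _group_values(reports, side, key)
            s = summarize(vals, unit="mm")
            per_side[side] = vals
            row.update(
                {
                    f"{side}_n": s.n,
                    f"{side}_mean": s.mean,
                    f"{side}_std": s.std,
                    f"{side}_min": s.min,
                    f"{side}_max": s.max,
                    f"{side}_mean_std": s.mean_std(),
                    f"{side}_min_max": s.min_max(),
                }
            )
        if "right" in per_side and "left" in per_side:
            row["p_right_vs_left"] = two_sample_t(
                per_side["right"], per_side["left"], equal_var=equal_var
            ).p
        rows.append(row)
    table = pd.DataFrame(rows)

    pairwise: dict = {"nt_vs_si": {}}
    for qty in {q for q, _, _ in present}:
        keys = {o: k for (q, o), k in _TABLE_KEYS.items() if q == qty}
        if "NT" not in keys or "SI" not in keys:
            continue
        for side in sides:
            try:
                a = _group_values(reports, side, keys["NT"])
                b = _group_values(reports, side, keys["SI"])
            except EmptyGroup:
                continue
            pairwise["nt_vs_si"][(qty, side)] = two_sample_t(
                a, b, equal_var=equal_var
            ).p
    return table, pairwise


def format_cohort_table(table: pd.DataFrame, pairwise: dict) -> str:
    """Plain-text rendering of the cohort table."""
    lines = ["Cohort summary (mean ± STD / min : max, mm)", "=" * 60]
    for _, row in table.iterrows():
        label = f"{row['quantity']:>7s} {row['orientation']:<9s}"
        cells = []
        for side in ("right", "left"):
            if f"{side}_mean_std" in row and isinstance(row.get(f"{side}_mean_std"), str):
                cells.append(
                    f"{side[0].upper()}: {row[f'{side}_mean_std']} "
                    f"({row[f'{side}_min_max']})"
                )
        p = row.get("p_right_vs_left")
        ptxt = f"  p(R vs L)={p:.3f}" if p == p and p is not None else ""
        lines.append(f"{label} " + "   ".join(cells) + ptxt)
    if pairwise.get("nt_vs_si"):
        lines.append("-" * 60)
        for (qty, side), p in sorted(pairwise["nt_vs_si"].items()):
            lines.append(f"{qty:>7s} NT vs SI ({side}): p = {p:.3f}")
    return "\n".join(lines)
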