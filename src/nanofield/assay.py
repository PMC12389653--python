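"""Flow-cytometry and plate-assay arithmetic for electroporation readouts.

Implements the measurement chain used to score membrane permeabilization
and gene electrotransfer (GET):

* scatter gating (debris exclusion) and singlet selection on
  (FSC-A, SSC-A, FSC-H) channels;
* sham-anchored PI thresholds: the 0 V control defines the live (A1) and
  dead (A3) fluorescence regions; viable permeabilized cells (A2) lie
  between them;
* the A1/A2/A3 partition of gated singlets (half-open bins, exact);
* MTS viability: sample absorbance normalized to the matched 0 V control;
* overall GET = %GFP-positive x %survival / 100, and the best-voltage
  selection on an overall-GET curve;
* one-way ANOVA with Holm-Sidak step-down adjusted pairwise comparisons
  against a control group.

Event tables are pandas DataFrames with columns ``fsc_a, fsc_h, ssc_a, fl``
and an optional hidden ``true_class`` column that carries generator ground
truth; no gating operation ever reads it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import stats

__all__ = [
    "AssayError", "GateSet", "AssayResult", "auto_gates", "gate_events",
    "derive_pi_thresholds", "permeabilization_fraction", "viability_mts",
    "overall_get", "best_voltage", "compare_groups",
]

EVENT_COLUMNS = ("fsc_a", "fsc_h", "ssc_a", "fl")


class AssayError(ValueError):
    pass


def _check_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise AssayError(f"event table lacks columns {missing}")
    vals = events[list(EVENT_COLUMNS)].to_numpy()
    if not np.isfinite(vals).all() or (vals < 0).any():
        raise AssayError("event channels must be finite and >= 0")
    return events


@dataclass(frozen=True)
class GateSet:
    """Scatter polygon + singlet band + PI thresholds.

    ``scatter_gate``: convex polygon vertices in (fsc_a, ssc_a); events on
    the boundary are retained (closed gate).  ``singlet_k`` and
    ``singlet_band``: singlets satisfy |fsc_a - k*fsc_h| <= band*k*fsc_h.
    ``pi_thresholds``: optional (t_low, t_high); A2 = [t_low, t_high).
    """

    scatter_gate: tuple[tuple[float, float], ...]
    singlet_k: float = 1.0
    singlet_band: float = 0.25
    pi_thresholds: Optional[tuple[float, float]] = None

    def __post_init__(self):
        poly = shapely.Polygon(self.scatter_gate)
        if not poly.is_valid or poly.area <= 0:
            raise AssayError("scatter gate polygon is degenerate")
        if self.pi_thresholds is not None:
            t_low, t_high = self.pi_thresholds
            if not t_low < t_high:
                raise AssayError("need t_low < t_high")

    @property
    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.scatter_gate)


def auto_gates(events: pd.DataFrame, lo_decades: float = 0.4,
               hi_decades: float = 0.55) -> GateSet:
    """Derive a scatter box and singlet ratio from the data itself.

    The box is anchored on the median scatter (the intact-cell cloud --
    debris is a minority at distinctly lower scatter) and extends
    ``lo_decades`` below and ``hi_decades`` above it on both axes; doublets
    (area ~ 2x height, +0.3 decades) stay inside the box and are removed by
    the singlet band, whose ratio k = median(FSC-A / FSC-H).
    """
    _check_events(events)
    if len(events) == 0:
        raise AssayError("cannot derive gates from an empty table")
    med_fa = float(np.median(events["fsc_a"]))
    med_sa = float(np.median(events["ssc_a"]))
    lo, hi = 10.0 ** -lo_decades, 10.0 ** hi_decades
    box = ((med_fa * lo, med_sa * lo), (med_fa * hi, med_sa * lo),
           (med_fa * hi, med_sa * hi), (med_fa * lo, med_sa * hi))
    k = float(np.median(events["fsc_a"] / np.maximum(events["fsc_h"], 1e-300)))
    return GateSet(scatter_gate=box, singlet_k=k)


def gate_events(events: pd.DataFrame, gates: GateSet) -> pd.DataFrame:
    """Scatter gate AND singlet band; order preserved, boundaries included.
    An empty input yields an empty output."""
    _check_events(events)
    if len(events) == 0:
        return events.copy()
    pts = shapely.points(np.c_[events["fsc_a"], events["ssc_a"]])
    in_scatter = shapely.covers(gates.polygon, pts)
    dev = np.abs(events["fsc_a"] - gates.singlet_k * events["fsc_h"])
    is_singlet = dev <= gates.singlet_band * gates.singlet_k * events["fsc_h"]
    return events[in_scatter & is_singlet.to_numpy()]


def derive_pi_thresholds(sham: pd.DataFrame, live_quantile: float = 0.995,
                         dead_quantile: float = 0.005,
                         fallback_multiplier: float = 30.0,
                         ) -> tuple[float, float]:
    """Thresholds (t_low, t_high) from a gated 0 V sham control.

    The sham fluorescence is split into a live mode and (if present) a dead
    mode by a deterministic two-means split on log10(fl).  t_low is the
    ``live_quantile`` (99.5th percentile) of the live mode; t_high is the
    log-scale midpoint between t_low and the ``dead_quantile`` (0.5th
    percentile) of the dead mode.  A unimodal sham (no dead events) falls
    back to t_high = fallback_multiplier * t_low.
    """
    _check_events(sham)
    if len(sham) == 0:
        raise AssayError("empty sham table")
    logf = np.log10(np.maximum(sham["fl"].to_numpy(), 1e-12))
    c = np.quantile(logf, [0.05, 0.95])
    for _ in range(50):
        split = (logf[:, None] - c[None, :]) ** 2
        lab = split.argmin(axis=1)
        new = np.array([logf[lab == k].mean() if (lab == k).any() else c[k]
                        for k in (0, 1)])
        if np.allclose(new, c, atol=1e-12):
            break
        c = new
    live = logf[lab == 0]
    dead = logf[lab == 1]
    separated = (len(dead) >= max(3, 0.002 * len(logf))
                 and (c[1] - c[0]) > 1.0)
    t_low = float(10 ** np.quantile(live if separated else logf, live_quantile))
    if separated:
        dead_edge = float(10 ** np.quantile(dead, dead_quantile))
        if dead_edge > t_low:
            t_high = math.sqrt(t_low * dead_edge)  # log-scale midpoint
        else:
            t_high = t_low * fallback_multiplier
    else:
        t_high = t_low * fallback_multiplier
    return t_low, t_high


@dataclass(frozen=True)
class AssayResult:
    """A1/A2/A3 percentages of gated singlets plus derived scores."""

    a1_pct: float
    a2_pct: float
    a3_pct: float
    n_gated: int
    permeabilized_pct: float = dc_field(init=False)
    dead_pct: float = dc_field(init=False)

    def __post_init__(self):
        total = self.a1_pct + self.a2_pct + self.a3_pct
        if self.n_gated and abs(total - 100.0) > 1e-9:
            raise AssayError(f"A1+A2+A3 = {total}, not 100")
        object.__setattr__(self, "permeabilized_pct", self.a2_pct)
        object.__setattr__(self, "dead_pct", self.a3_pct)


def permeabilization_fraction(events: pd.DataFrame,
                              thresholds: tuple[float, float]) -> AssayResult:
    """Partition gated events: A1 = fl < t_low (live, non-permeabilized),
    A2 = t_low <= fl < t_high (viable permeabilized), A3 = fl >= t_high
    (dead).  Half-open bins: an event exactly at t_low counts in A2."""
    _check_events(events)
    t_low, t_high = thresholds
    if not t_low < t_high:
        raise AssayError("need t_low < t_high")
    n = len(events)
    if n == 0:
        return AssayResult(a1_pct=0.0, a2_pct=0.0, a3_pct=0.0, n_gated=0)
    fl = events["fl"].to_numpy()
    a1 = int((fl < t_low).sum())
    a2 = int(((fl >= t_low) & (fl < t_high)).sum())
    a3 = n - a1 - a2
    return AssayResult(a1_pct=100.0 * a1 / n, a2_pct=100.0 * a2 / n,
                       a3_pct=100.0 * a3 / n, n_gated=n)


def viability_mts(sample_absorbance: float, control_absorbance: float) -> float:
    """Percent survival: sample absorbance normalized to the 0 V control
    with the same NP concentration.  Values above 100% are legitimate
    (proliferation noise)."""
    if control_absorbance <= 0:
        raise AssayError("control absorbance must be positive")
    if sample_absorbance < 0:
        raise AssayError("sample absorbance must be >= 0")
    return 100.0 * sample_absorbance / control_absorbance


def overall_get(gfp_pct: float, survival_pct: float) -> float:
    """Overall gene electrotransfer: %GFP-positive x %survival / 100."""
    if gfp_pct < 0 or survival_pct < 0:
        raise AssayError("percentages must be >= 0")
    return gfp_pct * survival_pct / 100.0


def best_voltage(curve: Sequence[tuple[float, float]]) -> float:
    """Voltage with the highest overall GET; ties resolve to the lowest
    voltage."""
    if not curve:
        raise AssayError("empty curve")
    best_v, best_y = None, -math.inf
    for v, y in sorted(curve, key=lambda p: p[0]):
        if y > best_y:
            best_v, best_y = v, y
    return best_v


def _holm_sidak(pvals: np.ndarray) -> np.ndarray:
    """Step-down Sidak adjustment: order raw p ascending,
    adj_i = 1 - (1 - p_(i))^(m - i + 1), enforce monotone non-decreasing."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        a = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, a)
        adj[idx] = min(1.0, running)
    return adj


def compare_groups(groups: dict[str, Sequence[float]], control: str | None = None,
                   alpha: float = 0.05) -> dict:
    """One-way ANOVA plus Holm-Sidak-adjusted pairwise t-tests vs control.

    ``groups`` maps label -> replicate values (>= 2 each); ``control``
    defaults to the first label.  Pairwise tests are two-sided pooled-
    variance t-tests; their raw p-values are Holm-Sidak adjusted and
    flagged at ``alpha``.
    """
    if len(groups) < 2:
        raise AssayError("need at least two groups")
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise AssayError(f"group {k!r} has fewer than 2 replicates")
    labels = list(arrays)
    control = control if control is not None else labels[0]
    if control not in arrays:
        raise AssayError(f"unknown control group {control!r}")

    vals = list(arrays.values())
    if np.ptp(np.concatenate(vals)) == 0:
        F, p_anova = 0.0, 1.0
    else:
        F, p_anova = stats.f_oneway(*vals)
        if math.isnan(F):  # degenerate within-group variance
            F, p_anova = 0.0, 1.0

    others = [k for k in labels if k != control]
    raw = []
    for k in others:
        a, b = arrays[control], arrays[k]
        if np.ptp(np.concatenate([a, b])) == 0:
            raw.append(1.0)
            continue
        t, p = stats.ttest_ind(a, b, equal_var=True)
        raw.append(1.0 if math.isnan(p) else float(p))
    raw = np.asarray(raw)
    adj = _holm_sidak(raw) if len(raw) else raw
    return {
        "anova_F": float(F),
        "anova_p": float(p_anova),
        "control": control,
        "comparisons": {
            k: {"p_raw": float(pr), "p_adjusted": float(pa),
                "significant": bool(pa < alpha)}
            for k, pr, pa in zip(others, raw, adj)
        },
        "alpha": alpha,
    }
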