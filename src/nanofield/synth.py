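"""Synthetic flow-cytometry and plate-assay data generators.

Every test input of the assay chain is generated here: event tables with
the class structure the gating assumes (debris, live, viable-permeabilized,
dead, doublets), voltage-response experiments built from logistic dose
curves, and MTS absorbance wells.  The generators emulate the *structure*
of real cytometry -- log-normal fluorescence modes ordered
live < permeabilized < dead, scatter clouds with low-scatter debris,
doublets with area ~ 2x height -- not any particular instrument's raw data
(none is publicly available for this assay); see docs/methods.md for what
that implies about test coverage.

Determinism: every output is a pure function of (model, n, seed); a single
numpy Generator seeded per call, no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "PopulationModel", "DoseResponseModel", "SynthError",
    "generate_events", "generate_experiment", "generate_viability",
    "get_curve",
]

CLASSES = ("debris", "live", "permeabilized", "dead", "doublet")


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class PopulationModel:
    """Event-class mixture and per-class channel distributions.

    Fluorescence is log-normal per class with log10 locations ordered
    live < permeabilized < dead (one decade of separation by default, the
    regime in which threshold gating is meaningful).  Scatter channels are
    log-normal; debris sits at low scatter; doublets have fsc_a ~ 2x
    fsc_h with jitter.
    """

    fractions: dict = field(default_factory=lambda: {
        "debris": 0.15, "live": 0.67, "permeabilized": 0.0,
        "dead": 0.02, "doublet": 0.16})
    #: log10 fluorescence location per class
    fl_loc: dict = field(default_factory=lambda: {
        "live": 1.9, "permeabilized": 2.9, "dead": 4.5})
    #: log10 fluorescence scale per class
    fl_scale: dict = field(default_factory=lambda: {
        "live": 0.18, "permeabilized": 0.15, "dead": 0.20})
    scatter_loc: float = 5.0        # log10 FSC-A of intact cells
    scatter_scale: float = 0.08
    ssc_loc: float = 4.6
    ssc_scale: float = 0.10
    debris_shift: float = -0.9      # debris scatter offset (decades)
    doublet_jitter: float = 0.06

    def __post_init__(self):
        fr = self.fractions
        if set(fr) - set(CLASSES):
            raise SynthError(f"unknown classes {set(fr) - set(CLASSES)}")
        vals = np.array([fr.get(c, 0.0) for c in CLASSES])
        if (vals < 0).any() or (vals > 1).any():
            raise SynthError("fractions must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise SynthError(f"fractions sum to {vals.sum()}, not 1")
        if not (self.fl_loc["live"] < self.fl_loc["permeabilized"]
                < self.fl_loc["dead"]):
            raise SynthError("need fluorescence order live < permeabilized < dead")

    def with_fractions(self, permeabilized: float, dead: float) -> "PopulationModel":
        """Same model with the (permeabilized, dead) fractions replaced;
        debris and doublet rates are kept, live absorbs the remainder."""
        fr = dict(self.fractions)
        other = fr.get("debris", 0.0) + fr.get("doublet", 0.0)
        live = 1.0 - other - permeabilized - dead
        if live < 0:
            raise SynthError("fractions exceed 1")
        fr.update(live=live, permeabilized=permeabilized, dead=dead)
        return replace(self, fractions=fr)


def generate_events(model: PopulationModel, n: int, seed: int) -> pd.DataFrame:
    """Draw an event table: class first, then channels given the class.

    The hidden ground truth label is recorded in ``true_class``; gating
    code never reads it (tests do).
    """
    if n < 1:
        raise SynthError("n must be >= 1")
    rng = np.random.default_rng(seed)
    fracs = np.array([model.fractions.get(c, 0.0) for c in CLASSES])
    cls = rng.choice(len(CLASSES), size=n, p=fracs)
    names = np.array(CLASSES)[cls]

    log_fsc = rng.normal(model.scatter_loc, model.scatter_scale, n)
    log_ssc = rng.normal(model.ssc_loc, model.ssc_scale, n)
    debris = names == "debris"
    log_fsc[debris] += model.debris_shift
    log_ssc[debris] += model.debris_shift
    fsc_a = 10 ** log_fsc
    ssc_a = 10 ** log_ssc
    fsc_h = fsc_a.copy()
    doublet = names == "doublet"
    # a doublet carries ~double area at single-cell height
    fsc_a[doublet] *= 2.0 * (1 + rng.normal(0, model.doublet_jitter,
                                            int(doublet.sum())))
    ssc_a[doublet] *= 2.0

    # fluorescence: debris/doublets resemble live-level background
    loc = np.full(n, model.fl_loc["live"])
    scale = np.full(n, model.fl_scale["live"])
    for c in ("live", "permeabilized", "dead"):
        m = names == c
        loc[m] = model.fl_loc[c]
        scale[m] = model.fl_scale[c]
    fl = 10 ** rng.normal(loc, scale)

    return pd.DataFrame({
        "fsc_a": fsc_a, "fsc_h": fsc_h, "ssc_a": ssc_a, "fl": fl,
        "true_class": names,
    })


@dataclass(frozen=True)
class DoseResponseModel:
    """Voltage dependence of permeabilization, death, GFP expression and
    survival, each a logistic in the applied voltage.

    Defaults emulate the experimental assay design: eight 100 us pulses,
    voltages 0-275 V across a 2 mm cuvette, permeabilization half-maximal
    at 150 V (the middle of the curve, where NP effects would show),
    death onset well above, and an overall-GET optimum at 250 V.
    ``np_effect``: additive permeabilization shift (percentage points)
    applied at ``np_effect_voltage`` only.
    """

    voltages: tuple[float, ...] = (0.0, 175.0, 200.0, 225.0, 250.0, 275.0)
    perm_midpoint: float = 150.0
    perm_slope: float = 0.05            # 1/V
    max_permeabilization: float = 95.0  # %
    death_midpoint: float = 300.0
    death_slope: float = 0.05
    max_death: float = 90.0
    gfp_midpoint: float = 215.0
    gfp_slope: float = 0.045
    max_gfp: float = 60.0
    np_effect: float = 0.0              # percentage points
    np_effect_voltage: Optional[float] = 150.0

    def __post_init__(self):
        if not self.death_midpoint > self.perm_midpoint:
            raise SynthError("death midpoint must exceed permeabilization midpoint")
        for v in (self.max_permeabilization, self.max_death, self.max_gfp):
            if not 0 <= v <= 100:
                raise SynthError("logistic maxima must lie in [0, 100]")

    @staticmethod
    def _logistic(v, mid, slope, top):
        return top / (1.0 + np.exp(-slope * (np.asarray(v, float) - mid)))

    def permeabilized_pct(self, voltage: float) -> float:
        base = self._logistic(voltage, self.perm_midpoint, self.perm_slope,
                              self.max_permeabilization)
        if (self.np_effect and self.np_effect_voltage is not None
                and math.isclose(voltage, self.np_effect_voltage)):
            base = min(100.0, base + self.np_effect)
        return float(base)

    def dead_pct(self, voltage: float) -> float:
        return float(self._logistic(voltage, self.death_midpoint,
                                    self.death_slope, self.max_death))

    def gfp_pct(self, voltage: float) -> float:
        return float(self._logistic(voltage, self.gfp_midpoint,
                                    self.gfp_slope, self.max_gfp))

    def survival_pct(self, voltage: float) -> float:
        return 100.0 - self.dead_pct(voltage)


def get_curve(dose: DoseResponseModel) -> list[tuple[float, float]]:
    """Noise-free overall-GET curve on the model's voltage grid."""
    return [(v, dose.gfp_pct(v) * dose.survival_pct(v) / 100.0)
            for v in dose.voltages]


def generate_experiment(dose: DoseResponseModel,
                        population: PopulationModel | None = None,
                        n_events: int = 10_000, seed: int = 0,
                        ) -> dict:
    """One synthetic permeabilization experiment: a sham (0 V) table plus
    one table per tested voltage, with true permeabilized/dead fractions
    given by the dose logistics, and a design manifest listing the two
    controls (CTRL1 = plasmid only, CTRL2 = no plasmid, both 0 V)."""
    if population is None:
        population = PopulationModel()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=len(dose.voltages) + 1)
    sham_model = population.with_fractions(
        permeabilized=0.0, dead=population.fractions.get("dead", 0.02))
    tables = {}
    truth = {}
    for v, s in zip(dose.voltages, seeds[1:]):
        cell_frac = 1.0 - (population.fractions.get("debris", 0.0)
                           + population.fractions.get("doublet", 0.0))
        perm = dose.permeabilized_pct(v) / 100.0
        dead = max(population.fractions.get("dead", 0.02) / cell_frac,
                   dose.dead_pct(v) / 100.0)
        live_share = cell_frac
        m = population.with_fractions(permeabilized=perm * (1 - dead) * live_share,
                                      dead=dead * live_share)
        tables[v] = generate_events(m, n_events, int(s))
        truth[v] = {"permeabilized_pct": 100 * perm * (1 - dead),
                    "dead_pct": 100 * dead}
    sham = generate_events(sham_model, n_events, int(seeds[0]))
    manifest = {
        "design": {
            "controls": {"CTRL1": "0 V, with plasmid",
                         "CTRL2": "0 V, without plasmid"},
            "voltages": list(dose.voltages),
            "n_events": n_events,
        },
        "seed": seed,
        "truth": truth,
    }
    return {"sham": sham, "tables": tables, "manifest": manifest}


def generate_viability(true_viability_pct: float, cv: float, n_wells: int,
                       seed: int, control_absorbance: float = 1.0,
                       ) -> pd.DataFrame:
    """Paired control/sample absorbances with multiplicative log-normal
    noise of coefficient of variation ``cv``.  Plate factors are shared
    within a pair, so the expected per-pair MTS viability equals the true
    value exactly (cv = 0 recovers it identically)."""
    if cv < 0:
        raise SynthError("cv must be >= 0")
    if n_wells < 1:
        raise SynthError("n_wells must be >= 1")
    rng = np.random.default_rng(seed)
    # log-normal with unit mean: exp(N(-s^2/2, s^2)), s^2 = ln(1 + cv^2)
    s2 = math.log1p(cv * cv)
    noise = lambda k: np.exp(rng.normal(-s2 / 2, math.sqrt(s2), k))
    # paired design: plate-level factors are shared by the control and its
    # sample well, so the per-pair viability ratio is unbiased
    control = control_absorbance * noise(n_wells)
    sample = control * true_viability_pct / 100.0 * noise(n_wells)
    return pd.DataFrame({"control_absorbance": control,
                         "sample_absorbance": sample})
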