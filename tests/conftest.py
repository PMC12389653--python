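"""Shared fixtures: solved scenarios are expensive (a few seconds each), so
one session-scoped fixture solves the whole builtin set once and every
metric/acceptance test reads from it."""

from __future__ import annotations

import numpy as np
import pytest

from nanofield import builtin_scenarios, solve_scenario


@pytest.fixture(scope="session")
def builtin():
    return {s.label: s for s in builtin_scenarios()}


@pytest.fixture(scope="session")
def solved(builtin):
    """label -> ScenarioResult for every builtin scenario (each NP scenario
    carries its matched-mesh baseline solution and metrics report)."""
    return {label: solve_scenario(spec) for label, spec in builtin.items()}


GAP_LABELS = ("gold_disc_r10", "silica_disc_r10", "gold_disc_r50",
              "silica_disc_r50", "gold_capsule")
EMBEDDED_LABEL = "gold_disc_r50_embedded"


@pytest.fixture(scope="session")
def gap_results(solved):
    return {k: solved[k] for k in GAP_LABELS}


@pytest.fixture(scope="session")
def embedded_result(solved):
    return solved[EMBEDDED_LABEL]


def profile_of(result):
    from nanofield import evaluation_line_profile
    return evaluation_line_profile(result.solution)


def center_field(result) -> float:
    """|E| (V/cm) at the evaluation-line centre sample."""
    prof = profile_of(result)
    return float(prof.field_V_per_cm[len(prof.field_V_per_cm) // 2])
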