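"""Shared fixtures: the packaged run table, resistance profiles, published
reference values, and surfaces rebuilt from the published coefficients."""

from __future__ import annotations

import pytest

import safperm
from safperm import rsm
from safperm.io import RESPONSE_TERM_SETS, published_reference, run_table_frame


@pytest.fixture(scope="session")
def runs():
    return safperm.calendula_runs()


@pytest.fixture(scope="session")
def run_frame(runs):
    return run_table_frame(runs)


@pytest.fixture(scope="session")
def profiles():
    return safperm.epidermis_profiles()


@pytest.fixture(scope="session")
def reference():
    return published_reference()


@pytest.fixture(scope="session")
def fits(run_frame):
    """Refits of all six responses with their documented term sets."""
    out = {}
    for response, terms in RESPONSE_TERM_SETS.items():
        data = [
            ((row.pressure_bar, row.co2_flow_g_min), getattr(row, response))
            for row in run_frame.itertuples()
        ]
        out[response] = rsm.fit_quadratic(data, terms, response=response)
    return out


def fit_from_published(reference: dict, response: str) -> rsm.QuadraticFit:
    """Build a QuadraticFit directly from published coefficients (for
    evaluating the published surface rather than the refit one)."""
    entry = reference["quadratic_fits"][response]
    coeffs = entry["coefficients"]
    return rsm.QuadraticFit(
        response=response,
        terms=rsm.ModelTermSet(
            linear_p="P" in coeffs,
            linear_q="Q" in coeffs,
            quad_p="P2" in coeffs,
            quad_q="Q2" in coeffs,
            interaction="PQ" in coeffs,
        ),
        coefficients=dict(coeffs),
        standard_errors={},
        p_values=dict(entry["p_values"]),
        r_squared=entry["r_squared_pct"],
        residual_sd=entry["residual_sd"],
        df_resid=0,
        coding="centered",
        domain=((80.0, 160.0), (10.0, 60.0)),
    )


@pytest.fixture(scope="session")
def published_fits(reference):
    return {
        response: fit_from_published(reference, response)
        for response in reference["quadratic_fits"]
    }
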