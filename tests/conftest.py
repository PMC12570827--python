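"""Shared fixtures: the full pipeline over the built-in worked examples is
run once per session; SCF profiles are cached process-wide, so individual
tests touching the same monomers reuse the converged wavefunctions."""

import pytest

from headtail.chemio import InputRecord
from headtail.harness import PipelineConfig, builtin_fixtures, run_pipeline


@pytest.fixture(scope="session")
def fixture_cases():
    return builtin_fixtures()


@pytest.fixture(scope="session")
def fixture_rows(fixture_cases):
    """Default-rule pipeline results for every built-in worked example."""
    records = [InputRecord(c.name, c.smiles, "monomer") for c in fixture_cases]
    return run_pipeline(records, PipelineConfig(seed=42))


@pytest.fixture(scope="session")
def rows_by_name(fixture_rows):
    return {r.polymer_name: r for r in fixture_rows}
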