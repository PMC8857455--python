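"""Shared fixtures: study summary rows and small synthetic tables."""

from __future__ import annotations

import pytest

from mudflatmix.foodweb import IsotopeSample, SourceSummary


@pytest.fixture()
def sediment_rows() -> list[SourceSummary]:
    """The three surface-sediment survey rows of the study food-web table."""
    return [
        SourceSummary("surface_sediment", "current", 9, -19.5, 1.0, 6.8, 0.7, 9.8),
        SourceSummary("surface_sediment", "survey_a", 32, -19.2, 2.6, 7.7, 1.7, 9.8),
        SourceSummary("surface_sediment", "survey_b", 55, -20.1, 0.9, 5.6, 0.7, 9.8),
    ]


@pytest.fixture()
def liver_samples() -> list[IsotopeSample]:
    """A small liver cohort containing two terrestrial-signal outliers."""
    values = [-16.0, -15.4, -21.4, -16.8, -23.1, -15.9]
    return [
        IsotopeSample(f"wesa_{i:02d}", "western_sandpiper", "liver", v, 13.0)
        for i, v in enumerate(values)
    ]
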