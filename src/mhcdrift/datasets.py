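"""Packaged reference fixtures.

Ships the calibrated radiocarbon ages of the 24 dated specimens that
yielded genotypes at all three DQA loci (12 pre-isolation, 12 island).
These ages drive the heterochronous sampling scheme of the drift simulator.
Ages reported only as bounds are stored at their bound value.
"""

from __future__ import annotations

from importlib import resources

from .io import read_sample_table
from .records import SampleRecord


def specimen_ages() -> list[SampleRecord]:
    """The 24 dated specimens used throughout the temporal analyses."""
    ref = resources.files("mhcdrift").joinpath("data/specimen_ages.csv")
    with resources.as_file(ref) as path:
        return read_sample_table(path)
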