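"""Shared helpers for the numbered analysis drivers.

All drivers analyse the same default synthetic study (seed 42) so their
tables are mutually consistent; the study itself is written once by
``01_simulate_study.py``.
"""

from __future__ import annotations

from pathlib import Path

from shoremeth import simulate as sim

STUDY_SEED = 42
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "study"


def get_dataset() -> sim.SimulatedDataset:
    """The study everyone analyses (regenerated deterministically)."""
    return sim.generate(sim.SimConfig(seed=STUDY_SEED))


def outdir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
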