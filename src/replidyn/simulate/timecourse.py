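"""Simulated 2CLC-emergence time courses (emulated hourly FACS readout).

The expected converted fraction comes from the compartment hazard model
(:func:`replidyn.cellcycle.predict_timecourse`); each observed time point is
a binomial sample of ``n_cells`` cells around that expectation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..cellcycle import CellCycleParams, TimeCourse, TransitionRates, predict_timecourse

__all__ = ["simulate_timecourse", "simulate_replicates"]


def simulate_timecourse(
    rates: TransitionRates,
    cycle: CellCycleParams,
    design: str,
    n_cells: int,
    times_h,
    seed: int = 0,
    replicate: int = 0,
) -> TimeCourse:
    """One noisy 2CLC-fraction time course for a synchronization design.

    Binomial sampling of ``n_cells`` per time point around the model
    expectation; phase-fraction columns are carried along.  Bit-reproducible
    given the seed.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = np.random.default_rng(seed)
    expected = predict_timecourse(rates, cycle, design, times_h)
    counts = rng.binomial(n_cells, expected.fraction)
    return TimeCourse(
        times_h=expected.times_h,
        fraction=counts / n_cells,
        design=design,
        n_cells=n_cells,
        replicate=replicate,
        phase_fractions=expected.phase_fractions,
    )


def simulate_replicates(
    rates: TransitionRates,
    cycle: CellCycleParams,
    designs,
    n_cells: int,
    times_h,
    n_replicates: int = 4,
    seed: int = 0,
) -> list[TimeCourse]:
    """Replicated time courses over several designs with independent seeds."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(designs) * n_replicates)
    out = []
    k = 0
    for design in designs:
        for rep in range(n_replicates):
            out.append(
                simulate_timecourse(
                    rates,
                    cycle,
                    design,
                    n_cells,
                    times_h,
                    seed=int(children[k].generate_state(1)[0] % (2**31)),
                    replicate=rep,
                )
            )
            k += 1
    return out


def timecourse_frame(courses: list[TimeCourse]) -> pd.DataFrame:
    """Tidy CSV-ready table (time_h, fraction, n_cells, design, replicate)."""
    rows = []
    for tc in courses:
        for t, f in zip(tc.times_h, tc.fraction):
            rows.append(
                {
                    "time_h": t,
                    "fraction": f,
                    "n_cells": tc.n_cells,
                    "design": tc.design,
                    "replicate": tc.replicate,
                }
            )
    return pd.DataFrame(rows)
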