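"""Shared fixtures: the hand-built toy cell and default parameters."""

from dataclasses import dataclass

import numpy as np
import pytest

from vetoflag import ModelParams


@dataclass
class ToyCell:
    """Minimal trace container the analysis functions accept."""

    n_flag: int
    motor: np.ndarray
    tumble: np.ndarray
    step: float
    waveform: np.ndarray = None


def make_toy_cell(motor: np.ndarray, step: float = 0.1, tumble=None) -> ToyCell:
    motor = np.asarray(motor, dtype=np.int8)
    if tumble is None:
        tumble = motor.max(axis=0)
    return ToyCell(
        n_flag=motor.shape[0], motor=motor,
        tumble=np.asarray(tumble, dtype=np.int8), step=step,
    )


@pytest.fixture
def model():
    return ModelParams()


@pytest.fixture
def toy_cell():
    """Three flagella over 20 windows of 100 ms.

    Flagellum 1 is CW on windows 5-8, flagellum 2 on 6-9, flagellum 3
    on window 6 (1-indexed).  Under the veto rule the cell tumbles on
    windows 5-9, giving tb = 0.25, cb = 0.15 and a single tumble with
    three simultaneously CW flagella at its peak.
    """
    motor = np.zeros((3, 20), dtype=np.int8)
    motor[0, 4:8] = 1
    motor[1, 5:9] = 1
    motor[2, 5] = 1
    return make_toy_cell(motor)


@pytest.fixture
def toy_factory():
    return make_toy_cell
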