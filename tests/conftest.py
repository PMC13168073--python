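"""Shared fixtures: canonical parameters and synthetic traces."""

from __future__ import annotations

import numpy as np
import pytest

from chiasm import ModelParams, TaskParams
from chiasm.task import SimulationTrace
from chiasm.network import ArchitectureSpec


@pytest.fixture
def mp() -> ModelParams:
    return ModelParams(d_long=5, sigma=0.05, i_inhib=0.5)


@pytest.fixture
def tp_2d() -> TaskParams:
    return TaskParams(dims="two_d", theta=0.3)


@pytest.fixture
def tp_1d() -> TaskParams:
    return TaskParams(dims="one_d", theta=0.0)


def make_trace(
    e_x: np.ndarray,
    m_l: np.ndarray | None = None,
    m_r: np.ndarray | None = None,
    nodes: np.ndarray | None = None,
    e_y: np.ndarray | None = None,
    warmup: int = 0,
    theta: float = 0.0,
) -> SimulationTrace:
    """Construct a synthetic trace with prescribed error/motor series."""
    e_x = np.asarray(e_x, dtype=float)
    T = len(e_x)
    if nodes is None:
        nodes = np.zeros((T, 6))
        if m_l is not None:
            nodes[:, 4] = m_l
        if m_r is not None:
            nodes[:, 5] = m_r
    x_target = e_x.copy()  # body at zero: e_x = target
    kwargs = {}
    if e_y is not None:
        kwargs["y_target"] = np.asarray(e_y, dtype=float)
        kwargs["y_body"] = np.zeros(T)
    return SimulationTrace(
        arch=ArchitectureSpec("ipsilateral", False, False),
        theta=theta,
        warmup=warmup,
        x_target=x_target,
        x_body=np.zeros(T),
        u_l=np.zeros(T),
        u_r=np.zeros(T),
        nodes=nodes,
        **kwargs,
    )
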