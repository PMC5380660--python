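"""Shared helpers for loading the packaged summary-table fixtures and
building forward Darcy samples."""

import importlib.resources

import numpy as np
import pandas as pd

from mediaperm.brinkman import HomogenizationSample


def _data_path(name):
    return importlib.resources.files("mediaperm") / "data" / name


def load_table1() -> pd.DataFrame:
    with importlib.resources.as_file(_data_path("table1_geometry.csv")) as p:
        return pd.read_csv(p, comment="#")


def load_table2() -> pd.DataFrame:
    with importlib.resources.as_file(_data_path("table2_k11.csv")) as p:
        return pd.read_csv(p, comment="#")


def forward_darcy_samples(k, mu=6.913e-4, G=1e7):
    samples = []
    for d, label in enumerate("rzt"):
        g = np.zeros(3)
        g[d] = G
        samples.append(HomogenizationSample(mean_velocity=k @ g / mu,
                                            mean_pressure_gradient=g,
                                            direction_label=label))
    return samples
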