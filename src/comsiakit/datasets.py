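"""Bundled reference tables for the beta3-adrenergic indole-alkylamine series.

Two small CSVs ship with the package:

* ``beta3_activities.csv`` — per-compound EC50 (nM) against the beta1, beta2
  and beta3 adrenergic subtypes for the 25-compound series, the published
  pEC50 (for cross-checking the unit conversion) and the train/test role.
* ``model_predictions.csv`` — published actual and predicted pEC50 per
  compound for the two best similarity-field models (steric+acceptor and
  donor+acceptor) and the 2D Hansch model, with residuals.

These are the printed summary tables of the study; the underlying 3D
structures and 2D descriptor values were never deposited, so external
validation statistics are recomputed from these tables rather than refit.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml


def _data_path(name: str):
    return resources.files("comsiakit.data").joinpath(name)


def load_activity_table():
    """The 25-compound beta3-agonist activity table as an ActivityTable."""
    from .chem_data import ActivityTable

    with resources.as_file(_data_path("beta3_activities.csv")) as p:
        return ActivityTable.from_csv(p)


def load_activity_frame() -> pd.DataFrame:
    """Raw activity CSV including the published pEC50 column."""
    with resources.as_file(_data_path("beta3_activities.csv")) as p:
        return pd.read_csv(p, dtype={"id": str})


def load_model_predictions() -> pd.DataFrame:
    """Published actual/predicted pEC50 per compound for the three best models."""
    with resources.as_file(_data_path("model_predictions.csv")) as p:
        return pd.read_csv(p, dtype={"id": str})


def load_atom_params() -> dict:
    """Per-element vdW radii and hydrophobicity contributions."""
    with resources.as_file(_data_path("atom_params.yaml")) as p:
        return yaml.safe_load(p.read_text())
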