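"""Bundled fixtures: the ESFFFQ definition and its published question subsets."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .questionnaire import QuestionnaireDef, load_questionnaire
from .reduction import FeatureSubset

__all__ = ["esfffq", "esfffq_subsets"]


def _fixture_path(name: str):
    return resources.files("ffqopt.fixtures").joinpath(name)


def esfffq() -> QuestionnaireDef:
    """The 27-item Extended Short Form FFQ with the vegetable target tables."""
    with resources.as_file(_fixture_path("esfffq.yaml")) as path:
        return load_questionnaire(path)


def esfffq_subsets() -> list[FeatureSubset]:
    """The nested ESFFFQ question subsets F0 ⊃ F1 ⊃ … ⊃ F5.

    F1..F5 were obtained on the original 289-respondent cohort with
    correlation thresholds 0.40/0.30/0.25/0.20/0.10 (sizes 19/16/10/6/2);
    F0 is the full questionnaire.
    """
    qdef = esfffq()
    with resources.as_file(_fixture_path("subsets.csv")) as path:
        table = pd.read_csv(path)
    subsets = [FeatureSubset(tag="F0", threshold=None, items=qdef.items)]
    for _, row in table.iterrows():
        subsets.append(
            FeatureSubset(
                tag=row["tag"],
                threshold=float(row["threshold"]),
                items=tuple(row["items"].split(";")),
            )
        )
    return subsets
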