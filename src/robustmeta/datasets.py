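"""Bundled example data: the four-study Rituximab meta-analysis.

Four randomized trials (REFLEX, WA16291, DANCER, SERENE) of Rituximab
plus methotrexate versus placebo plus methotrexate in rheumatoid
arthritis; the outcome is ACR50 response at week 24.  Ships with the
Cochrane risk-of-bias ratings of the source systematic review and an
example multi-domain constraint specification.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

from .studies import RobTable, StudyTable, read_rob_table, read_studies


def _data_path(name: str) -> Path:
    return Path(str(resources.files("robustmeta").joinpath("data", name)))


def load_rituximab_studies() -> StudyTable:
    """Outcome counts for the four Rituximab trials."""
    return read_studies(_data_path("rituximab_studies.csv"))


def load_rituximab_rob() -> RobTable:
    """Risk-of-bias ratings for the four Rituximab trials."""
    return read_rob_table(_data_path("rituximab_rob.csv"), load_rituximab_studies())


def rituximab_all_domains_spec() -> dict:
    """Example multi-domain constraint spec combining all six domains.

    Encodes the judgments: WA16291 is at least as good as every other
    study; DANCER and SERENE share the same biases; REFLEX is not
    comparable to DANCER/SERENE.
    """
    with open(_data_path("rituximab_all_domains.json")) as fh:
        return json.load(fh)
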