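"""Helpers for running the genome-scale validation scenarios.

The published iMK735 reconstruction (BioModels MODEL1510060001) is not
redistributed with this package; place it at
``data/iMK735.xml`` (or ``data/MODEL1510060001.xml``) in the repository
root to enable the genome-scale acceptance checks.
"""

from __future__ import annotations

import re
from pathlib import Path

from oleaflux import MetabolicModel, read_sbml

REPO_ROOT = Path(__file__).resolve().parent.parent
CANDIDATE_PATHS = [
    REPO_ROOT / "data" / "iMK735.xml",
    REPO_ROOT / "data" / "MODEL1510060001.xml",
    REPO_ROOT / "data" / "MODEL1510060001_url.xml",
]

#: free uptakes of the in-silico minimal medium: CO2, water, protons,
#: inositol, K+, NH4+, Na+, O2, phosphate, sulfate
IMM_PATTERNS = [
    r"co2", r"h2o", r"\bh\b|proton", r"inost", r"\bk\b|potassium",
    r"nh4|ammoni", r"\bna1?\b|sodium", r"\bo2\b|oxygen", r"\bpi\b|phosphate",
    r"so4|sulph?ate",
]


def imk735_path() -> Path | None:
    for path in CANDIDATE_PATHS:
        if path.exists():
            return path
    return None


def load_imk735() -> MetabolicModel:
    path = imk735_path()
    if path is None:
        raise FileNotFoundError(
            "iMK735 SBML not found; place the supplementary model file "
            "(BioModels MODEL1510060001) at data/iMK735.xml"
        )
    return read_sbml(path)


def _normalize(text: str) -> str:
    return re.sub(r"[^a-z0-9]+", " ", text.lower())


def find_exchange(model: MetabolicModel, pattern: str) -> str:
    """Exchange reaction whose id/name matches a regex (case-insensitive)."""
    rx = re.compile(pattern)
    for rid in model.exchange_reaction_ids():
        rxn = model.reactions[rid]
        if rx.search(_normalize(rid)) or rx.search(_normalize(rxn.name)):
            return rid
    raise KeyError(f"no exchange matching {pattern!r}")


def imm_free_exchanges(model: MetabolicModel) -> list[str]:
    free = []
    for pattern in IMM_PATTERNS:
        try:
            free.append(find_exchange(model, pattern))
        except KeyError:
            continue
    return free


def find_reaction(model: MetabolicModel, pattern: str) -> str:
    rx = re.compile(pattern)
    for rid, rxn in model.reactions.items():
        if rx.search(_normalize(rid)) or rx.search(_normalize(rxn.name)):
            return rid
    raise KeyError(f"no reaction matching {pattern!r}")
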