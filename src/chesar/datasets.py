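"""Packaged reference datasets.

The Ki fixture holds inhibition constants (with standard errors) of 48
quaternary Cinchona-alkaloid derivatives — cinchonidine (CD), cinchonine
(CN) and their 10,11-dihydro analogues (DHCD, DHCN) — against human BChE and
AChE, together with the selectivity index exactly as printed in the source
tables (kept as a string to preserve printed precision).  The non-quaternary
CD and CN parents are absent: their constants were reported elsewhere and
are not part of the panel.

Printed selectivity indices were evidently computed from unrounded constants:
for nine rows the index cannot be re-derived from the tabulated Ki at
half-a-last-digit precision (e.g. DHCD 3F prints 84 while 27/0.3 = 90; with
Ki 0.32 the printed value is recovered).  :data:`SI_FROM_UNROUNDED` lists
those rows.  The stereoselectivity fixture likewise carries the printed
CN/CD and DHCN/DHCD Ki-ratio cells; one AChE cell (4F) shows the same
unrounded-constant effect.

The physicochemical fixture stores MW/100 and PSA/10 exactly as printed;
the loader rescales via the explicit ``scaled`` flag.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .drug_likeness import read_physchem_csv

__all__ = [
    "load_ki_table",
    "load_printed_stereoselectivity",
    "load_physchem_table",
    "SI_FROM_UNROUNDED",
    "STEREO_FROM_UNROUNDED",
]

#: (series, substituent) rows whose printed SI reflects unrounded constants.
SI_FROM_UNROUNDED = frozenset(
    [
        ("CD", "2,4F"),
        ("CD", "2,6F"),
        ("CD", "2F-4Br"),
        ("CD", "2Cl-6F"),
        ("DHCD", "3F"),
        ("DHCD", "4F"),
        ("DHCN", "parent"),
        ("DHCN", "3F"),
        ("DHCN", "4CF3"),
    ]
)

#: (pair, substituent, enzyme) stereoselectivity cells with the same effect.
STEREO_FROM_UNROUNDED = frozenset([("CN/CD", "4F", "AChE")])


def _data_path(name: str):
    return resources.files("chesar.data").joinpath(name)


def load_ki_table() -> pd.DataFrame:
    """48-compound Ki table (µM) with printed selectivity indices."""
    with resources.as_file(_data_path("cholinesterase_ki.csv")) as path:
        return pd.read_csv(path, dtype={"SI_printed": str})


def load_printed_stereoselectivity() -> pd.DataFrame:
    """Printed CN/CD and DHCN/DHCD Ki-ratio cells (46 cells, both enzymes)."""
    with resources.as_file(_data_path("stereoselectivity_printed.csv")) as path:
        return pd.read_csv(path, dtype={"ratio_printed": str})


def load_physchem_table() -> pd.DataFrame:
    """Physicochemical properties in raw units (MW g/mol, PSA Å²).

    Covers the CD/DHCD series; pseudo-enantiomers share identical properties,
    so the CN/DHCN values are the same rows under the partner compound id.
    """
    with resources.as_file(_data_path("physchem_scaled.csv")) as path:
        return read_physchem_csv(path, scaled=True)
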