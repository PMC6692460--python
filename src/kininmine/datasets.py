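"""Bundled reference data.

``load_tick_kinins`` returns the published set of predicted kinin paracopies
from the cloned *Rhipicephalus microplus* precursor and the curated *Ixodes
scapularis* precursor, with the average masses as printed in the source
record.  Sequences are the peptide bodies before C-terminal amidation (the
printed forms carry a trailing "a" for the amide).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_KININ_FILE = "tick_kinins.tsv"


def load_tick_kinins(species: str | None = None) -> pd.DataFrame:
    """The bundled tick kinin table (name, species, sequence, printed_mass_da).

    ``species`` filters on the species column when given.
    """
    with resources.files("kininmine.data").joinpath(_KININ_FILE).open() as fh:
        table = pd.read_csv(fh, sep="\t")
    if species is not None:
        table = table[table["species"] == species].reset_index(drop=True)
    return table
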