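"""Published reference inputs bundled with the package.

Two small tables from a COI barcoding survey of Eastern Atlantic pelagic
fish larvae (237 individuals matched against GenBank- and BOLD-style
reference databases) serve as worked inputs for the consensus tally, the
survey summaries and the cost model.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .consensus import CATEGORIES
from .taxonomy import RANKS

#: Per-rank, per-category assignment counts for the 237 surveyed larvae:
#: rank -> (genbank_only, bold_only, concordance, discrepancy, ambiguity).
_ASSIGNMENT_COUNTS = {
    "order": (8, 0, 0, 0, 0),
    "family": (0, 0, 0, 0, 2),
    "genus": (0, 5, 11, 4, 18),
    "species": (0, 58, 63, 2, 66),
}


def survey_assignment_counts() -> pd.DataFrame:
    """Category × rank count matrix of the surveyed larvae (n = 237)."""
    return pd.DataFrame.from_dict(
        _ASSIGNMENT_COUNTS, orient="index", columns=list(CATEGORIES)
    ).loc[list(RANKS)]


def survey_species_marginals() -> pd.DataFrame:
    """The survey's 44 species-level identifications with lineage, individual
    count ``n`` and station-of-occurrence count ``St``."""
    with resources.files("larvid.data").joinpath(
        "atlantic_survey_species.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
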