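"""Published 5S rRNA reference counts shipped with the package.

These tables hold observed compensatory-switch counts and paired-difference
counts for 5S rRNA across four taxonomic data sets (eubacteria, fungi, plants,
animals).  They serve as inputs for aggregation and for the one-third-rule
test; the original alignments are not redistributed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("rnacoevo.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_reference_switch_counts() -> pd.DataFrame:
    """Long-format switch counts: dataset, switch_type, lca_state, lca_class, count."""
    return _load("switch_counts_5s.tsv")


def load_reference_paired_differences() -> pd.DataFrame:
    """Observed paired/unpaired double-change counts per taxonomic data set."""
    return _load("paired_differences_5s.tsv")
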