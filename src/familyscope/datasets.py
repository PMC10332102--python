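"""Bundled reference tables for the T. kirilowii AP2/ERF family.

These are the published selection estimates (Ka, Ks, Ka/Ks as printed, 6
decimals) for the family's paralog and ortholog pairs, and the published
per-subfamily member counts.  They serve as worked-example inputs: the
printed Ka and Ks columns can be re-divided and re-classified with this
package's functions and checked against the printed ratio column.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    path = resources.files("familyscope") / "data" / name
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def load_paralog_kaks() -> pd.DataFrame:
    """33 within-species paralog pairs: gene_a, gene_b, ka, ks, ratio."""
    return _load("paralog_kaks.tsv")


def load_ortholog_kaks() -> pd.DataFrame:
    """17 T. kirilowii / A. thaliana ortholog pairs: gene_a, gene_b, ka, ks, ratio."""
    return _load("ortholog_kaks.tsv")


def load_subfamily_counts() -> dict[str, int]:
    """Published member counts per subfamily (ERF, DREB, AP2, RAV)."""
    frame = _load("subfamily_counts.tsv")
    return dict(zip(frame["subfamily"], frame["count"]))
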