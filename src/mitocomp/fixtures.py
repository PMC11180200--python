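"""Packaged reference data transcribed from the *Otolithoides pama*
mitogenome annotation (GenBank OQ784575.1).

The gene coordinate table and the genome-wide base counts are printed data,
packaged here so that the geometry and skew stages run without any sequence
download. Coordinates are 1-based inclusive on the heavy strand.
"""

from __future__ import annotations

from importlib import resources

from .composition import BaseCounts
from .io_formats import GeneTable, read_gene_table

__all__ = ["load_opama_gene_table", "OPAMA_BASE_COUNTS", "OPAMA_ACCESSION"]

OPAMA_ACCESSION = "OQ784575.1"

#: Published genome-wide base tally: 29.63% A, 26.18% T, 14.64% G, 29.56% C.
OPAMA_BASE_COUNTS = BaseCounts(a=4892, c=4881, g=2417, t=4323)

_table_cache: GeneTable | None = None


def load_opama_gene_table() -> GeneTable:
    """The 37-gene + OL + CR feature table of the *O. pama* mitogenome."""
    global _table_cache
    if _table_cache is None:
        path = resources.files("mitocomp").joinpath("data/opama_gene_table.tsv")
        with resources.as_file(path) as p:
            _table_cache = read_gene_table(p)
    return _table_cache
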