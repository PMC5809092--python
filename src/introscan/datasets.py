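"""Loaders for the small reference tables packaged with the library.

``ltee_gene_gscores.tsv`` lists the genes under positive selection in the
long-term asexual experiment, with start position and coding length on the
REL606 reference and the parallelism G score.

``replaced_loci_synthetic.tsv`` is a *synthetic* stand-in for the
whole-protein alignments of the 30 replaced loci in the non-mutator
odd-numbered recombinant clones: the published alignments are not
redistributed here, so each locus carries a minimal two-site variable-site
encoding constructed to preserve the published relations among the
ancestral, donor, recipient, and recombinant sequences (which sequences
are identical and which differ).  The allelic-state classifier operates on
these encodings exactly as it would on real variable-site alignments.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .loci import GeneAnnotation


def _data_path(name: str):
    return importlib.resources.files("introscan.data").joinpath(name)


def load_gene_gscores() -> list[GeneAnnotation]:
    """Genes under positive selection in the asexual experiment, with G scores."""
    with importlib.resources.as_file(_data_path("ltee_gene_gscores.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return [
        GeneAnnotation(
            name=row.gene,
            start=int(row.start),
            coding_length=int(row.coding_length),
            g_score=float(row.g_score),
        )
        for row in df.itertuples()
    ]


def load_replaced_loci() -> pd.DataFrame:
    """The 30 replaced loci with synthetic variable-site sequence encodings.

    Columns: population, gene, ancestor, donor, recipient, recombinant,
    strong_selection (bool).
    """
    with importlib.resources.as_file(_data_path("replaced_loci_synthetic.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    df["strong_selection"] = df["strong_selection"].astype(bool)
    return df
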