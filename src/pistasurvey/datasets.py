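"""Bundled reference tables."""

from importlib import resources

import pandas as pd


def load_pistacia_locus_table() -> pd.DataFrame:
    """Published per-locus diversity statistics for 206 pistachio
    (CUPVSiirt) SSR markers scored in 44 *Pistacia* cultivars and genotypes.

    Columns: no, locus, allele_min, allele_max, na, ne, ho, he, pic, plus
    indicator columns for markers that amplified (``amplified_all_species``)
    or were polymorphic (``polymorphic_all_species``) in all six species.
    """
    with resources.files("pistasurvey.data").joinpath("pistacia_ssr_loci_206.csv").open() as fh:
        return pd.read_csv(fh)
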