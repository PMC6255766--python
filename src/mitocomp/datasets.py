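"""Bundled reference annotation tables.

The package ships the published 37-gene annotation of the black softshell
turtle (*Nilssonia nigricans*) mitogenome, accession MG383833 (16,796 bp),
transcribed from its printed gene table.  It carries coordinates, strands,
anticodons and the printed start/stop codons and sizes, but no sequence, so
every coordinate-arithmetic analysis runs on it directly.
"""

from importlib import resources

from .genome_io import MitoGenomeRecord, read_feature_table

NILSSONIA_GENOME_LENGTH = 16796
NILSSONIA_ACCESSION = "MG383833"


def nilssonia_nigricans_annotation() -> MitoGenomeRecord:
    """The 37-gene *N. nigricans* mitogenome annotation (no sequence)."""
    ref = resources.files("mitocomp.data") / "nilssonia_nigricans_genes.tsv"
    with resources.as_file(ref) as path:
        return read_feature_table(
            path,
            genome_length=NILSSONIA_GENOME_LENGTH,
            species="Nilssonia nigricans",
            accession=NILSSONIA_ACCESSION,
        )
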