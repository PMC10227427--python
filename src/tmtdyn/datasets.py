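"""Bundled reference files (shipped gene sets)."""

from importlib import resources

from .io_formats import GeneSetCollection, read_gene_sets


def ccm_gene_sets() -> GeneSetCollection:
    """Central-carbon-metabolism gene sets for budding yeast (bundled GMT)."""
    path = resources.files(__package__) / "data" / "ccm_yeast.gmt"
    with resources.as_file(path) as file_path:
        return read_gene_sets(file_path)
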