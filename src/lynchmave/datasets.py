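"""Bundled reference tables."""

from importlib import resources

from .variants import VariantRecord, read_variant_table


def load_abnormal_vus_reference() -> list[VariantRecord]:
    """The curated set of 24 functionally abnormal MSH2 missense VUS.

    Each record carries the deep-mutational-scan LoF score and the
    non-functional ACMG/AMP evidence codes established by clinical curation;
    the classification engine adds the functional code and recomputes the
    class from point arithmetic.
    """
    ref = resources.files("lynchmave.data") / "abnormal_vus_reference.tsv"
    with resources.as_file(ref) as path:
        return read_variant_table(path)
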